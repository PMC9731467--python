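"""Synthetic survey-style signed networks with planted structure.

The generator emulates the empirical regimes of school sociometric
networks: blocks of mutually nominating students (planted communities,
reciprocal positive pairs at rate ``p_pos_in``), extra one-way friendship
nominations, reciprocal enmities mostly *between* blocks (``p_neg_out``)
with an optional within-block perturbation knob (``p_neg_in``), partial
censoring of reciprocal enmities into one-way nominations (emulating
under-reporting on electronic surveys), and optionally injected
"negative hubs".  Every count the census and degree summary report has a
closed-form binomial expectation (:func:`expected_counts`), so each
downstream stage can be tested against the generator analytically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .detect import Partition
from .graph import DirectedSignedNetwork, ordered


@dataclass
class GeneratorParams:
    """Study conditions for one synthetic network.

    Either ``community_sizes`` (explicit) or ``community_size_mean``
    (geometric sampler, emulating the roughly exponential community-size
    distributions seen in real school networks) must be given.

    Within a block each unordered pair falls into exactly one category:
    reciprocal positive (``p_pos_in``), reciprocal negative (``p_neg_in``),
    a one-way positive arc in either direction (``p_posone_in`` per
    direction), or nothing.  Between blocks the categories are reciprocal
    positive (``p_pos_out``, 0 by default) and reciprocal negative
    (``p_neg_out``).  Mutual exclusivity keeps every census count an exact
    binomial and one-way arcs genuinely one-way.
    """

    n_nodes: int
    community_sizes: list[int] | None = None
    community_size_mean: float | None = None
    p_pos_in: float = 0.5
    p_posone_in: float | None = None  # default: 1.5 * p_pos_in, capped by feasibility
    p_pos_out: float = 0.0
    p_neg_out: float = 0.05
    p_neg_in: float = 0.0
    censor_prob: float = 0.0
    n_hubs: int = 0
    hub_neg_degree: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.community_sizes is None and self.community_size_mean is None:
            raise ValueError("give community_sizes or community_size_mean")
        probs = [self.p_pos_in, self.p_pos_out, self.p_neg_out, self.p_neg_in,
                 self.censor_prob]
        if self.p_posone_in is not None:
            probs.append(self.p_posone_in)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.p_pos_in + self.p_neg_in + 2 * self.effective_p_posone > 1.0 + 1e-12:
            raise ValueError("within-block category probabilities exceed 1")
        if self.p_pos_out + self.p_neg_out > 1.0 + 1e-12:
            raise ValueError("between-block category probabilities exceed 1")
        if self.community_sizes is not None:
            if sum(self.community_sizes) != self.n_nodes:
                raise ValueError("community sizes must sum to n_nodes")
            if any(s < 1 or s > self.n_nodes for s in self.community_sizes):
                raise ValueError("infeasible community size")

    @property
    def effective_p_posone(self) -> float:
        """Per-direction one-way positive rate; the default 1.5x the
        reciprocal-pair rate makes the expected exclusive layer ratio
        (one-way arcs / reciprocal pairs) equal 3, capped so the category
        probabilities stay feasible."""
        if self.p_posone_in is not None:
            return self.p_posone_in
        head = max(0.0, 1.0 - self.p_pos_in - self.p_neg_in)
        return min(1.5 * self.p_pos_in, head / 2.0)


@dataclass
class SyntheticGroundTruth:
    partition: Partition
    censored_pairs: list[tuple[str, str]]
    hub_nodes: list[str]
    realized: dict

    @property
    def community_sizes(self) -> list[int]:
        return self.partition.sizes()


@dataclass
class ExpectedCounts:
    m_pos: float
    m_neg: float  # reciprocal negatives surviving censoring
    k_pos: float
    k_neg: float
    neg_share_pct: float
    oneway_pos_arcs: float
    oneway_neg_arcs: float
    dunbar_pos: float | None
    dunbar_neg: float | None


def _resolve_sizes(params: GeneratorParams, rng: np.random.Generator) -> list[int]:
    if params.community_sizes is not None:
        return list(params.community_sizes)
    mean = float(params.community_size_mean)
    if mean < 2:
        raise ValueError("community_size_mean must be >= 2")
    sizes: list[int] = []
    remaining = params.n_nodes
    while remaining > 0:
        s = int(rng.geometric(1.0 / mean))
        s = max(2, min(s, remaining))
        if remaining - s == 1:  # avoid stranding a singleton
            s += 1
        sizes.append(s)
        remaining -= s
    return sizes


def generate(
    params: GeneratorParams,
) -> tuple[DirectedSignedNetwork, SyntheticGroundTruth]:
    """Draw one directed signed network; reproducible for a fixed seed.

    Per unordered pair one uniform draw selects its category (reciprocal
    positive, reciprocal negative, one-way positive in either direction,
    or absent; see :class:`GeneratorParams`).  Injected hubs then add
    reciprocal negative within-block edges on free pairs, and censoring
    independently degrades each reciprocal negative pair to a one-way arc
    (direction uniform) with probability ``censor_prob``.
    """
    rng = np.random.default_rng(params.seed)
    sizes = _resolve_sizes(params, rng)
    n = params.n_nodes
    nodes = [f"n{k}" for k in range(n)]
    comm = np.repeat(np.arange(len(sizes)), sizes)

    iu, ju = np.triu_indices(n, 1)
    intra = comm[iu] == comm[ju]
    q1 = params.effective_p_posone

    u = rng.random(iu.size)
    # category cut points: [recip_pos | recip_neg | ow_fwd | ow_bwd | none]
    c1 = np.where(intra, params.p_pos_in, params.p_pos_out)
    c2 = c1 + np.where(intra, params.p_neg_in, params.p_neg_out)
    c3 = c2 + np.where(intra, q1, 0.0)
    c4 = c3 + np.where(intra, q1, 0.0)
    recip_pos = u < c1
    recip_neg = (u >= c1) & (u < c2)
    ow_fwd = (u >= c2) & (u < c3)
    ow_rev = (u >= c3) & (u < c4)

    arcs: dict[tuple[str, str], int] = {}
    for a, b in zip(iu[recip_pos], ju[recip_pos]):
        arcs[(nodes[a], nodes[b])] = 1
        arcs[(nodes[b], nodes[a])] = 1
    for a, b in zip(iu[ow_fwd], ju[ow_fwd]):
        arcs[(nodes[a], nodes[b])] = 1
    for a, b in zip(iu[ow_rev], ju[ow_rev]):
        arcs[(nodes[b], nodes[a])] = 1

    neg_pairs: set[tuple[int, int]] = {
        (int(a), int(b)) for a, b in zip(iu[recip_neg], ju[recip_neg])
    }

    # Injected negative hubs: extra reciprocal enmities inside the hub's
    # block.  Free pairs are used first; if the block is too dense, existing
    # reciprocal friendships are converted so the requested degree is met.
    hub_nodes: list[str] = []
    hub_degrees: dict[str, int] = {}
    if params.n_hubs > 0:
        pos_pairs = {(int(a), int(b)) for a, b in zip(iu[recip_pos], ju[recip_pos])}
        hubs = rng.choice(n, size=min(params.n_hubs, n), replace=False)
        for h in hubs:
            h = int(h)
            free, friendly = [], []
            for v in range(n):
                if v == h or comm[v] != comm[h]:
                    continue
                key = tuple(sorted((h, v)))
                if key in neg_pairs:
                    continue
                (friendly if key in pos_pairs else free).append(v)
            rng.shuffle(free)
            rng.shuffle(friendly)
            mates = (free + friendly)[: params.hub_neg_degree]
            for v in mates:
                key = tuple(sorted((h, v)))
                if key in pos_pairs:
                    pos_pairs.discard(key)
                    del arcs[(nodes[key[0]], nodes[key[1]])]
                    del arcs[(nodes[key[1]], nodes[key[0]])]
                neg_pairs.add(key)
            hub_nodes.append(nodes[h])
            hub_degrees[nodes[h]] = len(mates)

    censored: list[tuple[str, str]] = []
    for a, b in sorted(neg_pairs):
        na, nb = nodes[a], nodes[b]
        if params.censor_prob > 0 and rng.random() < params.censor_prob:
            if rng.random() < 0.5:
                arcs[(na, nb)] = -1
            else:
                arcs[(nb, na)] = -1
            censored.append(ordered(na, nb))
        else:
            arcs[(na, nb)] = -1
            arcs[(nb, na)] = -1

    net = DirectedSignedNetwork(nodes, arcs)
    partition = Partition({nodes[v]: int(comm[v]) for v in range(n)})
    realized = {
        "sizes": sizes,
        "recip_pos_pairs": int(recip_pos.sum()),
        "recip_neg_pairs_drawn": len(neg_pairs),
        "recip_neg_pairs_surviving": len(neg_pairs) - len(censored),
        "n_censored": len(censored),
        "oneway_pos_arcs": int(ow_fwd.sum() + ow_rev.sum()),
        "hub_degrees": hub_degrees,
    }
    return net, SyntheticGroundTruth(partition, censored, hub_nodes, realized)


def expected_counts(params: GeneratorParams) -> ExpectedCounts:
    """Closed-form binomial expectations for the generator's link counts.

    Requires explicit ``community_sizes`` (with the geometric sampler the
    block structure is itself random and no closed form is reported).
    """
    if params.community_sizes is None:
        raise ValueError("expected_counts requires explicit community_sizes")
    sizes = params.community_sizes
    intra_pairs = sum(comb(s, 2) for s in sizes)
    inter_pairs = comb(params.n_nodes, 2) - intra_pairs
    q1 = params.effective_p_posone

    m_pos = intra_pairs * params.p_pos_in + inter_pairs * params.p_pos_out
    neg_drawn = (
        intra_pairs * params.p_neg_in
        + inter_pairs * params.p_neg_out
        + params.n_hubs * params.hub_neg_degree
    )
    m_neg = neg_drawn * (1 - params.censor_prob)
    ow_neg = neg_drawn * params.censor_prob
    ow_pos = 2.0 * q1 * intra_pairs
    n = params.n_nodes
    total = m_pos + m_neg
    return ExpectedCounts(
        m_pos=m_pos,
        m_neg=m_neg,
        k_pos=2 * m_pos / n,
        k_neg=2 * m_neg / n,
        neg_share_pct=100.0 * m_neg / total if total else float("nan"),
        oneway_pos_arcs=ow_pos,
        oneway_neg_arcs=ow_neg,
        dunbar_pos=ow_pos / m_pos if m_pos else None,
        dunbar_neg=ow_neg / m_neg if m_neg else None,
    )


def network_with_counts(
    n_nodes: int, m_pos: int, m_neg: int, seed: int = 0
) -> "UndirectedSignedNetwork":
    """Random undirected signed network with *exactly* the given link counts.

    Used to reproduce published accounting rows (mean degrees, negative
    share) from a network rather than from bare arithmetic.
    """
    from .graph import UndirectedSignedNetwork

    total = m_pos + m_neg
    n_pairs = comb(n_nodes, 2)
    if total > n_pairs:
        raise ValueError(f"{total} edges do not fit in {n_pairs} pairs")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, 1)
    chosen = rng.choice(n_pairs, size=total, replace=False)
    nodes = [f"n{k}" for k in range(n_nodes)]
    edges = {}
    for t, c in enumerate(chosen):
        edges[(nodes[iu[c]], nodes[ju[c]])] = 1 if t < m_pos else -1
    return UndirectedSignedNetwork(nodes, edges)


# ---------------------------------------------------------------------------
# Empirical regimes (published per-school link accounting)
# ---------------------------------------------------------------------------

#: per-network (nodes, reciprocal positive links, reciprocal negative links)
TABLE2_COUNTS: dict[str, tuple[int, int, int]] = {
    "esSC": (108, 312, 141),
    "esRRC": (222, 553, 248),
    "esIZ": (417, 1403, 592),
    "ssRDC": (473, 583, 201),
    "ssTN2": (390, 629, 273),
    "ssJLBG": (237, 387, 183),
    "hsCCP": (1429, 3025, 410),
    "hsHUN": (62, 95, 32),
    "usTRS": (561, 834, 169),
}

#: fraction of reciprocal negatives planted within communities, by school level
_NEG_IN_FRACTION = {"es": 0.4, "ss": 0.10, "hs": 0.08, "us": 0.08}

_REGIME_BLOCK_SIZE = 10


def table2_regime(school_label: str, seed: int = 0) -> GeneratorParams:
    """Generator parameters matching one school's published link accounting.

    Blocks of ~10 students; ``p_pos_in`` and the negative-pair rates are
    solved so the expected reciprocal link counts equal the school's
    (nodes, m+, m-) row exactly, hence expected <k>+, <k>- and negative
    share match the published values.  Censoring is off: the published
    counts are post-completion reciprocal links.
    """
    if school_label not in TABLE2_COUNTS:
        raise KeyError(
            f"unknown school label {school_label!r}; choose from {sorted(TABLE2_COUNTS)}"
        )
    n, m_pos, m_neg = TABLE2_COUNTS[school_label]
    sizes = [_REGIME_BLOCK_SIZE] * (n // _REGIME_BLOCK_SIZE)
    rem = n - sum(sizes)
    if rem >= 2:
        sizes.append(rem)
    elif rem == 1:
        sizes[-1] += 1
    intra_pairs = sum(comb(s, 2) for s in sizes)
    inter_pairs = comb(n, 2) - intra_pairs
    p_pos_in = m_pos / intra_pairs
    f_in = _NEG_IN_FRACTION[school_label[:2]]
    p_neg_in = f_in * m_neg / intra_pairs
    p_neg_out = (1 - f_in) * m_neg / inter_pairs
    return GeneratorParams(
        n_nodes=n,
        community_sizes=sizes,
        p_pos_in=p_pos_in,
        p_neg_in=p_neg_in,
        p_neg_out=p_neg_out,
        seed=seed,
    )
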