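"""Signed-community construction and perturbation metrics.

A partition found on the positive subnetwork is turned into *signed
communities* by laying the negative edges back onto it.  The negative
edges that land inside communities perturb them; the metrics quantify
that perturbation:

* Q- — modularity of the partition evaluated on the negative subnetwork;
* Qs — signed modularity, the link-count-weighted combination
  Qs = (2w+ Q+ - 2w- Q-) / (2w+ + 2w-), equal to Q+ when w- = 0;
* frustration F — count of "wrong-place" edges (negative inside a
  community, positive between communities), optionally normalized by the
  total link count; 0 means a perfect signed partition;
* CSB — fraction of within-community triangles that are balanced
  (sign product +1), under the strong-balance convention where (-,-,-)
  is unbalanced;
* PPC — percentage perturbation, 100 (Q+ - Qs)/Q+, mapped onto a
  three-way stable / semi-stable / unstable classification;
* negative hubs — nodes with many negative ties inside their own
  community, a potential bullying indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

from .detect import Partition, modularity, _modularity_counts
from .errors import UndefinedMetricError
from .graph import UndirectedSignedNetwork, subnetwork_by_sign

DEFAULT_STABILITY_THRESHOLDS = (10.0, 25.0)


# ---------------------------------------------------------------------------
# Signed community construction
# ---------------------------------------------------------------------------


@dataclass
class SignedCommunitySet:
    """A positive-subnet partition with the negative edges laid back on it."""

    net: UndirectedSignedNetwork
    partition: Partition
    mc_pos: dict[int, int]  # intra-community positive links per community
    mc_neg: dict[int, int]
    inter_pos: int
    inter_neg: int
    sizes: dict[int, int]

    @property
    def total_mc_pos(self) -> int:
        return sum(self.mc_pos.values())

    @property
    def total_mc_neg(self) -> int:
        return sum(self.mc_neg.values())

    def intra_neg_pct(self) -> float | None:
        """Percentage of intra-community links that are negative (Table-3 style)."""
        total = self.total_mc_pos + self.total_mc_neg
        return 100.0 * self.total_mc_neg / total if total else None

    def to_rows(self) -> list[dict]:
        return [
            {
                "community": c,
                "size": self.sizes[c],
                "mc_pos": self.mc_pos[c],
                "mc_neg": self.mc_neg[c],
            }
            for c in sorted(self.sizes)
        ]


def build_signed_communities(
    net: UndirectedSignedNetwork, p: Partition
) -> SignedCommunitySet:
    missing = [v for v in net.node_ids if v not in p.assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes {missing[:5]}")
    K = p.K
    mc_pos = {c: 0 for c in range(K)}
    mc_neg = {c: 0 for c in range(K)}
    inter_pos = inter_neg = 0
    for (i, j), s in net.edges.items():
        ci, cj = p.assignment[i], p.assignment[j]
        if ci == cj:
            (mc_pos if s > 0 else mc_neg)[ci] += 1
        elif s > 0:
            inter_pos += 1
        else:
            inter_neg += 1
    sizes = {c: 0 for c in range(K)}
    for v in net.node_ids:
        sizes[p.assignment[v]] += 1
    return SignedCommunitySet(net, p, mc_pos, mc_neg, inter_pos, inter_neg, sizes)


# ---------------------------------------------------------------------------
# Modularity-family metrics
# ---------------------------------------------------------------------------


def q_positive(net: UndirectedSignedNetwork, p: Partition) -> float:
    """Q+ of the partition on the positive subnetwork."""
    return modularity(subnetwork_by_sign(net, 1), p)


def q_negative(net: UndirectedSignedNetwork, p: Partition) -> float:
    """Modularity of the partition on the negative subnetwork.

    Convention: returns 0.0 when the network has no negative links (so
    Qs = Q+ holds exactly); callers needing to distinguish can check
    ``net.m_neg == 0``.
    """
    neg = subnetwork_by_sign(net, -1)
    if neg.m_total == 0:
        return 0.0
    return _modularity_counts(neg, p, 1.0)


def q_signed(net: UndirectedSignedNetwork, p: Partition) -> float:
    """Signed modularity Qs = (2w+ Q+ - 2w- Q-) / (2w+ + 2w-)."""
    w_pos, w_neg = net.m_pos, net.m_neg
    if w_pos + w_neg == 0:
        raise UndefinedMetricError("signed modularity undefined on edgeless network")
    qp = q_positive(net, p) if w_pos else 0.0
    qn = q_negative(net, p)
    return (w_pos * qp - w_neg * qn) / (w_pos + w_neg)


def frustration(
    net: UndirectedSignedNetwork, p: Partition, normalized: bool = True
) -> float:
    """Negative intra-community plus positive inter-community edge count.

    ``normalized=True`` divides by the total number of links; the result is
    then in [0, 1] with 0 meaning every positive edge sits inside a
    community and every negative edge between communities.
    """
    f = 0
    for (i, j), s in net.edges.items():
        same = p.assignment[i] == p.assignment[j]
        if (s < 0 and same) or (s > 0 and not same):
            f += 1
    if not normalized:
        return float(f)
    if net.m_total == 0:
        raise UndefinedMetricError("normalized frustration undefined on edgeless network")
    return f / net.m_total


# ---------------------------------------------------------------------------
# Balance
# ---------------------------------------------------------------------------


def classify_triad(s1: int, s2: int, s3: int) -> str:
    """Strong structural balance: balanced iff the sign product is +1.

    (+,+,+) and one-positive/two-negative triads are balanced; (+,+,-) and
    (-,-,-) are unbalanced.
    """
    for s in (s1, s2, s3):
        if s not in (-1, 1):
            raise ValueError(f"triad signs must be -1 or +1, got {s!r}")
    return "balanced" if s1 * s2 * s3 > 0 else "unbalanced"


@dataclass
class TriadCensus:
    balanced_in_communities: int
    total_in_communities: int
    per_community: dict[int, tuple[int, int]]  # community -> (balanced, total)

    def to_dict(self) -> dict:
        return {
            "balanced_in_communities": self.balanced_in_communities,
            "total_in_communities": self.total_in_communities,
            "per_community": {
                str(c): {"balanced": b, "total": t}
                for c, (b, t) in sorted(self.per_community.items())
            },
        }


def csb(
    net: UndirectedSignedNetwork,
    p: Partition,
    min_community_size: int = 2,
) -> tuple[float | None, TriadCensus]:
    """Community social balance: balanced within-community triangles / all
    within-community triangles.

    Each triangle (all three nodes in one community, all three signed edges
    present) is counted once.  Returns ``(None, census)`` when no
    within-community triangle exists.  ``min_community_size`` > 2 excludes
    small communities from the census (sensitivity analysis; size-2
    communities can never contribute a triangle anyway).
    """
    adj = net.adjacency()
    per: dict[int, tuple[int, int]] = {}
    total_b = total_t = 0
    for c, members in enumerate(p.communities()):
        if len(members) < max(3, min_community_size):
            per[c] = (0, 0)
            continue
        members = sorted(members)
        b = t = 0
        for i, j, k in combinations(members, 3):
            s_ij = adj[i].get(j)
            if s_ij is None:
                continue
            s_ik = adj[i].get(k)
            if s_ik is None:
                continue
            s_jk = adj[j].get(k)
            if s_jk is None:
                continue
            t += 1
            if s_ij * s_ik * s_jk > 0:
                b += 1
        per[c] = (b, t)
        total_b += b
        total_t += t
    census = TriadCensus(total_b, total_t, per)
    return (total_b / total_t if total_t else None), census


# ---------------------------------------------------------------------------
# Perturbation percentage and stability classes
# ---------------------------------------------------------------------------


def ppc(q_pos: float, q_signed_val: float) -> float:
    """Percentage perturbation of communities: 100 (Q+ - Qs) / Q+."""
    if q_pos <= 0:
        raise UndefinedMetricError("PPC undefined for non-positive Q+")
    return 100.0 * (q_pos - q_signed_val) / q_pos


def classify_stability(
    ppc_pct: float, thresholds: tuple[float, float] = DEFAULT_STABILITY_THRESHOLDS
) -> str:
    """Map PPC onto stable / semi-stable / unstable (half-open intervals).

    ``ppc < t1`` is stable, ``t1 <= ppc < t2`` semi-stable, else unstable.
    The default (10, 25) split is an operational choice, reported alongside
    results; it is configurable everywhere it is consumed.
    """
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must satisfy t1 < t2")
    if ppc_pct < t1:
        return "stable"
    if ppc_pct < t2:
        return "semi-stable"
    return "unstable"


# ---------------------------------------------------------------------------
# Aggregate report and negative hubs
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    q_pos: float
    q_neg: float
    q_signed: float
    frustration_norm: float
    csb: float | None
    ppc_pct: float | None
    stability_class: str | None
    q_neg_defined: bool = True
    ppc_defined: bool = True

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def metrics_report(
    net: UndirectedSignedNetwork,
    p: Partition,
    stability_thresholds: tuple[float, float] = DEFAULT_STABILITY_THRESHOLDS,
    min_community_size: int = 2,
) -> MetricsReport:
    """All perturbation metrics for one network/partition in one pass.

    Degenerate networks (no edges, or no positive edges) yield a fully
    flagged report instead of raising.
    """
    if net.m_total == 0:
        return MetricsReport(
            q_pos=0.0, q_neg=0.0, q_signed=0.0, frustration_norm=0.0,
            csb=None, ppc_pct=None, stability_class=None,
            q_neg_defined=False, ppc_defined=False,
        )
    qp = q_positive(net, p) if net.m_pos else 0.0
    qn = q_negative(net, p)
    qs = q_signed(net, p)
    fr = frustration(net, p, normalized=True)
    csb_val, _ = csb(net, p, min_community_size=min_community_size)
    try:
        ppc_val: float | None = ppc(qp, qs)
        stab: str | None = classify_stability(ppc_val, stability_thresholds)
        ppc_ok = True
    except UndefinedMetricError:
        ppc_val, stab, ppc_ok = None, None, False
    return MetricsReport(
        q_pos=qp,
        q_neg=qn,
        q_signed=qs,
        frustration_norm=fr,
        csb=csb_val,
        ppc_pct=ppc_val,
        stability_class=stab,
        q_neg_defined=net.m_neg > 0,
        ppc_defined=ppc_ok,
    )


@dataclass
class NegativeHubReport:
    per_node: dict[str, tuple[int, int]]  # node -> (community, intra-neg degree)
    flagged: list[str]
    threshold: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "flagged": self.flagged,
            "per_node": {
                v: {"community": c, "intra_neg_degree": d}
                for v, (c, d) in self.per_node.items()
            },
        }


def negative_hubs(scs: SignedCommunitySet, min_intra_neg: int = 3) -> NegativeHubReport:
    """Flag nodes whose within-community negative degree reaches the threshold."""
    if min_intra_neg < 1:
        raise ValueError("min_intra_neg must be >= 1")
    deg: dict[str, int] = {}
    assign = scs.partition.assignment
    for (i, j), s in scs.net.edges.items():
        if s < 0 and assign[i] == assign[j]:
            deg[i] = deg.get(i, 0) + 1
            deg[j] = deg.get(j, 0) + 1
    per = {v: (assign[v], d) for v, d in sorted(deg.items())}
    flagged = [v for v, (_, d) in per.items() if d >= min_intra_neg]
    return NegativeHubReport(per, flagged, min_intra_neg)
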