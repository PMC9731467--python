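"""Structural-balance imputation of missing reciprocal negative links.

Electronic-survey respondents under-report enmities, leaving many negative
nominations one-way.  The heuristic implemented here upgrades a one-way
negative arc (i -> j) to a reciprocal negative pair when the balance of
evidence from structural balance theory supports it: for every common
reciprocal neighbour v of i and j, the triad {i, j, v} — evaluated as if
{i, j} were a negative edge — is balanced iff the product of its three
signs is +1 ("a common enemy of my friends is probably my enemy").  The
link is added only on a strict majority of balanced over unbalanced triads.

Conservatism rules, since false negatives are cheaper than inventing an
enmity: pairs where the reverse arc is positive are excluded by default, a
tie or an empty context rejects, and all candidates are judged against the
same pre-completion reciprocal projection in a single simultaneous pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import (
    DirectedSignedNetwork,
    UndirectedSignedNetwork,
    ordered,
    reciprocal_projection,
)

DECISIONS = ("added", "rejected-tie", "rejected-minority", "rejected-no-context")


@dataclass
class CandidatePair:
    i: str
    j: str
    direction: str  # "i->j" or "j->i": which negative arc exists
    balanced_count: int | None = None
    unbalanced_count: int | None = None
    decision: str | None = None


@dataclass
class CompletionReport:
    candidates: list[CandidatePair] = field(default_factory=list)
    n_added: int = 0
    m_neg_before: int = 0
    m_neg_after: int = 0
    n_iterations: int = 1

    def to_dict(self) -> dict:
        return {
            "n_candidates": len(self.candidates),
            "n_added": self.n_added,
            "m_neg_before": self.m_neg_before,
            "m_neg_after": self.m_neg_after,
            "n_iterations": self.n_iterations,
            "candidates": [
                {
                    "i": c.i,
                    "j": c.j,
                    "direction": c.direction,
                    "balanced": c.balanced_count,
                    "unbalanced": c.unbalanced_count,
                    "decision": c.decision,
                }
                for c in self.candidates
            ],
        }

    @property
    def added_pairs(self) -> list[tuple[str, str]]:
        return [ordered(c.i, c.j) for c in self.candidates if c.decision == "added"]


def find_candidates(
    net: DirectedSignedNetwork, include_positive_reverse: bool = False
) -> list[CandidatePair]:
    """Unordered pairs with exactly one negative arc and no reciprocal negative.

    By default a pair whose reverse arc is *positive* is not a candidate
    (completing it would override a declared friendship); pass
    ``include_positive_reverse=True`` for the permissive policy.
    """
    out: list[CandidatePair] = []
    seen: set[tuple[str, str]] = set()
    for (i, j), s in net.arcs.items():
        if s > 0:
            continue
        key = ordered(i, j)
        if key in seen:
            continue
        rev = net.arcs.get((j, i))
        if rev == -1:
            seen.add(key)  # already reciprocal negative
            continue
        if rev == 1 and not include_positive_reverse:
            continue
        seen.add(key)
        out.append(CandidatePair(i=key[0], j=key[1], direction="i->j" if (i, j) == key else "j->i"))
    return out


def evaluate_candidate(
    recip: UndirectedSignedNetwork, i: str, j: str
) -> tuple[int, int]:
    """Balanced / unbalanced triad counts for the hypothetical edge {i,j} = -1.

    Only reciprocal edges provide triad context: every node v adjacent (in
    `recip`) to both i and j closes a triad whose balance is the sign
    product s(i,v) * s(j,v) * (-1).
    """
    if i == j:
        raise ValueError("candidate endpoints must differ")
    adj = recip.adjacency()
    bal = unbal = 0
    ai, aj = adj[i], adj[j]
    if len(aj) < len(ai):
        ai, aj = aj, ai
    for v, s_iv in ai.items():
        s_jv = aj.get(v)
        if s_jv is None:
            continue
        if s_iv * s_jv * -1 > 0:
            bal += 1
        else:
            unbal += 1
    return bal, unbal


def _decide(bal: int, unbal: int) -> str:
    if bal + unbal == 0:
        return "rejected-no-context"
    if bal > unbal:
        return "added"
    if bal == unbal:
        return "rejected-tie"
    return "rejected-minority"


def complete_negative_links(
    net: DirectedSignedNetwork,
    include_positive_reverse: bool = False,
    iterate: bool = False,
    max_iterations: int = 50,
) -> tuple[DirectedSignedNetwork, CompletionReport]:
    """Add the reverse negative arc for every majority-balanced candidate.

    All candidates of a pass are evaluated against the same pre-completion
    reciprocal projection, so the result is deterministic and independent of
    candidate order.  ``iterate=True`` repeats passes until no candidate is
    added (off by default: a single application is the intended use; chained
    passes compound the balance bias of the heuristic).
    """
    recip0, _ = reciprocal_projection(net)
    result = net.copy()
    report = CompletionReport(m_neg_before=recip0.m_neg)
    for it in range(1, (max_iterations if iterate else 1) + 1):
        recip, _ = reciprocal_projection(result)
        candidates = find_candidates(result, include_positive_reverse)
        n_added_pass = 0
        additions: dict[tuple[str, str], int] = {}
        for cand in candidates:
            bal, unbal = evaluate_candidate(recip, cand.i, cand.j)
            cand.balanced_count, cand.unbalanced_count = bal, unbal
            cand.decision = _decide(bal, unbal)
            if cand.decision == "added":
                src, dst = (cand.i, cand.j) if cand.direction == "i->j" else (cand.j, cand.i)
                additions[(dst, src)] = -1
                n_added_pass += 1
        result = DirectedSignedNetwork(
            list(result.node_ids), {**result.arcs, **additions}
        )
        report.candidates.extend(candidates)
        report.n_added += n_added_pass
        report.n_iterations = it
        if not iterate or n_added_pass == 0:
            break
    final_recip, _ = reciprocal_projection(result)
    report.m_neg_after = final_recip.m_neg
    return result, report
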