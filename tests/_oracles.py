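"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's own code paths: modularity and
frustration are recomputed from first principles (networkx modularity /
direct pair loops), triads by exhaustive triple enumeration, and optima by
enumerating every set partition of the node set.
"""

from itertools import combinations

import networkx as nx


def set_partitions(items):
    """Yield every partition of `items` as a list of lists."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1 :]
        yield [[first]] + part


def nx_modularity(und, blocks):
    """Modularity via networkx on the (single-sign) network's edges."""
    g = und.to_networkx()
    return nx.community.modularity(g, [set(b) for b in blocks])


def brute_max_modularity(und):
    """(best value, best blocks) over every partition of the node set."""
    best_val, best_blocks = -2.0, None
    for blocks in set_partitions(und.node_ids):
        val = nx_modularity(und, blocks)
        if val > best_val:
            best_val, best_blocks = val, blocks
    return best_val, best_blocks


def frustration_count(und, assignment):
    """Wrong-place edges counted with independent logic."""
    f = 0
    for (i, j), s in und.edges.items():
        same = assignment[i] == assignment[j]
        if same and s < 0:
            f += 1
        if not same and s > 0:
            f += 1
    return f


def brute_min_frustration(und):
    best = None
    for blocks in set_partitions(und.node_ids):
        assignment = {v: k for k, b in enumerate(blocks) for v in b}
        f = frustration_count(und, assignment)
        if best is None or f < best:
            best = f
    return best


def triads_for_pair(und, i, j, hypothetical_sign=-1):
    """(balanced, unbalanced) for edge {i,j}=hypothetical_sign by full
    enumeration of node triples containing i and j."""
    bal = unbal = 0
    for v in und.node_ids:
        if v in (i, j):
            continue
        s_iv = und.sign(i, v)
        s_jv = und.sign(j, v)
        if s_iv is None or s_jv is None:
            continue
        if s_iv * s_jv * hypothetical_sign > 0:
            bal += 1
        else:
            unbal += 1
    return bal, unbal


def community_triads(und, assignment):
    """(balanced, total) within-community triangles by O(n^3) enumeration."""
    bal = tot = 0
    for i, j, k in combinations(und.node_ids, 3):
        if not assignment[i] == assignment[j] == assignment[k]:
            continue
        s1, s2, s3 = und.sign(i, j), und.sign(i, k), und.sign(j, k)
        if None in (s1, s2, s3):
            continue
        tot += 1
        if s1 * s2 * s3 > 0:
            bal += 1
    return bal, tot


def pairwise_q_signed(und, assignment):
    """Q-signed by direct summation over all ordered node pairs of
    (A+_ij - k+_i k+_j / 2w+) - (A-_ij - k-_i k-_j / 2w-), divided by
    (2w+ + 2w-), restricted to same-community pairs."""
    nodes = und.node_ids
    kp = {v: 0 for v in nodes}
    kn = {v: 0 for v in nodes}
    for (i, j), s in und.edges.items():
        d = kp if s > 0 else kn
        d[i] += 1
        d[j] += 1
    wp = sum(kp.values()) / 2
    wn = sum(kn.values()) / 2
    total = 0.0
    # the i == j terms carry no adjacency but do contribute to the null model
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            s = und.sign(i, j) if i != j else None
            ap = 1.0 if s == 1 else 0.0
            an = 1.0 if s == -1 else 0.0
            pos_term = (ap - kp[i] * kp[j] / (2 * wp)) if wp else 0.0
            neg_term = (an - kn[i] * kn[j] / (2 * wn)) if wn else 0.0
            total += pos_term - neg_term
    return total / (2 * wp + 2 * wn)
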