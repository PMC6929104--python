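"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle re-derives the expected result by literal enumeration, sharing
no code with the implementation under test.
"""

import math
from itertools import combinations


def _sign(x):
    return (x > 0) - (x < 0)


def oracle_mouse_consensus(values3, values5, fc_threshold=1.5, min_studies=2):
    """Literal application of the three arm-combining criteria.

    ``values3``/``values5``: study -> log2FC (0.0 or absence = not
    observed).  Returns (direction, criterion) or None, where direction is
    "up"/"down", applying the same written tie rules: a study whose two
    arms pass with opposite signs disqualifies the stem; when both
    directions qualify the larger support wins, ties disqualify.
    """
    log_t = math.log2(fc_threshold)
    pass3 = {s: _sign(v) for s, v in values3.items() if v and abs(v) >= log_t}
    pass5 = {s: _sign(v) for s, v in values5.items() if v and abs(v) >= log_t}
    for s in set(pass3) & set(pass5):
        if pass3[s] != pass5[s]:
            return None
    candidates = []  # (criterion order, criterion, sign, n_support)
    for order, (crit, passing) in enumerate(
        [("3p_two_studies", pass3), ("5p_two_studies", pass5)]
    ):
        for sgn in (1, -1):
            sup = [s for s, v in passing.items() if v == sgn]
            # enumerate subsets: does ANY subset of size min_studies agree?
            for combo in combinations(sorted(sup), min_studies):
                candidates.append((order, crit, sgn, len(sup)))
                break
    for sgn in (1, -1):
        if any(
            pass3.get(a) == sgn and pass5.get(b) == sgn
            for a in pass3
            for b in pass5
            if a != b
        ):
            candidates.append((2, "cross_arm", sgn, 2))
    if not candidates:
        return None
    signs = {c[2] for c in candidates}
    if len(signs) > 1:
        best = {s: max(c[3] for c in candidates if c[2] == s) for s in signs}
        top = max(best.values())
        winners = [s for s, n in best.items() if n == top]
        if len(winners) > 1:
            return None
        candidates = [c for c in candidates if c[2] == winners[0]]
    candidates.sort()
    _, crit, sgn, _ = candidates[0]
    return ("up" if sgn > 0 else "down", crit)


def oracle_connections(mirna_lfc, gene_lfc, edges):
    """Brute-force double loop: every (miRNA key, gene key) edge whose two
    endpoints are present with strictly opposite log2FC signs."""
    out = set()
    for mkey, gkey in edges:
        if mkey in mirna_lfc and gkey in gene_lfc:
            if _sign(mirna_lfc[mkey]) * _sign(gene_lfc[gkey]) == -1:
                out.add((mkey, gkey))
    return out


def oracle_hypergeom_upper_tail(N, K, n, k):
    """P(X >= k) by full enumeration of all C(N, n) draws (N small)."""
    universe = list(range(N))
    annotated = set(range(K))
    hits = total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


def oracle_triplets(sig_genes, gene_sign, mirna_sign, edges, adjacency, sig_metabolites):
    """Literal three-criteria check: significant gene, >= 1 opposing
    significant miRNA regulator, >= 1 adjacent significant metabolite."""
    out = set()
    for g in sig_genes:
        has_opposing = any(
            m in mirna_sign and mirna_sign[m] == -gene_sign[g]
            for m, g2 in edges
            if g2 == g
        )
        has_met = any(
            met in sig_metabolites for g2, met in adjacency if g2 == g
        )
        if has_opposing and has_met:
            out.add(g)
    return out
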