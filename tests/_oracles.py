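"""Independent brute-force oracles used to validate package operations.

Everything here is deliberately written with the most naive algorithm
available (quadratic DP, exhaustive enumeration, direct summation) and
shares no code with the implementations it checks.
"""

from itertools import permutations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

BLOSUM62 = substitution_matrices.load("BLOSUM62")
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOPS = set(_TABLE.stop_codons)


def sw_score_dp(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman with affine gaps (Gotoh three-matrix recursion)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def n50_scan(lengths) -> int:
    """N50 by direct definition: largest L such that fragments >= L hold at
    least half the total length."""
    total = sum(lengths)
    candidates = sorted(set(lengths), reverse=True)
    for L in candidates:
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    raise AssertionError("unreachable")


def ng86_counts(codon1: str, codon2: str):
    """Per-codon-pair NG86 quantities by full enumeration:
    (syn sites of codon1, syn sites of codon2, syn diffs, nonsyn diffs)."""

    def aa(c):
        return _TABLE.forward_table[c]

    def syn_sites(codon):
        s = 0.0
        for k in range(3):
            for nt in "ACGT":
                if nt == codon[k]:
                    continue
                mut = codon[:k] + nt + codon[k + 1 :]
                if mut in STOPS:
                    continue
                if aa(mut) == aa(codon):
                    s += 1 / 3
        return s

    diffs = [k for k in range(3) if codon1[k] != codon2[k]]
    path_counts = []
    for order in permutations(diffs):
        cur, sd, nd, valid = codon1, 0, 0, True
        for k in order:
            nxt = cur[:k] + codon2[k] + cur[k + 1 :]
            if nxt in STOPS:
                valid = False
                break
            if aa(cur) == aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            path_counts.append((sd, nd))
    if diffs and not path_counts:
        sd_avg, nd_avg = 0.0, float(len(diffs))
    elif not diffs:
        sd_avg = nd_avg = 0.0
    else:
        sd_avg = sum(p[0] for p in path_counts) / len(path_counts)
        nd_avg = sum(p[1] for p in path_counts) / len(path_counts)
    return syn_sites(codon1), syn_sites(codon2), sd_avg, nd_avg


def enumerate_best_chain(anchors, min_block, max_gap):
    """All maximal collinear chains by exhaustive DFS over anchor subsets.

    ``anchors`` is a list of (qi, si) index pairs. Returns the longest
    valid chain (ties: lexicographically smallest sequence of pairs), or
    None if no chain reaches ``min_block``.
    """
    anchors = sorted(anchors)
    best = None

    def extend(chain, sign):
        nonlocal best
        if len(chain) >= min_block:
            cand = tuple(chain)
            if best is None or len(cand) > len(best) or (
                len(cand) == len(best) and cand < best
            ):
                best = cand
        last = chain[-1]
        for a in anchors:
            dq = a[0] - last[0]
            ds = sign * (a[1] - last[1])
            if 1 <= dq <= max_gap + 1 and 1 <= ds <= max_gap + 1:
                extend(chain + [a], sign)

    for sign in (1, -1):
        for a in anchors:
            extend([a], sign)
    return best


def pruning_bruteforce(alignment, tree_edges, pi, P_matrices, codon_index):
    """lnL of a <=3-taxon star tree by summation over the root state.

    ``tree_edges`` maps taxon -> branch length key into ``P_matrices``.
    """
    taxa = sorted(alignment)
    n_codons = len(next(iter(alignment.values()))) // 3
    lnL = 0.0
    for s in range(n_codons):
        site = 0.0
        states = {
            t: codon_index[alignment[t][3 * s : 3 * s + 3]] for t in taxa
        }
        for root_state in range(len(pi)):
            term = pi[root_state]
            for t in taxa:
                term *= P_matrices[t][root_state, states[t]]
            site += term
        lnL += np.log(site)
    return lnL
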