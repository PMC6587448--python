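"""Codon-level building blocks shared by the simulator and the selection scan.

The 61 sense codons of the standard genetic code are the state space of the
Goldman–Yang (GY94) substitution model used throughout: instantaneous rates
are nonzero only between codons differing at a single nucleotide position,
multiplied by kappa for transitions and by omega for nonsynonymous changes,
and weighted by the target codon's equilibrium frequency.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
CODONS = tuple(
    "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in STOP_CODONS
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = {c: _TABLE.forward_table[c] for c in CODONS}

#: codon prefixes whose third position is fourfold degenerate
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(x) for x in product("ACGT", repeat=2))
    if len({_TABLE.forward_table.get(p + n) for n in "ACGT"} - {None}) == 1
    and all(p + n not in STOP_CODONS for n in "ACGT")
)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def codon_diffs(c1: str, c2: str) -> list[int]:
    """Positions (0..2) at which two codons differ."""
    return [k for k in range(3) if c1[k] != c2[k]]


@lru_cache(maxsize=1)
def _single_step_structure():
    """Precompute, for every single-nucleotide codon pair, (i, j, ts, nonsyn)."""
    rows, cols, ts, nonsyn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            d = codon_diffs(ci, cj)
            if len(d) != 1:
                continue
            k = d[0]
            rows.append(i)
            cols.append(j)
            ts.append(is_transition(ci[k], cj[k]))
            nonsyn.append(CODON_AA[ci] != CODON_AA[cj])
    return (
        np.array(rows),
        np.array(cols),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


def f1x4_frequencies(nuc_freqs) -> np.ndarray:
    """Codon frequencies from a single set of nucleotide frequencies (F1x4).

    ``nuc_freqs`` is indexed in T, C, A, G order. Stop codons are excluded and
    the vector renormalised over the 61 sense codons.
    """
    f = {n: q for n, q in zip(NUCLEOTIDES, nuc_freqs)}
    pi = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in CODONS])
    return pi / pi.sum()


def f3x4_frequencies(pos_freqs) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4).

    ``pos_freqs`` is a 3x4 array (codon position x nucleotide in T,C,A,G
    order), as estimated from an alignment (PAML CodonFreq=2).
    """
    pos_freqs = np.asarray(pos_freqs, dtype=float)
    pi = np.array(
        [
            pos_freqs[0, NUCLEOTIDES.index(c[0])]
            * pos_freqs[1, NUCLEOTIDES.index(c[1])]
            * pos_freqs[2, NUCLEOTIDES.index(c[2])]
            for c in CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate position frequencies")
    return pi / total


def empirical_codon_frequencies(seqs, model: str = "F3x4") -> np.ndarray:
    """Estimate equilibrium codon frequencies from coding sequences.

    ``seqs`` is an iterable of in-frame nucleotide strings (gaps allowed and
    skipped). ``model`` is F1x4 or F3x4.
    """
    counts = np.ones((3, 4))  # +1 pseudocount per cell
    for s in seqs:
        s = s.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3]
            if any(ch not in "TCAG" for ch in codon):
                continue
            for k in range(3):
                counts[k, NUCLEOTIDES.index(codon[k])] += 1
    if model == "F3x4":
        return f3x4_frequencies(counts / counts.sum(axis=1, keepdims=True))
    if model == "F1x4":
        tot = counts.sum(axis=0)
        return f1x4_frequencies(tot / tot.sum())
    raise ValueError(f"unknown frequency model {model!r}")


def build_codon_rate_matrix(
    kappa: float, omega: float, codon_frequencies, scale: bool = True
) -> np.ndarray:
    """GY94 61x61 instantaneous rate matrix.

    q_ij = pi_j (x kappa for transitions, x omega for nonsynonymous changes)
    for single-nucleotide changes, 0 otherwise; diagonal makes rows sum to
    zero. With ``scale`` the matrix is normalised so the expected number of
    substitutions per codon per unit time, sum_i pi_i * (-q_ii), equals 1.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    pi = np.asarray(codon_frequencies, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-6:
        raise ValueError("codon_frequencies must be 61 positive values summing to 1")
    rows, cols, ts, nonsyn = _single_step_structure()
    rates = pi[cols].copy()
    rates[ts] *= kappa
    rates[nonsyn] *= omega
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[rows, cols] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if scale:
        mu = -(pi * np.diag(Q)).sum()
        if mu > 0:
            Q /= mu
    return Q


class CodonEigen:
    """Eigendecomposition of a (reversible) GY94 rate matrix.

    The matrix is decomposed unscaled; ``rate`` holds its expected number
    of substitutions per codon per unit time, sum_i pi_i * (-q_ii). By
    default branch lengths given to :meth:`transition_matrix` are measured
    in expected substitutions/codon under this matrix itself; for
    site-class mixtures pass the mixture-averaged ``rate`` instead, so all
    classes share one time scale and rate differences between classes are
    preserved (the standard convention for branch-site models).
    """

    def __init__(self, kappa: float, omega: float, codon_frequencies):
        pi = np.asarray(codon_frequencies, dtype=float)
        Q = build_codon_rate_matrix(kappa, omega, pi, scale=False)
        self.rate = float(-(pi * np.diag(Q)).sum())
        sqrt_pi = np.sqrt(pi)
        # symmetrize: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        B = (Q / sqrt_pi[None, :]) * sqrt_pi[:, None]
        B = (B + B.T) / 2.0
        w, U = np.linalg.eigh(B)
        self.pi = pi
        self._w = w
        self._left = U / sqrt_pi[:, None]   # D^{-1/2} U
        self._right = (U * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float, rate: float | None = None) -> np.ndarray:
        """P(t) = exp(Q t / rate); rows sum to 1, entries clipped to [0, 1].

        ``rate`` defaults to this matrix's own rate (branch length measured
        in substitutions/codon under this matrix).
        """
        if t < 0:
            raise ValueError("branch length must be non-negative")
        r = self.rate if rate is None else rate
        if r <= 0:
            raise ValueError("rate must be positive")
        P = (self._left * np.exp(self._w * (t / r))) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def encode_codons(seq: str) -> np.ndarray:
    """Encode an in-frame nucleotide string as codon indices.

    Gap or ambiguous codons map to -1 (treated as missing data downstream).
    Internal stop codons raise ValueError.
    """
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in CODON_INDEX:
            out[i // 3] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            if i < len(seq) - 3:
                raise ValueError(f"internal stop codon at codon {i // 3}")
            out[i // 3] = -1
        else:
            out[i // 3] = -1
    return out


def decode_codons(indices) -> str:
    return "".join(CODONS[i] if i >= 0 else "---" for i in indices)
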