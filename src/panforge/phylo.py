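"""Supermatrix phylogeny: alignment, filtering, distances, NJ and dating.

Single-copy families are aligned at the protein level and back-translated
to codons, concatenated, and cleaned with a two-rule column filter (drop
columns with gaps; drop columns whose majority residue is rare). Pairwise
GTR distances feed a neighbor-joining tree, rooted on a declared outgroup.
Fourfold-degenerate third positions — approximately neutral sites — are
extracted for divergence dating under a strict molecular clock: node ages
and a single rate are found by constrained least squares against the
observed root-to-node path lengths, with calibration intervals as hard
constraints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from scipy.linalg import logm
from scipy.optimize import minimize

from ._codon import FOURFOLD_PREFIXES
from ._trees import parse_newick
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

SATURATION_CAP = 5.0
_NUC = "ACGT"


# ---------------------------------------------------------------------------
# family alignment (star alignment around the longest member)


def _global_protein_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _translate_or_reject(name: str, cds: str) -> str:
    if len(cds) % 3:
        raise InputError(f"{name}: CDS length not divisible by 3")
    prot = str(Seq(cds).translate())
    body = prot[:-1] if prot.endswith("*") else prot
    if "*" in body:
        raise InputError(f"{name}: internal stop codon")
    return body


def align_family(cds_by_taxon: dict[str, str]) -> dict[str, str]:
    """Codon-aware multiple alignment of one family's coding sequences.

    Proteins are aligned pairwise (Needleman-Wunsch, BLOSUM62, 11/1 affine
    gaps) against the longest member as reference; the pairwise alignments
    are merged on reference coordinates (insertions relative to the
    reference are pooled per position) and back-translated so gaps come in
    whole codons. Families with internal stop codons are rejected.
    """
    if len(cds_by_taxon) < 2:
        raise InputError("align_family needs at least two taxa")
    prots = {t: _translate_or_reject(t, s) for t, s in cds_by_taxon.items()}
    ref = max(sorted(prots), key=lambda t: len(prots[t]))
    ref_prot = prots[ref]
    L = len(ref_prot)
    aligner = _global_protein_aligner()

    # per-taxon: residue index at each ref column, and insertions before col i
    res_of: dict[str, list[int | None]] = {}
    insertions: dict[str, dict[int, str]] = {}
    for taxon in sorted(prots):
        if taxon == ref:
            res_of[taxon] = list(range(L))
            insertions[taxon] = {}
            continue
        aln = aligner.align(ref_prot, prots[taxon])[0]
        ref_blocks, qry_blocks = aln.aligned
        mapping: list[int | None] = [None] * L
        ins: dict[int, str] = {}
        prev_r_end, prev_q_end = 0, 0
        for (rs, re), (qs, qe) in zip(ref_blocks, qry_blocks):
            if qs > prev_q_end:  # insertion in query before ref column rs
                ins[rs] = ins.get(rs, "") + prots[taxon][prev_q_end:qs]
            for k in range(rs, re):
                mapping[k] = qs + (k - rs)
            prev_r_end, prev_q_end = re, qe
        if prev_q_end < len(prots[taxon]):
            ins[L] = ins.get(L, "") + prots[taxon][prev_q_end:]
        res_of[taxon] = mapping
        insertions[taxon] = ins

    ins_width = {
        i: max((len(insertions[t].get(i, "")) for t in prots), default=0)
        for i in range(L + 1)
    }

    out = {}
    for taxon in sorted(prots):
        codons = [cds_by_taxon[taxon][3 * k : 3 * k + 3] for k in range(len(prots[taxon]))]
        parts: list[str] = []
        for i in range(L + 1):
            w = ins_width[i]
            if w:
                extra = insertions[taxon].get(i, "")
                start = res_of[taxon][i] if i < L else None
                # insertion residues precede ref column i
                if extra:
                    first = _first_query_index(res_of[taxon], i, len(codons), extra)
                    parts += [codons[first + j] for j in range(len(extra))]
                parts += ["---"] * (w - len(extra))
            if i < L:
                q = res_of[taxon][i]
                parts.append(codons[q] if q is not None else "---")
        out[taxon] = "".join(parts)
    lengths = {len(s) for s in out.values()}
    assert len(lengths) == 1, "merged alignment rows differ in length"
    return out


def _first_query_index(mapping, ref_col, n_res, extra):
    """Query index of the first inserted residue before ref column ref_col."""
    nxt = None
    for k in range(ref_col, len(mapping)):
        if mapping[k] is not None:
            nxt = mapping[k]
            break
    if nxt is not None:
        return nxt - len(extra)
    return n_res - len(extra)


def concatenate_alignments(alignments: list[dict[str, str]], taxa=None):
    """Concatenate family alignments into a supermatrix.

    Returns ``(matrix, offsets)`` where offsets maps the family's list
    index to its column range. Families missing a taxon are skipped.
    """
    if taxa is None:
        taxa = sorted({t for aln in alignments for t in aln})
    taxa = list(taxa)
    parts = {t: [] for t in taxa}
    offsets = {}
    pos = 0
    for k, aln in enumerate(alignments):
        if not set(taxa) <= set(aln):
            continue
        width = len(next(iter(aln.values())))
        offsets[k] = (pos, pos + width)
        pos += width
        for t in taxa:
            parts[t].append(aln[t])
    return {t: "".join(parts[t]) for t in taxa}, offsets


# ---------------------------------------------------------------------------
# column filtering


def filter_columns(
    matrix: dict[str, str],
    max_gap_fraction: float = 0.0,
    min_conservation: float = 0.5,
):
    """Drop unreliable alignment columns.

    A column is removed when its gap fraction exceeds ``max_gap_fraction``
    (default: any gap) or when the frequency of its most common non-gap
    character is below ``min_conservation``. Returns the filtered matrix
    and the kept original column indices.
    """
    if not matrix:
        raise InputError("empty matrix")
    taxa = sorted(matrix)
    arr = np.array([list(matrix[t]) for t in taxa])
    n_taxa, n_cols = arr.shape
    kept = []
    for j in range(n_cols):
        col = arr[:, j]
        gaps = np.sum((col == "-") | (col == "N") | (col == "?"))
        if gaps / n_taxa > max_gap_fraction:
            continue
        residues = col[(col != "-") & (col != "N") & (col != "?")]
        _vals, counts = np.unique(residues, return_counts=True)
        if counts.size and counts.max() / residues.size < min_conservation:
            continue
        kept.append(j)
    if not kept:
        raise InputError("all columns removed by filtering")
    out = {t: "".join(arr[i, kept]) for i, t in enumerate(taxa)}
    return out, kept


# ---------------------------------------------------------------------------
# distances


def _tn93(x: np.ndarray, y: np.ndarray) -> float:
    """Tamura-Nei 1993 closed-form distance; fallback for ill-conditioned
    GTR estimates."""
    n = x.size
    freqs = np.bincount(np.concatenate([x, y]), minlength=4) / (2 * n)
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    diff = x != y
    ts_AG = np.mean(((x == 0) & (y == 2) | (x == 2) & (y == 0)))
    ts_CT = np.mean(((x == 1) & (y == 3) | (x == 3) & (y == 1)))
    tv = np.mean(diff) - ts_AG - ts_CT
    k1 = 2 * gA * gG / gR if gR > 0 else 0
    k2 = 2 * gC * gT / gY if gY > 0 else 0
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    w1 = 1 - ts_AG / k1 - tv / (2 * gR) if k1 > 0 else 0
    w2 = 1 - ts_CT / k2 - tv / (2 * gY) if k2 > 0 else 0
    w3 = 1 - tv / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return SATURATION_CAP
    return float(-k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3))


def gtr_distances(matrix: dict[str, str], cap: float = SATURATION_CAP) -> pd.DataFrame:
    """Pairwise GTR distances from a nucleotide alignment.

    Uses the general time-reversible ML distance
    ``d = -tr(Pi log(Pi^-1 F))`` on the symmetrised divergence matrix F;
    pairs where the matrix logarithm is ill-conditioned fall back to the
    Tamura-Nei closed form, and saturated pairs are set to ``cap`` with a
    warning. The result is symmetric with a zero diagonal.
    """
    taxa = sorted(matrix)
    if len(taxa) < 2:
        raise InputError("need at least two taxa")
    lookup = np.full(256, -1, dtype=np.int8)
    for i, ch in enumerate(_NUC):
        lookup[ord(ch)] = i
    enc = {
        t: lookup[np.frombuffer(matrix[t].upper().encode(), dtype=np.uint8)]
        for t in taxa
    }
    D = np.zeros((len(taxa), len(taxa)))
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            x, y = enc[taxa[i]], enc[taxa[j]]
            ok = (x >= 0) & (y >= 0)
            xi, yi = x[ok].astype(int), y[ok].astype(int)
            if xi.size == 0:
                raise InputError(f"no comparable sites for {taxa[i]},{taxa[j]}")
            F = np.zeros((4, 4))
            np.add.at(F, (xi, yi), 1.0)
            F = (F + F.T) / (2.0 * xi.size)
            pi = F.sum(axis=1)
            d = None
            if np.all(pi > 0):
                M = np.linalg.solve(np.diag(pi), F)
                eigvals = np.linalg.eigvals(M)
                if np.all(np.real(eigvals) > 1e-12) and np.max(np.abs(np.imag(eigvals))) < 1e-8:
                    Lm = logm(M)
                    if np.max(np.abs(np.imag(Lm))) < 1e-8:
                        d = float(-np.trace(np.diag(pi) @ np.real(Lm)))
            if d is None or not np.isfinite(d):
                d = _tn93(xi, yi)
            if d < 0:
                d = 0.0
            if d > cap:
                logger.warning(
                    "saturated pair (%s, %s): distance capped at %g",
                    taxa[i], taxa[j], cap,
                )
                d = cap
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=taxa, columns=taxa)


# ---------------------------------------------------------------------------
# neighbor joining + rooting


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the difference moved
    onto the adjacent branch (scikit-bio's standard handling). The result
    is unrooted.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    arr = distances.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-9):
        raise InputError("distance matrix must be symmetric")
    dm = DistanceMatrix(arr, ids=list(distances.index))
    newick = str(skbio_nj(dm))
    return parse_newick(newick, rooted=False)


def root_with(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root the tree on the branch leading to ``outgroup``.

    ``outgroup`` is a leaf label or an iterable of labels (rooted on the
    branch above their MRCA). The split point on that branch is chosen so
    the mean root-to-leaf distance is equal on both sides, which places the
    root correctly when the tree is clock-like.
    """
    tree = tree.clone(depth=1)
    tree.is_rooted = True
    labels = [outgroup] if isinstance(outgroup, str) else sorted(outgroup)
    have = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not set(labels) <= have:
        raise InputError(f"outgroup {labels} not in tree")
    if len(labels) == 1:
        node = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == labels[0]
        )
    else:
        node = tree.mrca(taxon_labels=labels)
        if node is tree.seed_node:
            # unrooted tree read with the outgroup at the base: use the
            # complement side's parent edge instead
            comp = have - set(labels)
            node = tree.mrca(taxon_labels=sorted(comp))
    length = node.edge.length or 0.0

    def mean_leaf_depth(n):
        depths = []

        def walk(x, d):
            if x.is_leaf():
                depths.append(d)
                return
            for c in x.child_nodes():
                walk(c, d + (c.edge.length or 0.0))

        walk(n, 0.0)
        return float(np.mean(depths))

    m_out = mean_leaf_depth(node)
    tree.reroot_at_edge(node.edge, update_bipartitions=False)
    children = tree.seed_node.child_nodes()
    other = [c for c in children if c is not node]
    m_rest = float(np.mean([mean_leaf_depth(c) for c in other])) if other else 0.0
    # x + m_out = (length - x) + m_rest, clipped into the branch
    x = min(max((length + m_rest - m_out) / 2.0, 0.0), length)
    node.edge.length = x
    for c in other:
        c.edge.length = length - x
    return tree


# ---------------------------------------------------------------------------
# fourfold-degenerate sites


def fourfold_sites(codon_matrix: dict[str, str]) -> dict[str, str]:
    """Third positions of codon columns that are fourfold degenerate in
    every taxon, requiring cross-taxon identity of the first two positions
    (conservative; suitable for neutral-site dating)."""
    taxa = sorted(codon_matrix)
    length = len(codon_matrix[taxa[0]])
    if any(len(codon_matrix[t]) != length for t in taxa) or length % 3:
        raise InputError("codon matrix must be rectangular with length % 3 == 0")
    out = {t: [] for t in taxa}
    for i in range(0, length, 3):
        codons = [codon_matrix[t][i : i + 3].upper() for t in taxa]
        if any("-" in c or set(c) - set(_NUC) for c in codons):
            continue
        prefixes = {c[:2] for c in codons}
        if len(prefixes) == 1 and next(iter(prefixes)) in FOURFOLD_PREFIXES:
            for t, c in zip(taxa, codons):
                out[t].append(c[2])
    return {t: "".join(v) for t, v in out.items()}


# ---------------------------------------------------------------------------
# strict-clock dating


@dataclass
class DatedTree:
    tree: dendropy.Tree
    ages: dict[frozenset, float]  # clade (leaf-label set) -> age in MY
    rate: float  # substitutions/site/MY
    calibrations: dict = field(default_factory=dict)

    def age_of(self, taxa) -> float:
        return self.ages[frozenset(taxa)]

    def to_newick(self) -> str:
        """Newick with node ages (MY) as ``[&age=..]`` comments."""

        def render(node):
            if node.is_leaf():
                label = node.taxon.label
            else:
                inner = ",".join(render(c) for c in node.child_nodes())
                label = f"({inner})[&age={node.age:.4f}]"
            if node.edge.length is not None and node.parent_node is not None:
                return f"{label}:{node.edge.length:.8f}"
            return label

        return render(self.tree.seed_node) + ";"


def strict_clock_dating(
    tree: dendropy.Tree, calibrations: dict, rate_bounds=(1e-9, 10.0)
) -> DatedTree:
    """Least-squares strict-clock dating of a rooted tree.

    ``calibrations`` maps a clade (an iterable of leaf labels, matched
    against the MRCA) to an ``(age_min, age_max)`` interval in MY. Node
    ages and a single substitution rate minimise the squared differences
    between ``rate * (root_age - node_age)`` and the observed root-to-node
    path lengths, subject to parent-older-than-child ordering and the
    calibration intervals (hard constraints). Deterministic.
    """
    if not calibrations:
        raise ConfigurationError("at least one calibration is required")
    tree = tree.clone(depth=1)
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): k for k, n in enumerate(internal)}
    n_int = len(internal)

    # observed root-to-node path lengths
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    clade_of = {
        id(n): frozenset(lf.taxon.label for lf in n.leaf_iter()) for n in internal
    }
    calib_by_node: dict[int, tuple[float, float]] = {}
    for taxa, (lo, hi) in calibrations.items():
        target = frozenset(taxa)
        mrca = None
        for n in internal:
            cl = clade_of[id(n)]
            if target <= cl and (mrca is None or cl < clade_of[id(mrca)]):
                mrca = n
        if mrca is None:
            raise ConfigurationError(f"no MRCA for calibration {sorted(target)}")
        if lo > hi:
            raise ConfigurationError("calibration interval reversed")
        calib_by_node[index[id(mrca)]] = (float(lo), float(hi))

    # feasibility: a calibrated descendant cannot be required older than a
    # calibrated ancestor allows
    for node in internal:
        k = index[id(node)]
        if k not in calib_by_node:
            continue
        anc = node.parent_node
        while anc is not None:
            ka = index.get(id(anc))
            if ka in calib_by_node:
                if calib_by_node[k][0] > calib_by_node[ka][1]:
                    raise ConfigurationError(
                        "infeasible calibrations: child interval above parent's"
                    )
            anc = anc.parent_node

    # initial ages from clock heights scaled through the calibrations
    height: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            height[id(node)] = 0.0
        else:
            height[id(node)] = float(
                np.mean(
                    [
                        height[id(c)] + (c.edge.length or 0.0)
                        for c in node.child_nodes()
                    ]
                )
            )
    ratios = [
        height[id(internal[k])] / np.mean(interval)
        for k, interval in calib_by_node.items()
        if np.mean(interval) > 0
    ]
    r0 = max(float(np.mean(ratios)), rate_bounds[0]) if ratios else 1e-3
    ages0 = np.array([max(height[id(n)] / r0, 1e-6) for n in internal])
    for k, (lo, hi) in calib_by_node.items():
        ages0[k] = float(np.clip(ages0[k], lo, hi))

    nodes_all = list(tree.preorder_node_iter())
    d_obs = np.array([depth[id(n)] for n in nodes_all])
    which_int = np.array(
        [index[id(n)] if not n.is_leaf() else -1 for n in nodes_all]
    )
    root_k = index[id(tree.seed_node)]

    # optimise in scaled units (ages / age_scale, rate / rate_scale) so the
    # quadratic objective is well-conditioned regardless of the time scale
    age_scale = max(float(ages0.max()), 1.0)
    rate_scale = max(r0, rate_bounds[0])
    obj_scale = max(float(np.sum(d_obs**2)), 1e-12)

    def objective(y):
        ages, r = y[:n_int] * age_scale, y[n_int] * rate_scale
        node_ages = np.where(which_int >= 0, ages[np.maximum(which_int, 0)], 0.0)
        expected = r * (ages[root_k] - node_ages)
        return float(np.sum((expected - d_obs) ** 2)) / obj_scale

    constraints = []
    for node in internal:
        k = index[id(node)]
        for child in node.child_nodes():
            if child.is_leaf():
                constraints.append(
                    {"type": "ineq", "fun": (lambda y, k=k: y[k])}
                )
            else:
                kc = index[id(child)]
                constraints.append(
                    {"type": "ineq", "fun": (lambda y, k=k, kc=kc: y[k] - y[kc])}
                )
    bounds = []
    for k in range(n_int):
        lo, hi = calib_by_node.get(k, (0.0, None))
        bounds.append(
            (lo / age_scale, hi / age_scale if hi is not None else None)
        )
    bounds.append((rate_bounds[0] / rate_scale, rate_bounds[1] / rate_scale))

    y0 = np.concatenate([ages0 / age_scale, [r0 / rate_scale]])
    res = minimize(
        objective,
        y0,
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": 1000, "ftol": 1e-16},
    )
    ages = res.x[:n_int] * age_scale
    rate = float(res.x[n_int] * rate_scale)
    out_ages = {clade_of[id(n)]: float(ages[index[id(n)]]) for n in internal}
    for leaf in tree.leaf_node_iter():
        out_ages[frozenset([leaf.taxon.label])] = 0.0
    for node in internal:
        node.age = float(ages[index[id(node)]])
    for leaf in tree.leaf_node_iter():
        leaf.age = 0.0
    return DatedTree(tree, out_ages, rate, dict(calibrations))
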