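"""All-vs-all protein similarity and ortholog-family clustering.

The similarity stage mirrors an all-by-all BLASTP search: candidate pairs
are found by shared-word seeding, scored by Smith-Waterman local alignment
(BLOSUM62, affine gaps 11/1), and given an e-value from Karlin-Altschul
statistics with the fixed gapped-BLOSUM62 parameters. Edges better than the
e-value cutoff (default 1e-5) form an undirected similarity graph whose
weights are -log10(e-value), capped at 300.

Families are then obtained by Markov clustering (MCL): alternate matrix
expansion (squaring) and inflation (entry-wise powering with column
renormalisation) until the column-stochastic flow matrix is idempotent;
the connected structure of the limit matrix defines the clusters. Genes
ending up in no cluster of size >= 2 are reported as unclustered
("variety-specific") genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import InputError

# gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1
KA_LAMBDA = 0.267
KA_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def sw_score(a: str, b: str) -> float:
    """Smith-Waterman score of two proteins under BLOSUM62, 11/1 gaps."""
    return float(_aligner("local").score(a.rstrip("*"), b.rstrip("*")))


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S) with the fixed BLOSUM62 parameters."""
    bits = (KA_LAMBDA * score - np.log(KA_K)) / np.log(2.0)
    return float(m * n * 2.0 ** (-bits))


def _seed_candidates(proteins: dict[str, str], k: int = 4, min_shared: int = 2):
    """Pairs of sequences sharing >= min_shared length-k words.

    This is the usual word-seeding heuristic of database search tools: it
    cheaply discards the quadratically many unrelated pairs so that the
    exact local alignment only runs on plausible homologs.
    """
    index: dict[str, list[str]] = {}
    for name in sorted(proteins):
        seq = proteins[name].rstrip("*")
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(name)
    counts: dict[tuple[str, str], int] = {}
    for word, names in index.items():
        uniq = sorted(set(names))
        if len(uniq) < 2 or len(uniq) > 50:  # skip low-complexity hub words
            continue
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                key = (uniq[i], uniq[j])
                counts[key] = counts.get(key, 0) + 1
    return sorted(p for p, c in counts.items() if c >= min_shared)


def pairwise_similarity(
    proteins: dict[str, str],
    evalue_cutoff: float = 1e-5,
    seed_word: int = 4,
    min_shared_words: int = 2,
) -> pd.DataFrame:
    """All-vs-all protein similarity edges above an e-value cutoff.

    Returns a DataFrame with columns qseqid, sseqid, bitscore, evalue (one
    row per unordered pair, qseqid < sseqid). Self-hits are never reported.
    """
    for name, seq in proteins.items():
        if not set(seq.rstrip("*")) <= _AA:
            bad = sorted(set(seq.rstrip("*")) - _AA)
            raise InputError(f"{name}: invalid residues {bad}")
    total_residues = sum(len(s.rstrip("*")) for s in proteins.values())
    aligner = _aligner("local")
    rows = []
    for a, b in _seed_candidates(proteins, k=seed_word, min_shared=min_shared_words):
        score = float(aligner.score(proteins[a].rstrip("*"), proteins[b].rstrip("*")))
        m = len(proteins[a].rstrip("*"))
        evalue = karlin_altschul_evalue(score, m, total_residues)
        if evalue <= evalue_cutoff:
            bits = (KA_LAMBDA * score - np.log(KA_K)) / np.log(2.0)
            rows.append((a, b, bits, evalue))
    return pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue"])


def read_edges_outfmt6(path) -> pd.DataFrame:
    """Ingest a precomputed outfmt-6 table as similarity edges verbatim."""
    from .scaffolding import OUTFMT6_COLUMNS

    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return df[["qseqid", "sseqid", "bitscore", "evalue"]].copy()


@dataclass
class SimilarityGraph:
    """Undirected gene-similarity graph with per-gene species labels."""

    nodes: dict[str, str]  # gene -> variety/species
    edges: pd.DataFrame  # qseqid, sseqid, bitscore, evalue

    @classmethod
    def build(cls, edges: pd.DataFrame, species_of: dict[str, str]):
        e = edges[edges["qseqid"] != edges["sseqid"]].copy()
        return cls(dict(species_of), e.reset_index(drop=True))

    def edge_weights(self, cap: float = 300.0) -> pd.DataFrame:
        """Symmetric -log10(evalue) weights, capped; averaged over duplicate
        (a,b)/(b,a) rows."""
        e = self.edges.copy()
        with np.errstate(divide="ignore"):
            w = -np.log10(e["evalue"].to_numpy(dtype=float))
        e["weight"] = np.minimum(np.where(np.isfinite(w), w, cap), cap)
        a = np.minimum(e["qseqid"], e["sseqid"])
        b = np.maximum(e["qseqid"], e["sseqid"])
        sym = (
            pd.DataFrame({"a": a, "b": b, "weight": e["weight"]})
            .groupby(["a", "b"], as_index=False)["weight"]
            .mean()
        )
        return sym


@dataclass
class OrthoCluster:
    cluster_id: str
    members: tuple[str, ...]
    varieties_present: tuple[str, ...]


def _mcl_component(W: np.ndarray, inflation: float, prune: float, tol: float,
                   max_iter: int):
    """Run MCL on one dense component matrix; returns (clusters, converged)
    as lists of local indices."""
    n = W.shape[0]
    M = W.copy()
    # self-loops at the column maximum, the canonical convergence device
    np.fill_diagonal(M, M.max(axis=0))
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        M2 = M @ M  # expansion
        np.power(M2, inflation, out=M2)  # inflation
        M2[M2 < prune] = 0.0
        colsum = M2.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M2 /= colsum
        if np.abs(M2 - M).max() < tol:
            M = M2
            converged = True
            break
        M = M2
    # clusters = connected components of the limit matrix's support
    support = sparse.csr_matrix((M + M.T) > prune)
    _, labels = connected_components(support, directed=False)
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    return list(clusters.values()), converged


def mcl_cluster(
    graph: SimilarityGraph,
    inflation: float = 1.5,
    prune: float = 1e-6,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Markov clustering of the similarity graph.

    Returns ``(clusters, unclustered, warnings)``: clusters of size >= 2 as
    :class:`OrthoCluster` (deterministically ordered and numbered),
    unclustered singleton genes sorted by id, and a list of component ids
    that hit the iteration cap without converging.
    """
    genes = sorted(graph.nodes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    W = graph.edge_weights()
    rows = W["a"].map(gene_idx).to_numpy(dtype=int) if len(W) else np.array([], int)
    cols = W["b"].map(gene_idx).to_numpy(dtype=int) if len(W) else np.array([], int)
    vals = W["weight"].to_numpy(dtype=float) if len(W) else np.array([])
    A = sparse.coo_matrix(
        (np.concatenate([vals, vals]), (np.concatenate([rows, cols]),
                                        np.concatenate([cols, rows]))),
        shape=(len(genes), len(genes)),
    ).tocsr()
    n_comp, comp = connected_components(A, directed=False)

    member_sets: list[list[str]] = []
    unclustered: list[str] = []
    warnings: list[int] = []
    for c in range(n_comp):
        idx = np.where(comp == c)[0]
        if len(idx) == 1:
            unclustered.append(genes[idx[0]])
            continue
        sub = A[np.ix_(idx, idx)].toarray()
        local_clusters, ok = _mcl_component(sub, inflation, prune, tol, max_iter)
        if not ok:
            warnings.append(c)
        for loc in local_clusters:
            names = sorted(genes[idx[i]] for i in loc)
            if len(names) == 1:
                unclustered.append(names[0])
            else:
                member_sets.append(names)

    member_sets.sort(key=lambda ms: ms[0])
    clusters = []
    width = max(5, len(str(len(member_sets))))
    for k, names in enumerate(member_sets):
        varieties = tuple(sorted({graph.nodes[g] for g in names}))
        clusters.append(
            OrthoCluster(f"ORTHO{k + 1:0{width}d}", tuple(names), varieties)
        )
    return clusters, sorted(unclustered), warnings


def reciprocal_best_hits(
    graph: SimilarityGraph, species_a: str, species_b: str
) -> list[tuple[str, str]]:
    """Mutual top-bitscore pairs between two species; ties broken by id."""
    species = set(graph.nodes.values())
    for sp in (species_a, species_b):
        if sp not in species:
            raise InputError(f"species {sp!r} absent from graph")
    e = graph.edges
    both = pd.concat(
        [
            e[["qseqid", "sseqid", "bitscore"]],
            e.rename(columns={"qseqid": "sseqid", "sseqid": "qseqid"})[
                ["qseqid", "sseqid", "bitscore"]
            ],
        ]
    )

    def best_of(src: str, dst: str) -> dict[str, str]:
        sub = both[
            both["qseqid"].map(graph.nodes).eq(src)
            & both["sseqid"].map(graph.nodes).eq(dst)
        ]
        best: dict[str, tuple[float, str]] = {}
        for q, s, score in sub.itertuples(index=False):
            cur = best.get(q)
            if cur is None or score > cur[0] or (score == cur[0] and s < cur[1]):
                best[q] = (score, s)
        return {q: s for q, (sc, s) in best.items()}

    a_best = best_of(species_a, species_b)
    b_best = best_of(species_b, species_a)
    pairs = [
        (a, b)
        for a, b in sorted(a_best.items())
        if b_best.get(b) == a
    ]
    return pairs


def single_copy_families(clusters, gene_species: dict[str, str], required_taxa):
    """Clusters with exactly one member per required taxon and none extra."""
    required = set(required_taxa)
    out = []
    for cl in clusters:
        counts: dict[str, int] = {}
        for g in cl.members:
            counts[gene_species[g]] = counts.get(gene_species[g], 0) + 1
        if set(counts) == required and all(v == 1 for v in counts.values()):
            out.append(cl)
    return out


def write_clusters(clusters, path):
    """OrthoMCL-style text output: ``cluster_id: geneA geneB ...``"""
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f"{cl.cluster_id}: " + " ".join(cl.members) + "\n")


def read_clusters(path) -> list[OrthoCluster]:
    clusters = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cid, members = line.split(":", 1)
            clusters.append(
                OrthoCluster(cid.strip(), tuple(members.split()), ())
            )
    return clusters
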