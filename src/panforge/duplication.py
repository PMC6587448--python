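"""Duplication-origin labelling: tandem arrays and collinear blocks.

Tandem-duplicated (TD) genes are homologous genes lying adjacent on a
chromosome (within a small gene-index gap, default strictly consecutive),
grouped by single linkage into maximal arrays. WGD-type genes are those
anchored in collinear (syntenic) blocks against an outgroup genome: runs of
homologous gene pairs whose order is conserved on both genomes, chained by
dynamic programming with a per-step gap limit (default 1 intervening gene)
and a minimum block size (default 15 anchors). A gene in both signals is
labelled TD (the more specific signal); everything else is "other".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError


def self_homolog_pairs(proteins: dict[str, str], evalue_cutoff: float = 1e-20):
    """Within-genome homologous pairs above a stringent e-value cutoff.

    Runs the package's all-vs-all similarity search and keeps symmetric,
    self-free pairs. Returns a DataFrame (gene_a, gene_b, bitscore, evalue)
    with one row per unordered pair.
    """
    from .orthology import pairwise_similarity

    edges = pairwise_similarity(proteins, evalue_cutoff=evalue_cutoff)
    edges = edges[edges["qseqid"] != edges["sseqid"]].copy()
    return edges.rename(columns={"qseqid": "gene_a", "sseqid": "gene_b"})


@dataclass(frozen=True)
class TandemArray:
    array_id: str
    chromosome: str
    members: tuple[str, ...]  # in gene order


def detect_tandem_arrays(
    pairs, gene_order: dict[str, list[str]], max_gap: int = 1
) -> list[TandemArray]:
    """Maximal single-linkage runs of adjacent homologs on one chromosome.

    ``pairs`` is any iterable of (gene_a, gene_b) or a DataFrame with those
    columns; two homologs are linked when fewer than ``max_gap`` genes lie
    between them. Arrays have >= 2 members and are disjoint.
    """
    if isinstance(pairs, pd.DataFrame):
        pair_list = list(zip(pairs["gene_a"], pairs["gene_b"]))
    else:
        pair_list = [(a, b) for a, b, *_ in (tuple(p) for p in pairs)]
    position: dict[str, tuple[str, int]] = {}
    for chrom, genes in gene_order.items():
        for i, g in enumerate(genes):
            position[g] = (chrom, i)
    missing = sorted(
        {g for p in pair_list for g in p if g not in position}
    )
    if missing:
        raise InputError(f"genes absent from gene_order: {missing}")

    parent: dict[str, str] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for a, b in pair_list:
        ca, ia = position[a]
        cb, ib = position[b]
        if ca == cb and abs(ia - ib) - 1 < max_gap:
            union(a, b)

    groups: dict[str, list[str]] = {}
    for g in parent:
        groups.setdefault(find(g), []).append(g)
    arrays = []
    roots = sorted(groups, key=lambda r: (position[r][0], position[r][1]))
    for k, root in enumerate(roots):
        members = sorted(set(groups[root]) | {root}, key=lambda g: position[g][1])
        if len(members) < 2:
            continue
        arrays.append(
            TandemArray(f"TD{k + 1:05d}", position[root][0], tuple(members))
        )
    return arrays


@dataclass(frozen=True)
class CollinearBlock:
    block_id: str
    anchors: tuple[tuple[str, str], ...]  # (query gene, subject gene) in order
    orientation: str  # + (parallel) or - (inverted)


@dataclass(frozen=True)
class Anchor:
    """A homologous gene pair with gene-order indices on both genomes."""

    query_gene: str
    subject_gene: str
    query_index: int
    subject_index: int


def _chain(anchors: list[Anchor], max_gap: int, sign: int):
    """Best chain per anchor by DP; subject index moves with ``sign``."""
    order = sorted(
        range(len(anchors)),
        key=lambda i: (anchors[i].query_index, sign * anchors[i].subject_index),
    )
    score = [1] * len(anchors)
    back = [-1] * len(anchors)
    for oi, i in enumerate(order):
        ai = anchors[i]
        for j in order[:oi]:
            aj = anchors[j]
            dq = ai.query_index - aj.query_index
            ds = sign * (ai.subject_index - aj.subject_index)
            if 1 <= dq <= max_gap + 1 and 1 <= ds <= max_gap + 1:
                if score[j] + 1 > score[i]:
                    score[i] = score[j] + 1
                    back[i] = j
    return score, back


def collinear_blocks(
    anchors, min_block: int = 15, max_gap: int = 1
) -> list[CollinearBlock]:
    """Chain ordered homolog pairs into collinear blocks.

    ``anchors`` is an iterable of :class:`Anchor` (or tuples
    (query_gene, subject_gene, query_index, subject_index)). A chain
    extends when the query index increases and the subject index increases
    (parallel) or decreases (inverted), each by at most ``max_gap + 1``.
    Maximal chains with >= ``min_block`` anchors are reported, best chain
    first; each anchor belongs to at most one block.
    """
    pool = [
        a if isinstance(a, Anchor) else Anchor(*a)
        for a in anchors
    ]
    blocks: list[CollinearBlock] = []
    serial = 0
    while True:
        best_chain, best_sign = None, None
        for sign in (1, -1):
            score, back = _chain(pool, max_gap, sign)
            if not score:
                continue
            top = max(range(len(pool)), key=lambda i: (score[i], -pool[i].query_index))
            if score[top] >= min_block:
                chain = []
                i = top
                while i != -1:
                    chain.append(pool[i])
                    i = back[i]
                chain.reverse()
                if best_chain is None or len(chain) > len(best_chain):
                    best_chain, best_sign = chain, sign
        if best_chain is None:
            break
        serial += 1
        blocks.append(
            CollinearBlock(
                f"BLK{serial:04d}",
                tuple((a.query_gene, a.subject_gene) for a in best_chain),
                "+" if best_sign == 1 else "-",
            )
        )
        used = {(a.query_gene, a.subject_gene) for a in best_chain}
        pool = [a for a in pool if (a.query_gene, a.subject_gene) not in used]
    return blocks


def anchors_from_pairs(pairs, query_order: dict[str, list[str]],
                       subject_order: dict[str, list[str]]):
    """Build per-chromosome-pair anchor lists from homolog pairs and gene
    orders; indices are positions within each chromosome's gene list."""
    qpos = {
        g: (c, i) for c, genes in query_order.items() for i, g in enumerate(genes)
    }
    spos = {
        g: (c, i) for c, genes in subject_order.items() for i, g in enumerate(genes)
    }
    if isinstance(pairs, pd.DataFrame):
        pair_list = list(zip(pairs["gene_a"], pairs["gene_b"]))
    else:
        pair_list = [(a, b) for a, b, *_ in (tuple(p) for p in pairs)]
    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for a, b in pair_list:
        if a not in qpos or b not in spos:
            continue
        (qc, qi), (sc, si) = qpos[a], spos[b]
        grouped.setdefault((qc, sc), []).append(Anchor(a, b, qi, si))
    return grouped


def classify_duplication_origin(
    genes, arrays, blocks_vs_outgroup
) -> dict[str, str]:
    """Per-gene origin label: TD beats WGD beats other.

    A gene is WGD-type when it participates in any collinear-block anchor
    (for a self-comparison both anchor sides are genes of this genome, so
    both are counted; against a true outgroup only the query side ever
    matches); TD-type when it is a member of any tandem array; TD takes
    precedence when both apply.
    """
    wgd = {g for blk in blocks_vs_outgroup for pair in blk.anchors for g in pair}
    td = {g for arr in arrays for g in arr.members}
    out = {}
    for g in genes:
        if g in td:
            out[g] = "TD"
        elif g in wgd:
            out[g] = "WGD"
        else:
            out[g] = "other"
    return out


def summarize_by_class(
    origin_labels: dict[str, str],
    core_genes: dict[str, set],
    dispensable_genes: dict[str, set],
) -> pd.DataFrame:
    """Per-variety totals and WGD/TD counts + percentages for the core and
    dispensable gene sets (percentages to 2 dp of the category total)."""
    rows = []
    for variety in sorted(set(core_genes) | set(dispensable_genes)):
        for category, members in (
            ("core", core_genes.get(variety, set())),
            ("dispensable", dispensable_genes.get(variety, set())),
        ):
            total = len(members)
            n_wgd = sum(1 for g in members if origin_labels.get(g) == "WGD")
            n_td = sum(1 for g in members if origin_labels.get(g) == "TD")
            rows.append(
                {
                    "variety": variety,
                    "category": category,
                    "total": total,
                    "wgd_count": n_wgd,
                    "wgd_pct": round(100.0 * n_wgd / total, 2) if total else 0.0,
                    "td_count": n_td,
                    "td_pct": round(100.0 * n_td / total, 2) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
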