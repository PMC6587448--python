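"""Core/dispensable classification of gene families and genome regions.

A gene family (ortholog cluster) is *core* when every variety of the panel
contributes at least one member, *dispensable* otherwise; unclustered genes
are the variety-specific part of the dispensable gene set and are kept out
of the cluster percentage denominator. Genome regions follow the same
logic on alignment blocks: blocks shared by the full panel form the core
genome, everything else — subset-shared blocks plus each variety's
unaligned sequence — is dispensable, and core + dispensable is the
pan-genome, with every block counted once (non-redundant coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError


def membership_matrix(clusters, gene_variety: dict[str, str], panel) -> pd.DataFrame:
    """Cluster x variety gene-count matrix from clusters and gene labels."""
    panel = list(panel)
    rows = {}
    for cl in clusters:
        counts = {v: 0 for v in panel}
        for g in cl.members:
            v = gene_variety[g]
            if v in counts:
                counts[v] += 1
        rows[cl.cluster_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index", columns=panel)
    return df.fillna(0).astype(int)


def classify_clusters(matrix: pd.DataFrame, panel) -> dict[str, str]:
    """core iff every panel variety has count > 0; dispensable otherwise."""
    panel = list(panel)
    if not panel:
        raise InputError("panel must be non-empty")
    missing = set(panel) - set(matrix.columns)
    if missing:
        raise InputError(f"panel varieties absent from matrix: {sorted(missing)}")
    core_mask = (matrix[panel] > 0).all(axis=1)
    return {
        cid: ("core" if is_core else "dispensable")
        for cid, is_core in core_mask.items()
    }


@dataclass
class PanGenomeSummary:
    n_clusters_total: int
    n_core: int
    n_dispensable_clusters: int
    n_variety_specific_genes: int
    pct_core: float
    pct_dispensable: float
    per_variety_core_genes: dict[str, int] = field(default_factory=dict)
    per_variety_dispensable_genes: dict[str, int] = field(default_factory=dict)
    core_genome_bp: int | None = None
    dispensable_genome_bp: int | None = None
    pan_genome_bp: int | None = None

    def as_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def pangenome_composition(
    labels: dict[str, str],
    matrix: pd.DataFrame | None = None,
    unclustered_by_variety: dict[str, int] | None = None,
) -> PanGenomeSummary:
    """Composition summary of a classified cluster set.

    Percentages are computed over clusters only; variety-specific
    (unclustered) genes are reported separately. When the membership
    ``matrix`` is given, per-variety core and dispensable gene counts are
    included; a variety's dispensable count includes its unclustered genes.
    """
    n_total = len(labels)
    n_core = sum(1 for v in labels.values() if v == "core")
    n_disp = n_total - n_core
    pct_core = 100.0 * n_core / n_total if n_total else 0.0
    pct_disp = 100.0 * n_disp / n_total if n_total else 0.0
    unclustered_by_variety = unclustered_by_variety or {}
    summary = PanGenomeSummary(
        n_clusters_total=n_total,
        n_core=n_core,
        n_dispensable_clusters=n_disp,
        n_variety_specific_genes=sum(unclustered_by_variety.values()),
        pct_core=round(pct_core, 2),
        pct_dispensable=round(pct_disp, 2),
    )
    if matrix is not None:
        lab = pd.Series(labels).reindex(matrix.index)
        core_counts = matrix[lab == "core"].sum(axis=0)
        disp_counts = matrix[lab == "dispensable"].sum(axis=0)
        summary.per_variety_core_genes = {
            v: int(core_counts.get(v, 0)) for v in matrix.columns
        }
        summary.per_variety_dispensable_genes = {
            v: int(disp_counts.get(v, 0)) + int(unclustered_by_variety.get(v, 0))
            for v in matrix.columns
        }
    return summary


@dataclass(frozen=True)
class RegionBlock:
    """A multi-genome alignment block: one span per variety that shares it."""

    block_id: str
    spans: dict  # variety -> (chromosome, start, end), 0-based half-open

    def __post_init__(self):
        for v, (_c, s, e) in self.spans.items():
            if s >= e:
                raise InputError(f"block {self.block_id}: empty span for {v}")

    @property
    def present_in(self) -> frozenset:
        return frozenset(self.spans)

    @property
    def length(self) -> int:
        """Representative (non-redundant) length: the longest member span."""
        return max(e - s for _c, s, e in self.spans.values())


def read_blocks_tsv(path) -> list[RegionBlock]:
    """Simple block dialect: block_id, variety, chromosome, start, end (TSV,
    0-based half-open), one row per variety sharing the block."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["block_id", "variety", "chromosome", "start", "end"],
        comment="#",
    )
    blocks = []
    for bid, grp in df.groupby("block_id", sort=True):
        spans = {
            r.variety: (r.chromosome, int(r.start), int(r.end))
            for r in grp.itertuples(index=False)
        }
        blocks.append(RegionBlock(str(bid), spans))
    return blocks


def read_blocks_maf(path) -> list[RegionBlock]:
    """Read multi-genome alignment blocks from a MAF file.

    Sequence names must follow the usual ``variety.chromosome`` MAF
    convention; minus-strand spans are converted to forward-strand
    coordinates using srcSize. Each alignment becomes one RegionBlock.
    """
    from Bio import AlignIO

    blocks = []
    for k, msa in enumerate(AlignIO.parse(str(path), "maf")):
        spans = {}
        for rec in msa:
            variety, _, chrom = rec.id.partition(".")
            start = int(rec.annotations["start"])
            size = int(rec.annotations["size"])
            if rec.annotations.get("strand", 1) == -1:
                src = int(rec.annotations["srcSize"])
                start = src - start - size
            spans[variety] = (chrom or rec.id, start, start + size)
        blocks.append(RegionBlock(f"maf{k + 1:05d}", spans))
    return blocks


def _merged_aligned_length(spans_per_chrom: dict) -> int:
    """Union length of per-chromosome interval lists."""
    from .refine import interval_union

    total = 0
    for intervals in spans_per_chrom.values():
        total += sum(e - s for s, e in interval_union(intervals))
    return total


def partition_genome_regions(
    blocks, genome_lengths: dict[str, int], panel
) -> dict[str, int]:
    """Split the pan-genome into core and dispensable base pairs.

    core_bp sums the representative length of blocks shared by the whole
    panel; dispensable_bp sums subset-shared blocks the same way plus each
    variety's unaligned sequence (genome length minus the merged aligned
    length). pan_bp = core_bp + dispensable_bp.
    """
    panel = frozenset(panel)
    if not panel:
        raise InputError("panel must be non-empty")
    core_bp = 0
    disp_bp = 0
    aligned: dict[str, dict] = {v: {} for v in genome_lengths}
    for blk in blocks:
        if not blk.present_in <= set(genome_lengths):
            raise InputError(f"block {blk.block_id} references unknown variety")
        for v, (chrom, s, e) in blk.spans.items():
            if e > genome_lengths[v]:
                raise InputError(
                    f"block {blk.block_id} exceeds genome length of {v}"
                )
            aligned[v].setdefault(chrom, []).append((s, e))
        if blk.present_in == panel:
            core_bp += blk.length
        else:
            disp_bp += blk.length
    for v, length in sorted(genome_lengths.items()):
        disp_bp += length - _merged_aligned_length(aligned[v])
    return {"core_bp": core_bp, "dispensable_bp": disp_bp, "pan_bp": core_bp + disp_bp}


def group_unique_sets(
    matrix: pd.DataFrame,
    unclustered_by_variety: dict[str, list | int],
    group_a,
    group_b,
) -> dict:
    """Families and variety-specific genes unique to each variety group.

    A family is unique to group A iff present in at least one member of A
    and in no member of B (other columns are ignored). Variety-specific
    gene counts sum the unclustered genes of the group's members.
    """
    A, B = set(group_a), set(group_b)
    if A & B:
        raise InputError("groups must be disjoint")
    if not (A | B) <= set(matrix.columns):
        raise InputError("groups must be subsets of the matrix columns")

    in_a = (matrix[sorted(A)] > 0).any(axis=1)
    in_b = (matrix[sorted(B)] > 0).any(axis=1)

    def count_specific(group):
        total = 0
        for v in sorted(group):
            val = unclustered_by_variety.get(v, 0)
            total += len(val) if hasattr(val, "__len__") else int(val)
        return total

    return {
        "families_unique_to_a": sorted(matrix.index[in_a & ~in_b]),
        "families_unique_to_b": sorted(matrix.index[in_b & ~in_a]),
        "specific_genes_in_a": count_specific(A),
        "specific_genes_in_b": count_specific(B),
    }
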