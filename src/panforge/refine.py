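"""Gene-set refinement: evidence-support filtering and fragment merging.

Candidate gene models from ab initio predictors are kept when at least half
of their coding bases are covered by protein-homology and/or transcript
evidence; models below that threshold survive only when both ab initio
sources agree on them. Adjacent same-strand models whose evidence is one and
the same single homolog are treated as fragments of a single gene and merged
into one model spanning both (the merged CDS is the union of the two
interval sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import InputError

logger = logging.getLogger(__name__)

AB_INITIO_SOURCES = {"augustus", "fgenesh"}


@dataclass(frozen=True)
class Evidence:
    """An evidence interval in CDS coordinates (0-based half-open)."""

    kind: str  # protein | transcript
    start: int
    end: int
    homolog_id: str | None = None
    hom_start: int | None = None
    hom_end: int | None = None


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    variety: str
    chromosome: str
    cds_intervals: tuple[tuple[int, int], ...]  # genomic, 0-based half-open
    strand: str = "+"
    sources: frozenset = frozenset({"augustus"})
    evidence: tuple[Evidence, ...] = ()

    def __post_init__(self):
        ivs = sorted(self.cds_intervals)
        if ivs != list(self.cds_intervals):
            object.__setattr__(self, "cds_intervals", tuple(ivs))
        prev_end = None
        for s, e in self.cds_intervals:
            if s >= e:
                raise InputError(f"{self.gene_id}: empty CDS interval")
            if prev_end is not None and s < prev_end:
                raise InputError(f"{self.gene_id}: overlapping CDS intervals")
            prev_end = e
        if not self.sources:
            raise InputError(f"{self.gene_id}: sources must be non-empty")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


def interval_union(intervals) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals as a sorted tuple of disjoint intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def _union_length(intervals) -> int:
    return sum(e - s for s, e in interval_union(intervals))


def evidence_support_fraction(gene: CandidateGene) -> float:
    """Fraction of CDS bases covered by the union of all evidence intervals.

    Evidence is given in CDS coordinates; intervals reaching outside the
    CDS length are clipped with a logged warning.
    """
    L = gene.cds_length
    if L <= 0:
        raise InputError(f"{gene.gene_id}: CDS length must be positive")
    clipped = []
    for ev in gene.evidence:
        s, e = ev.start, ev.end
        if s < 0 or e > L:
            logger.warning(
                "%s: evidence interval [%d,%d) clipped to CDS length %d",
                gene.gene_id,
                s,
                e,
                L,
            )
            s, e = max(s, 0), min(e, L)
        if s < e:
            clipped.append((s, e))
    return _union_length(clipped) / L


@dataclass
class RefinementResult:
    retained: list[CandidateGene]
    removed: list[tuple[CandidateGene, str]]
    merged_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    def report(self):
        import pandas as pd

        rows = [(g.gene_id, "retained", "") for g in self.retained]
        rows += [(g.gene_id, "removed", why) for g, why in self.removed]
        rows += [(m, "merged", f"{a}+{b}") for a, b, m in self.merged_pairs]
        return pd.DataFrame(rows, columns=["gene_id", "status", "detail"])


def _single_shared_homolog(a: CandidateGene, b: CandidateGene) -> bool:
    """True when a and b look like two fragments of one gene: consecutive
    (checked by the caller), same strand, evidence from exactly one shared
    homolog, with non-overlapping aligned portions on that homolog when the
    homolog coordinates are known."""
    if a.strand != b.strand:
        return False
    hom_a = {ev.homolog_id for ev in a.evidence if ev.homolog_id}
    hom_b = {ev.homolog_id for ev in b.evidence if ev.homolog_id}
    if len(hom_a) != 1 or hom_a != hom_b:
        return False
    spans_a = [
        (ev.hom_start, ev.hom_end)
        for ev in a.evidence
        if ev.hom_start is not None and ev.hom_end is not None
    ]
    spans_b = [
        (ev.hom_start, ev.hom_end)
        for ev in b.evidence
        if ev.hom_start is not None and ev.hom_end is not None
    ]
    for sa, ea in spans_a:
        for sb, eb in spans_b:
            if sa < eb and sb < ea:  # aligned portions overlap -> paralogs
                return False
    return True


def refine_gene_set(genes: list[CandidateGene]) -> RefinementResult:
    """Apply the retention, removal and fragment-merging rules to one
    variety's candidate genes.

    Retained: support fraction >= 0.5, or prediction by both ab initio
    sources. Removed: below threshold and predicted by a single source.
    Among the retained genes, adjacent same-strand pairs whose evidence is
    one shared single homolog are merged into one model (CDS = union of
    both interval sets, sources = union).
    """
    varieties = {g.variety for g in genes}
    if len(varieties) > 1:
        raise InputError(f"genes from several varieties: {sorted(varieties)}")

    kept, removed = [], []
    for g in genes:
        frac = evidence_support_fraction(g)
        if frac >= 0.5:
            kept.append(g)
        elif AB_INITIO_SOURCES <= set(g.sources):
            kept.append(g)
        else:
            removed.append(
                (g, f"support {frac:.2f} < 0.5; ab initio from one source")
            )

    # fragment merging among retained genes, per chromosome in gene order;
    # iterated to a fixpoint so chains of fragments collapse into one model
    # and refinement stays idempotent
    merged_pairs = []
    current = kept
    while True:
        by_chrom: dict[str, list[CandidateGene]] = {}
        for g in current:
            by_chrom.setdefault(g.chromosome, []).append(g)
        retained: list[CandidateGene] = []
        changed = False
        for chrom in sorted(by_chrom):
            ordered = sorted(by_chrom[chrom], key=lambda g: g.span)
            i = 0
            while i < len(ordered):
                g = ordered[i]
                nxt = ordered[i + 1] if i + 1 < len(ordered) else None
                if nxt is not None and _single_shared_homolog(g, nxt):
                    merged = replace(
                        g,
                        gene_id=f"{g.gene_id}--{nxt.gene_id}",
                        cds_intervals=interval_union(
                            list(g.cds_intervals) + list(nxt.cds_intervals)
                        ),
                        sources=frozenset(g.sources | nxt.sources),
                        evidence=_shift_merged_evidence(g, nxt),
                    )
                    retained.append(merged)
                    merged_pairs.append((g.gene_id, nxt.gene_id, merged.gene_id))
                    changed = True
                    i += 2
                else:
                    retained.append(g)
                    i += 1
        current = retained
        if not changed:
            break
    return RefinementResult(current, removed, merged_pairs)


def _shift_merged_evidence(a: CandidateGene, b: CandidateGene):
    """Evidence of a merged model: a's as-is, b's shifted past a's CDS."""
    offset = a.cds_length
    shifted = [
        replace(ev, start=ev.start + offset, end=ev.end + offset)
        for ev in b.evidence
    ]
    return tuple(list(a.evidence) + shifted)
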