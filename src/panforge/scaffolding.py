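"""Reference-assisted scaffolding: fragment placement and pseudomolecules.

Draft fragments (contigs/scaffolds) are anchored to reference chromosomes
from tabular alignment hits. A fragment is placed at its best-scoring
location only when that location beats the runner-up by a score ratio
(default 1.05, inclusive); otherwise it is ambiguous. Placed fragments are
concatenated per chromosome in anchor order, joined by runs of 100 N, and
everything else goes to an unplaced bin. Assembly statistics (N50 etc.)
summarise the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .errors import InputError

OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a fragment to a reference chromosome.

    Coordinates are 0-based half-open on both axes; strand is '+' or '-'.
    """

    fragment_id: str
    reference_chromosome: str
    fragment_start: int
    fragment_end: int
    reference_start: int
    reference_end: int
    strand: str
    score: float
    identity: float = 1.0

    def __post_init__(self):
        if self.fragment_start >= self.fragment_end:
            raise InputError("fragment_start must be < fragment_end")
        if self.reference_start >= self.reference_end:
            raise InputError("reference_start must be < reference_end")
        if self.score <= 0:
            raise InputError("alignment score must be positive")


@dataclass(frozen=True)
class Placement:
    fragment_id: str
    status: str  # placed | ambiguous | unplaced
    reference_chromosome: str | None = None
    orientation: str | None = None
    reference_anchor_position: int | None = None


def read_hits_table(path_or_df) -> list[AlignmentHit]:
    """Read alignment hits from a BLAST outfmt-6 table (1-based inclusive).

    ``sstart > send`` marks a minus-strand hit, as BLAST emits it.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(
            path_or_df, sep="\t", names=OUTFMT6_COLUMNS, comment="#"
        )
    hits = []
    for row in df.itertuples(index=False):
        sstart, send = int(row.sstart), int(row.send)
        strand = "+" if sstart <= send else "-"
        lo, hi = min(sstart, send), max(sstart, send)
        hits.append(
            AlignmentHit(
                fragment_id=str(row.qseqid),
                reference_chromosome=str(row.sseqid),
                fragment_start=int(row.qstart) - 1,
                fragment_end=int(row.qend),
                reference_start=lo - 1,
                reference_end=hi,
                strand=strand,
                score=float(row.bitscore),
                identity=float(row.pident) / 100.0,
            )
        )
    return hits


def _merge_locations(hits: list[AlignmentHit], window: int):
    """Merge co-linear hits of one fragment to the same chromosome/strand.

    Hits within ``window`` bp of each other on the reference are summed into
    one candidate location; this approximates whole-fragment placement when
    the aligner reports a fragment as several local hits.
    """
    locations = []
    by_target: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        by_target.setdefault((h.reference_chromosome, h.strand), []).append(h)
    for (chrom, strand), group in sorted(by_target.items()):
        group.sort(key=lambda h: h.reference_start)
        current = [group[0]]
        for h in group[1:]:
            if h.reference_start - current[-1].reference_end <= window:
                current.append(h)
            else:
                locations.append((chrom, strand, current))
                current = [h]
        locations.append((chrom, strand, current))
    out = []
    for chrom, strand, group in locations:
        out.append(
            {
                "chromosome": chrom,
                "strand": strand,
                "score": sum(h.score for h in group),
                "anchor": min(h.reference_start for h in group),
            }
        )
    return out


def place_fragments(
    hits,
    ratio_threshold: float = 1.05,
    fragment_lengths: dict[str, int] | None = None,
    all_fragments=None,
) -> list[Placement]:
    """Assign each fragment to placed / ambiguous / unplaced.

    The best candidate location must outscore the second best by at least
    ``ratio_threshold`` (inclusive); single-location fragments are placed
    outright. ``all_fragments`` optionally supplies ids with no hits at all,
    which come back ``unplaced``.
    """
    if ratio_threshold <= 1:
        raise InputError("ratio_threshold must exceed 1")
    by_fragment: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_fragment.setdefault(h.fragment_id, []).append(h)
    placements = []
    for frag in sorted(by_fragment):
        fhits = by_fragment[frag]
        if fragment_lengths and frag in fragment_lengths:
            window = fragment_lengths[frag]
        else:
            window = max(h.fragment_end for h in fhits)
        locs = _merge_locations(fhits, window)
        locs.sort(key=lambda d: (-d["score"], d["chromosome"], d["anchor"]))
        best = locs[0]
        if len(locs) == 1 or best["score"] / locs[1]["score"] >= ratio_threshold:
            placements.append(
                Placement(
                    frag,
                    "placed",
                    best["chromosome"],
                    best["strand"],
                    best["anchor"],
                )
            )
        else:
            placements.append(Placement(frag, "ambiguous"))
    if all_fragments is not None:
        for frag in sorted(set(all_fragments) - set(by_fragment)):
            placements.append(Placement(frag, "unplaced"))
    return placements


def build_pseudomolecules(
    placements, fragments: dict[str, str], gap_length: int = 100
):
    """Concatenate placed fragments into per-chromosome pseudomolecules.

    Fragments on one chromosome are joined in order of their anchor
    position (ties broken by fragment id), reverse-complemented when
    anchored on the minus strand, and separated by exactly ``gap_length``
    N characters. Ambiguous and unplaced fragments land in the returned
    unplaced bin, so no sequence is ever lost.
    """
    seen = set()
    for p in placements:
        if p.fragment_id in seen:
            raise InputError(f"fragment {p.fragment_id} placed twice")
        seen.add(p.fragment_id)
    per_chrom: dict[str, list[Placement]] = {}
    unplaced: dict[str, str] = {}
    for p in placements:
        if p.fragment_id not in fragments:
            raise InputError(f"unknown fragment {p.fragment_id}")
        if p.status == "placed":
            per_chrom.setdefault(p.reference_chromosome, []).append(p)
        else:
            unplaced[p.fragment_id] = fragments[p.fragment_id]
    pseudomolecules = {}
    for chrom in sorted(per_chrom):
        ordered = sorted(
            per_chrom[chrom],
            key=lambda p: (p.reference_anchor_position, p.fragment_id),
        )
        parts = []
        for p in ordered:
            seq = fragments[p.fragment_id]
            if p.orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
        pseudomolecules[chrom] = ("N" * gap_length).join(parts)
    return pseudomolecules, unplaced


def assembly_stats(lengths) -> dict:
    """Total length, fragment count and N50 of an assembly.

    N50 is the length at which the cumulative sum over fragments, scanned
    longest first, first reaches half the total.
    """
    lengths = [int(x) for x in lengths]
    if not lengths:
        raise InputError("assembly_stats requires at least one fragment")
    if min(lengths) <= 0:
        raise InputError("fragment lengths must be positive")
    total = sum(lengths)
    half = total / 2
    acc = 0
    n50 = None
    for L in sorted(lengths, reverse=True):
        acc += L
        if acc >= half:
            n50 = L
            break
    return {"total_length": total, "N50": n50, "count": len(lengths)}
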