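# Methods

This note documents the models and procedures panforge implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not demonstrate.

## Synthetic pan-genome generator

The generator emulates the data layout of a five-variety crop pan-genome
study. Its defaults define the standard study conditions used by the test
suite and the acceptance experiments:

* **Panel and tree.** Five varieties on a dated topology in which the two
  youngest modern cultivars split 0.9 MY ago, a landrace joins at 4.7 MY,
  a second landrace at 6.0 MY, and the basal (Indian-type) lineage at
  14.2 MY. Branch lengths are age differences times a clock rate of
  0.0035 substitutions/site/MY, keeping within-family coding identity
  around 90–97% — high enough to cluster reliably, low enough to be
  non-trivial. A 12-taxon extension adds seven outgroup species with node
  ages of 46 (monocot crown), 66.1, 85, 110, 117 and 160 MY for the
  phylogeny/dating experiments.
* **Families.** 400 core families (one gene per variety), 200 dispensable
  families present in a random proper subset of 2–4 varieties, and 50
  variety-specific genes per variety (~3,000 genes). Dispensable presence
  subsets default to size ≥ 2 because a one-gene single-variety family is
  observationally identical to a variety-specific singleton; size-1
  subsets are allowed when configured explicitly. Variety-specific genes
  are independent random codon strings, which keeps them below any
  clustering threshold with overwhelming probability.
* **Coding sequences.** Ancestral CDS of 100–200 codons drawn from F1x4
  frequencies (nucleotide weights T/C/A/G = 0.3/0.2/0.3/0.2), evolved
  along the tree under a GY94 Markov codon model (61 sense codons,
  default κ = 2.5, ω = 0.2 per branch). Stop codons cannot arise because
  the chain lives on sense codons only; sequences stay aligned because
  the simulator introduces no indels.
* **Duplications.** A tandem array of size *k* takes one resident gene
  and inserts *k* − 1 slightly diverged copies (t = 0.02, purifying)
  immediately after it; a duplicated block copies a run of *n*
  consecutive genes, in order, onto a different chromosome. Truth labels
  originals and copies (TD and WGD respectively), and placements never
  overlap. The defaults plant, per variety, arrays of sizes 3 and 2 and
  one 20-anchor block.
* **Layout.** Genes are shuffled, split contiguously across 4
  chromosomes, strand-randomised, and separated by 200 bp of random
  intergenic sequence. GFF3 output is 1-based inclusive; the in-memory
  representation is 0-based half-open.

What the generator does **not** model: indels within families, repeats and
transposons, gene loss along the tree (variety-specific genes are unrelated
sequences, not losses), assembly errors, or fragmented gene models.
Passing the planted-truth tests therefore demonstrates algorithmic
correctness under clean conditions, not robustness to the noise of real
annotations.

## Orthology

Candidate pairs are found by shared 4-mer seeding (≥ 2 shared words, hub
words occurring in > 50 sequences skipped) — the standard database-search
device that avoids aligning the quadratically many unrelated pairs. Scores
are exact Smith–Waterman (BLOSUM62, gap open 11, extend 1, via Biopython's
PairwiseAligner) and e-values use Karlin–Altschul statistics with the
fixed gapped-BLOSUM62 parameters (λ = 0.267, K = 0.041) against the total
database residue count. The seeding heuristic can in principle miss very
weak homologies that full BLASTP would report near the 1e-5 cutoff; at the
within-family identities the generator produces this does not occur.

MCL is implemented directly: edge weights −log10(e-value) capped at 300,
symmetrised by averaging; self-loops at the column maximum (the canonical
convergence device); expansion = squaring; inflation 1.5 with column
renormalisation; pruning below 1e-6; convergence when the flow matrix is
idempotent within 1e-8 or 200 iterations, run per connected component.
Clusters are the connected structure of the limit matrix; singletons are
reported as unclustered, and "variety-specific" means unclustered (a
single-variety cluster of paralogs still counts as a cluster).

## Pan-genome accounting

Percentages are computed over clusters only; variety-specific genes are
reported separately, and a variety's dispensable gene count includes its
unclustered genes. Region accounting counts each alignment block once at
its longest member span (non-redundant pan-genome coordinates) — the
published pan-genome size exceeds any single genome but is far below the
summed genome sizes, which implies exactly this convention — and assigns
each variety's unaligned residue count to the dispensable genome, making
core + dispensable = pan additive by construction.

## Duplication origins

Tandem arrays are maximal single-linkage runs of homologous genes
(self-similarity at e ≤ 1e-20) separated by fewer than `max_gap`
intervening genes (default 1, i.e. strictly adjacent). Collinear blocks
chain homolog pairs by dynamic programming: the query index must increase
and the subject index increase (parallel) or decrease (inverted) by at
most `max_gap` + 1 per step; chains need ≥ 15 anchors (`s = 15`-style
threshold), score is anchor count, best chain extracted first, anchors
used once. A gene in both signals is labelled TD: the published summary
tables report disjoint WGD/TD classes, so a precedence is required, and
the tandem array is the more specific, locally-verifiable signal.

## Phylogeny and dating

Family alignment is a star alignment: proteins are globally aligned
(Needleman–Wunsch, BLOSUM62, 11/1) against the longest member and merged
on reference coordinates, then back-translated so gaps come in whole
codons. This is a deliberate desk-scale simplification of a full
progressive aligner; simulator output is gap-free, so the tests exercise
the machinery without depending on alignment heuristics. Column filtering
applies two explicit rules (drop columns with any gap by default; drop
columns whose majority residue frequency is below 0.5) in place of
block-based heuristic trimmers, trading their context rules for exact
reproducibility.

Distances are GTR maximum-likelihood distances,
d = −tr(Π log(Π⁻¹F)) on the symmetrised divergence matrix, falling back
to the Tamura–Nei closed form when the matrix logarithm is
ill-conditioned, and capped at 5 substitutions/site (with a warning) when
saturated. Trees come from neighbor joining (scikit-bio; negative branch
lengths clamped with compensation on the adjacent branch). Rooting on a
declared outgroup splits the outgroup branch at the point equalising mean
root-to-leaf distance on both sides, which recovers the true root
position on clock-like trees — plain midpoint splitting of that branch
does not, and visibly distorts downstream dating.

Fourfold-degenerate sites are third positions of codon columns whose
first two positions are identical across all taxa and form a
fourfold-degenerate box; requiring cross-taxon identity is conservative
but guarantees the extracted site evolved under fourfold degeneracy along
the whole tree.

Strict-clock dating minimises Σ(r·(a_root − a_v) − d_v)² over node ages
and one rate, subject to parent-older-than-child ordering and hard
calibration intervals, solved by SLSQP on variables rescaled to unit
magnitude (the raw problem mixes ages ~10² with rates ~10⁻³ and
converges poorly otherwise). Identifiability caveat: with perfectly
clock-like input and a single *interval* calibration, the objective is
flat along a rate/age ridge and the rate is identified only up to the
interval; the solver resolves the ridge near its initialisation, which
uses the interval midpoint. Ages of very young nodes (≪ 1/rate × data
noise) have large relative errors under branch-length noise — an
information limit, not a solver defect.

## Codon models and selection tests

The substitution model is GY94: rates π_j·(κ for transitions)·(ω for
nonsynonymous changes) on single-nucleotide codon changes, frequencies
F3x4 estimated from the alignment by default (F1x4 available, matching
the simulator's default). Likelihoods use Felsenstein pruning over site
patterns with per-node scaling; gap/ambiguous codons are missing data.
Branch lengths are re-estimated under every model; optimisation is
L-BFGS-B over bounded parameters with κ initialised at 2.5 and ω at 0.2.
The branch-site alternative additionally starts from ω₂ = 1.5 (the
conventional initialisation), from just above 1, and from 4, keeping the
best — ω₂ sits on the null boundary and a single start can otherwise land
a hair below the nested null, breaking the likelihood ordering
numerically.

**Rate scaling across site classes.** In mixture (branch-site) models all
site classes share one time scale per branch: each class's rate matrix is
scaled by the *mixture-averaged* substitution rate, so a class under
positive selection genuinely evolves faster. Normalising each class to
one substitution per codon separately would equalise total rates across
classes and erase most of the selective signal; this applies to the
simulator and the likelihood alike. Single-class models are unaffected
(per-branch scaling is a pure reparameterisation there).

Decision rules: a family is *fast-evolving* when the BH-adjusted p of the
two-ratio vs one-ratio LRT (df 1) is below α = 0.01, the free-ratio model
is *not* significantly better than the two-ratio model (df = branches − 2),
and the foreground ω exceeds the background. It is *positively selected*
when the branch-site alternative beats the null (df 1, plain χ²₁ — more
conservative than the 50:50 boundary mixture) at BH-adjusted p < 0.01
with ω₂ > 1. Benjamini–Hochberg is used wherever an FDR correction is
called for. The free-ratio degrees of freedom (branches − 2) follow from
counting ω parameters: one per branch versus the two of the two-ratio
model.

**NG86 cross-check.** Nei–Gojobori counting (pathway-averaged differences,
Jukes–Cantor correction; mutations to stops excluded from pathways and
counted as nonsynonymous in site counting) provides a model-free ω. NG86
assumes no transition/transversion bias; on κ = 2.5 data it
underestimates ω by roughly 15% (transitions are enriched and
preferentially synonymous, inflating the apparent synonymous rate).
Dual-route agreement tests are therefore run at κ = 1 where both
estimators share assumptions; the κ = 2.5 regime is validated by ML
recovery within Monte-Carlo error instead.

## Validation experiment sizes

The standard problem sizes were chosen as the smallest at which each
estimate is statistically meaningful: planted-truth recovery on ~3,000
genes across five varieties; LRT type-I error from 200 null replicates of
666 codons on a five-taxon tree whose internal foreground branch is 0.15
substitutions/codon; power from 50 replicates of 1,666 codons at
foreground ω 0.8 vs background 0.2 using the full three-model decision
rule; ω recovery from two-taxon 3,333-codon alignments; topology recovery
from 20 kb of GTR-simulated fourfold-site-like data on the 12-taxon
panel; dating from 20 replicate clock-like trees with randomly rescaled
ages and rates under the 40–53 MY monocot-crown calibration.

## Known limitations

* The e-value layer is an approximation with fixed Karlin–Altschul
  parameters, not a reimplementation of BLAST's composition-dependent
  statistics; absolute e-values near the cutoff differ from BLASTP's.
* MCL here follows the textbook algorithm; it is not bit-compatible with
  OrthoMCL's weighting scheme (which additionally normalises
  within/between-species e-values).
* The star alignment can misplace insertions relative to a simultaneous
  progressive alignment when several sequences carry distinct indels.
* Branch-site power is intrinsically limited on short foreground branches;
  the calibration experiments use a foreground long enough for the stated
  contrasts to be detectable.
* The dating solver returns point estimates under hard interval
  constraints; it does not quantify age uncertainty.
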