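"""Synthetic multi-variety pan-genome generator with planted ground truth.

The generator emulates the data layout of a five-variety crop pan-genome
study: a panel of closely related varieties whose gene complements are a
mixture of core families (present in every variety), dispensable families
(present in a proper subset), and variety-specific genes (unrelated
sequences that should never cluster). Coding sequences are evolved along a
known dated variety tree under a GY94 Markov codon model with per-branch
dN/dS, so downstream estimates (clusters, core/dispensable labels,
duplication origins, trees, omega) can be scored against planted truth.

Tandem arrays (consecutive homologous copies at one locus) and
whole-genome-duplication-like collinear blocks (a run of genes copied in
order onto a different chromosome) are planted on request, which gives the
duplication-origin classifier a noiseless gold standard.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import _codon
from ._trees import edge_key, lookup_branch_value, parse_newick
from .errors import ConfigurationError, InputError

# Default variety panel and dated topology. Ages (MY) follow the divergence
# pattern of a modern-cultivar/landrace panel: the two youngest cultivars
# split most recently, the Indian lineage is basal. Branch lengths are
# age differences times a clock rate of 0.0035 substitutions/site/MY, which
# keeps within-family sequence identity around 90-97% -- high enough to
# cluster, low enough to be non-trivial.
DEFAULT_VARIETIES = ("zz13", "yz11", "bzm", "mszm", "swetha")
DEFAULT_TREE = (
    "((((zz13:0.00315,yz11:0.00315):0.0133,bzm:0.01645):0.00455,"
    "mszm:0.021):0.0287,swetha:0.0497);"
)
DEFAULT_NUC_FREQS = (0.3, 0.2, 0.3, 0.2)  # T, C, A, G


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic pan-genome draw.

    The defaults define the standard study conditions used throughout the
    test-suite: 5 varieties, 400 core + 200 dispensable families, 50
    variety-specific genes per variety (~3,000 genes), one size-3 and one
    size-2 tandem array plus one 20-anchor duplicated block per variety.
    """

    varieties: tuple[str, ...] = DEFAULT_VARIETIES
    tree: str = DEFAULT_TREE
    n_core_families: int = 400
    n_dispensable_families: int = 200
    dispensable_presence: tuple[tuple[str, ...], ...] | None = None
    n_specific_genes: int = 50
    td_arrays: tuple[tuple[str, int, str], ...] = ()
    wgd_blocks: tuple[tuple[str, int], ...] = ()
    omega_map: object = 0.2
    kappa: float = 2.5
    seed: int = 1
    n_chromosomes: int = 4
    gene_length_codons: tuple[int, int] = (100, 200)
    intergenic_length: int = 200
    nuc_freqs: tuple[float, float, float, float] = DEFAULT_NUC_FREQS

    def with_default_duplications(self) -> "SimulationConfig":
        """Standard duplication plan: per variety, TD arrays of sizes 3 and 2
        on the first two chromosomes and one 20-anchor duplicated block."""
        td = tuple(
            (v, size, f"chr{c}")
            for v in self.varieties
            for size, c in ((3, 1), (2, 2))
        )
        wgd = tuple((v, 20) for v in self.varieties)
        return replace(self, td_arrays=td, wgd_blocks=wgd)

    def validate(self) -> None:
        n = len(self.varieties)
        if n < 2 or len(set(self.varieties)) != n:
            raise ConfigurationError("need >=2 distinct varieties")
        for count in (
            self.n_core_families,
            self.n_dispensable_families,
            self.n_specific_genes,
            self.n_chromosomes,
        ):
            if count < 0 or (self.n_chromosomes < 1):
                raise ConfigurationError("counts must be non-negative")
        if self.dispensable_presence is not None:
            if len(self.dispensable_presence) != self.n_dispensable_families:
                raise ConfigurationError(
                    "dispensable_presence must list one subset per family"
                )
            for subset in self.dispensable_presence:
                s = set(subset)
                if not s or not s < set(self.varieties):
                    raise ConfigurationError(
                        "each dispensable subset must be a proper non-empty "
                        "subset of the varieties"
                    )
        for v, size, _chrom in self.td_arrays:
            if v not in self.varieties or size < 2:
                raise ConfigurationError(f"bad TD spec ({v}, {size})")
        for v, count in self.wgd_blocks:
            if v not in self.varieties or count < 1:
                raise ConfigurationError(f"bad WGD spec ({v}, {count})")
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")


@dataclass
class Gene:
    gene_id: str
    variety: str
    chromosome: str
    start: int  # 0-based half-open on the chromosome
    end: int
    strand: str
    cds: str
    family: str | None = None

    @property
    def protein(self) -> str:
        return str(Seq(self.cds).translate())


@dataclass
class VarietyGenome:
    variety: str
    chromosomes: dict[str, str]
    genes: list[Gene]

    def gene_order(self) -> dict[str, list[str]]:
        """Per-chromosome gene ids in left-to-right coordinate order."""
        order: dict[str, list[Gene]] = {}
        for g in self.genes:
            order.setdefault(g.chromosome, []).append(g)
        return {
            c: [g.gene_id for g in sorted(gs, key=lambda g: g.start)]
            for c, gs in sorted(order.items())
        }

    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    def cds(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes}


@dataclass
class DuplicationTruth:
    origin: dict[str, str]  # gene -> WGD | TD
    arrays: list[list[str]]  # planted tandem arrays, in gene order
    anchor_pairs: list[tuple[str, str]]  # (original, copy) per planted block


@dataclass
class GroundTruth:
    family_labels: dict[str, str]  # family -> core | dispensable | specific
    gene_family: dict[str, str]  # gene -> family
    gene_origin: dict[str, str]  # gene -> WGD | TD | other
    tree: str
    omega_map: object
    td_arrays: dict[str, list[list[str]]] = field(default_factory=dict)
    wgd_anchors: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# codon evolution


def _evolve_indices(ancestor_idx, tree, omega_map, kappa, pi, rng, rate_map=None):
    """Evolve codon-index arrays down a dendropy tree; returns leaf arrays.

    ``rate_map`` optionally overrides the per-edge time scale (used for
    site-class mixtures, where every class shares the mixture-averaged
    substitution rate per branch).
    """
    cache: dict[float, _codon.CodonEigen] = {}

    def eigen(omega):
        if omega not in cache:
            cache[omega] = _codon.CodonEigen(kappa, omega, pi)
        return cache[omega]

    states = {tree.seed_node: np.asarray(ancestor_idx)}
    leaves = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            if node.is_leaf():
                leaves[node.taxon.label] = states[node]
            continue
        ekey = edge_key(node)
        omega = lookup_branch_value(ekey, omega_map)
        if omega is None:
            raise ConfigurationError(f"no omega for branch {ekey!r}")
        t = node.edge.length or 0.0
        parent = states[node.parent_node]
        if t == 0:
            child = parent.copy()
        else:
            rate = rate_map.get(ekey) if rate_map else None
            P = eigen(float(omega)).transition_matrix(t, rate=rate)
            child = np.empty_like(parent)
            for s in np.unique(parent):
                mask = parent == s
                child[mask] = rng.choice(
                    _codon.N_CODONS, size=int(mask.sum()), p=P[s]
                )
        states[node] = child
        if node.is_leaf():
            leaves[node.taxon.label] = child
    return leaves


def evolve_family(
    ancestor_cds: str,
    tree,
    omega_map=0.2,
    kappa: float = 2.5,
    seed=None,
    codon_frequencies=None,
) -> dict[str, str]:
    """Evolve one ancestral CDS along a tree under GY94.

    ``tree`` is a newick string or dendropy tree with branch lengths in
    substitutions/site (per codon after scaling). ``omega_map`` is a scalar
    or a dict keyed by branch (leaf label, or frozenset of descendant leaf
    labels; a ``"default"`` entry acts as fallback). The output sequences are
    gap-free and aligned by construction; no stop codons are ever produced
    because the chain lives on the 61 sense codons.
    """
    if len(ancestor_cds) % 3:
        raise InputError("ancestor length must be divisible by 3")
    try:
        idx = _codon.encode_codons(ancestor_cds)
    except ValueError as exc:
        raise InputError(str(exc)) from exc
    if np.any(idx < 0):
        raise InputError("ancestor contains stop or ambiguous codons")
    if isinstance(tree, str):
        tree = parse_newick(tree)
    if codon_frequencies is None:
        codon_frequencies = _codon.empirical_codon_frequencies(
            [ancestor_cds], model="F1x4"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    leaves = _evolve_indices(idx, tree, omega_map, kappa, codon_frequencies, rng)
    return {taxon: _codon.decode_codons(v) for taxon, v in leaves.items()}


def simulate_alignment(
    tree,
    n_codons: int,
    kappa: float = 2.5,
    omega_map=0.2,
    site_classes=None,
    codon_frequencies=None,
    seed=None,
) -> dict[str, str]:
    """Simulate a gap-free codon alignment along a tree.

    ``site_classes``, when given, is a list of ``(proportion, omega_map)``
    pairs (proportions summing to 1); each site is assigned to a class and
    evolved under that class's per-branch omegas — this is how branch-site
    data are generated. The root sequence is drawn from the stationary
    codon distribution.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    if codon_frequencies is None:
        codon_frequencies = _codon.f1x4_frequencies(DEFAULT_NUC_FREQS)
    pi = np.asarray(codon_frequencies)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ancestor = rng.choice(_codon.N_CODONS, size=n_codons, p=pi)
    if site_classes is None:
        leaves = _evolve_indices(ancestor, tree, omega_map, kappa, pi, rng)
    else:
        props = np.array([p for p, _ in site_classes], dtype=float)
        if abs(props.sum() - 1) > 1e-8 or np.any(props < 0):
            raise ConfigurationError("site-class proportions must sum to 1")
        assignment = rng.choice(len(site_classes), size=n_codons, p=props)
        # all classes share one time scale per branch (the mixture-averaged
        # rate), so a class under positive selection really evolves faster
        rate_map = {}
        mu_cache: dict[float, float] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            ekey = edge_key(node)
            mus = []
            for _p, omap in site_classes:
                omega = lookup_branch_value(ekey, omap)
                if omega is None:
                    raise ConfigurationError(f"no omega for branch {ekey!r}")
                omega = float(omega)
                if omega not in mu_cache:
                    mu_cache[omega] = _codon.CodonEigen(kappa, omega, pi).rate
                mus.append(mu_cache[omega])
            rate_map[ekey] = float(props @ np.array(mus))
        leaves = None
        for ci, (_, omap) in enumerate(site_classes):
            sites = np.where(assignment == ci)[0]
            if sites.size == 0:
                continue
            part = _evolve_indices(
                ancestor[sites], tree, omap, kappa, pi, rng, rate_map=rate_map
            )
            if leaves is None:
                leaves = {
                    tax: np.empty(n_codons, dtype=np.int64) for tax in part
                }
            for tax, vals in part.items():
                leaves[tax][sites] = vals
    return {tax: _codon.decode_codons(v) for tax, v in leaves.items()}


def simulate_gtr_alignment(
    tree, length: int, rates=None, base_freqs=(0.25, 0.25, 0.25, 0.25), seed=None
) -> dict[str, str]:
    """Simulate nucleotide sequences along a tree under GTR.

    ``rates`` are the six exchangeabilities in (AC, AG, AT, CG, CT, GT)
    order; ``base_freqs`` in A, C, G, T order. Used for fourfold-site-style
    neutral data when testing distance and dating methods.
    """
    if isinstance(tree, str):
        tree = parse_newick(tree)
    if rates is None:
        rates = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
    pi = np.asarray(base_freqs, dtype=float)
    pi = pi / pi.sum()
    R = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), r in zip(pairs, rates):
        R[i, j] = R[j, i] = r
    Q = R * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()
    sqrt_pi = np.sqrt(pi)
    B = (Q / sqrt_pi[None, :]) * sqrt_pi[:, None]
    w, U = np.linalg.eigh((B + B.T) / 2)
    left, right = U / sqrt_pi[:, None], (U * sqrt_pi[:, None]).T

    def P_of(t):
        P = (left * np.exp(w * t)) @ right
        np.clip(P, 0, 1, out=P)
        return P / P.sum(axis=1, keepdims=True)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = {tree.seed_node: rng.choice(4, size=length, p=pi)}
    alphabet = np.array(list("ACGT"))
    out = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = node.edge.length or 0.0
            parent = states[node.parent_node]
            if t == 0:
                child = parent.copy()
            else:
                P = P_of(t)
                child = np.empty_like(parent)
                for s in range(4):
                    mask = parent == s
                    if mask.any():
                        child[mask] = rng.choice(4, size=int(mask.sum()), p=P[s])
            states[node] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(alphabet[states[node]])
    return out


# Twelve-taxon panel analog: five varieties plus seven outgroup species on
# a dated topology (ages in MY, youngest cultivar split 0.9, landrace split
# 4.7, Indian lineage 14.2, monocot calibration node 46, root 160).
PANEL_TOPOLOGY = (
    (
        (
            "vvi",
            (
                "ath",
                (
                    ((((("zz13", "yz11"), "bzm"), "mszm"), "swetha"), "ugibba"),
                    ("slyc", "stub"),
                ),
            ),
        ),
        ("osa", "zma"),
    )
)
PANEL_AGES = {
    frozenset({"zz13", "yz11"}): 0.9,
    frozenset({"zz13", "yz11", "bzm"}): 4.7,
    frozenset({"zz13", "yz11", "bzm", "mszm"}): 6.0,
    frozenset({"zz13", "yz11", "bzm", "mszm", "swetha"}): 14.2,
    frozenset({"zz13", "yz11", "bzm", "mszm", "swetha", "ugibba"}): 66.1,
    frozenset({"slyc", "stub"}): 8.0,
    frozenset(
        {"zz13", "yz11", "bzm", "mszm", "swetha", "ugibba", "slyc", "stub"}
    ): 85.0,
    frozenset(
        {"zz13", "yz11", "bzm", "mszm", "swetha", "ugibba", "slyc", "stub", "ath"}
    ): 110.0,
    frozenset(
        {
            "zz13", "yz11", "bzm", "mszm", "swetha", "ugibba", "slyc", "stub",
            "ath", "vvi",
        }
    ): 117.0,
    frozenset({"osa", "zma"}): 46.0,
    frozenset(
        {
            "zz13", "yz11", "bzm", "mszm", "swetha", "ugibba", "slyc", "stub",
            "ath", "vvi", "osa", "zma",
        }
    ): 160.0,
}


def panel_tree(rate: float = 0.002):
    """Clock-like newick for the 12-taxon panel analog.

    Branch lengths are ``rate * (parent_age - child_age)`` in
    substitutions/site; returns ``(newick, ages)`` where ``ages`` maps each
    internal clade (frozenset of leaf names) to its age in MY.
    """

    def leaves_of(node):
        if isinstance(node, str):
            return frozenset({node})
        out = frozenset()
        for c in node:
            out |= leaves_of(c)
        return out

    def build(node, parent_age):
        if isinstance(node, str):
            return f"{node}:{rate * parent_age:.8f}"
        age = PANEL_AGES[leaves_of(node)]
        inner = "(" + ",".join(build(c, age) for c in node) + ")"
        if parent_age is None:
            return inner + ";"
        return f"{inner}:{rate * (parent_age - age):.8f}"

    return build(PANEL_TOPOLOGY, None), dict(PANEL_AGES)


# ---------------------------------------------------------------------------
# genome assembly helpers


def _random_cds(rng, n_codons: int, pi) -> str:
    idx = rng.choice(_codon.N_CODONS, size=n_codons, p=pi)
    return _codon.decode_codons(idx)


def _random_intergenic(rng, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _materialize(
    variety: str,
    chrom_layout: dict[str, list[tuple[str, str, str, str | None]]],
    intergenic_length: int,
    rng,
) -> VarietyGenome:
    """Turn per-chromosome (gene_id, cds, strand, family) lists into a
    genome with coordinates and sequence."""
    chromosomes, genes = {}, []
    for chrom in sorted(chrom_layout):
        parts, pos = [], 0
        for gene_id, cds, strand, family in chrom_layout[chrom]:
            spacer = _random_intergenic(rng, intergenic_length)
            parts.append(spacer)
            pos += len(spacer)
            start = pos
            genomic = cds if strand == "+" else str(Seq(cds).reverse_complement())
            parts.append(genomic)
            pos += len(genomic)
            genes.append(
                Gene(gene_id, variety, chrom, start, pos, strand, cds, family)
            )
        parts.append(_random_intergenic(rng, intergenic_length))
        chromosomes[chrom] = "".join(parts)
    return VarietyGenome(variety, chromosomes, genes)


def _layout_of(genome: VarietyGenome):
    layout: dict[str, list[tuple[str, str, str, str | None]]] = {
        c: [] for c in genome.chromosomes
    }
    for g in sorted(genome.genes, key=lambda g: (g.chromosome, g.start)):
        layout[g.chromosome].append((g.gene_id, g.cds, g.strand, g.family))
    return layout


def _diverge_copy(cds: str, rng, kappa: float, t: float = 0.02) -> str:
    """A slightly diverged duplicate of a CDS (purifying, omega=0.2)."""
    pi = _codon.empirical_codon_frequencies([cds], model="F1x4")
    eig = _codon.CodonEigen(kappa, 0.2, pi)
    P = eig.transition_matrix(t)
    idx = _codon.encode_codons(cds)
    out = np.empty_like(idx)
    for s in np.unique(idx):
        mask = idx == s
        out[mask] = rng.choice(_codon.N_CODONS, size=int(mask.sum()), p=P[s])
    return _codon.decode_codons(out)


def plant_duplications(
    genome: VarietyGenome,
    td_spec=(),
    wgd_spec=(),
    seed=None,
    kappa: float = 2.5,
    intergenic_length: int = 200,
) -> tuple[VarietyGenome, DuplicationTruth]:
    """Plant tandem arrays and collinear duplicated blocks in one genome.

    ``td_spec`` is a list of ``(array_size, chromosome)``; each array takes
    an existing gene on that chromosome and inserts ``array_size - 1``
    slightly diverged copies immediately after it, so the array is
    ``array_size`` consecutive homologous genes. ``wgd_spec`` is a list of
    anchor counts; each block copies a run of that many consecutive genes,
    in order, onto a different chromosome. Truth labels both the originals
    and the copies (TD and WGD respectively); placements never overlap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    layout = _layout_of(genome)
    used: set[str] = set()
    truth = DuplicationTruth({}, [], [])

    for size, chrom in td_spec:
        if chrom not in layout:
            raise ConfigurationError(f"unknown chromosome {chrom!r}")
        candidates = [
            i
            for i, (gid, _cds, _strand, fam) in enumerate(layout[chrom])
            if gid not in used and fam is not None
        ] or [
            i for i, (gid, *_rest) in enumerate(layout[chrom]) if gid not in used
        ]
        if not candidates:
            raise ConfigurationError(f"no room for a TD array on {chrom}")
        i = int(rng.choice(candidates))
        gid, cds, strand, family = layout[chrom][i]
        members = [gid]
        copies = []
        for k in range(1, size):
            cid = f"{gid}_td{k}"
            copies.append((cid, _diverge_copy(cds, rng, kappa), strand, family))
            members.append(cid)
        layout[chrom][i + 1 : i + 1] = copies
        used.update(members)
        for m in members:
            truth.origin[m] = "TD"
        truth.arrays.append(members)

    for count in wgd_spec:
        sources = [
            c
            for c in sorted(layout)
            if sum(1 for gid, *_ in layout[c] if gid not in used) >= count
            and len(layout) > 1
        ]
        placed = False
        for chrom in sources:
            free = [
                i for i, (gid, *_rest) in enumerate(layout[chrom]) if gid not in used
            ]
            runs = [
                i
                for i in free
                if set(range(i, i + count)) <= set(free)
                and i + count <= len(layout[chrom])
            ]
            if not runs:
                continue
            i = int(rng.choice(runs))
            run = layout[chrom][i : i + count]
            target = str(
                rng.choice([c for c in sorted(layout) if c != chrom])
            )
            copies = []
            for gid, cds, strand, family in run:
                cid = f"{gid}_wgd"
                copies.append((cid, _diverge_copy(cds, rng, kappa), strand, family))
                truth.anchor_pairs.append((gid, cid))
                truth.origin[gid] = "WGD"
                truth.origin[cid] = "WGD"
                used.add(gid)
                used.add(cid)
            layout[target].extend(copies)
            placed = True
            break
        if not placed:
            raise ConfigurationError(
                f"cannot place a {count}-anchor duplicated block without overlap"
            )

    rebuilt = _materialize(genome.variety, layout, intergenic_length, rng)
    return rebuilt, truth


# ---------------------------------------------------------------------------
# the full pan-genome draw


def simulate_pangenome(config: SimulationConfig):
    """Draw a complete synthetic pan-genome dataset plus its ground truth.

    Returns ``(dataset, truth)`` where ``dataset`` maps variety name to a
    :class:`VarietyGenome`. The draw is fully determined by ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = parse_newick(config.tree)
    taxa = {t.label for t in tree.taxon_namespace}
    if not set(config.varieties) <= taxa:
        raise ConfigurationError("tree must contain every variety")
    pi = _codon.f1x4_frequencies(config.nuc_freqs)
    lo, hi = config.gene_length_codons

    family_labels: dict[str, str] = {}
    gene_family: dict[str, str] = {}
    per_variety_genes: dict[str, list[tuple[str, str, str | None]]] = {
        v: [] for v in config.varieties
    }

    presence = list(config.dispensable_presence or [])
    if config.dispensable_presence is None:
        n = len(config.varieties)
        for _ in range(config.n_dispensable_families):
            size = int(rng.integers(2, n)) if n > 2 else 1
            subset = rng.choice(config.varieties, size=size, replace=False)
            presence.append(tuple(sorted(subset)))

    n_fam = config.n_core_families + config.n_dispensable_families
    width = max(4, len(str(n_fam)))
    for k in range(n_fam):
        family = f"F{k + 1:0{width}d}"
        core = k < config.n_core_families
        family_labels[family] = "core" if core else "dispensable"
        members = (
            set(config.varieties)
            if core
            else set(presence[k - config.n_core_families])
        )
        n_codons = int(rng.integers(lo, hi + 1))
        ancestor = _random_cds(rng, n_codons, pi)
        leaves = evolve_family(
            ancestor,
            tree,
            omega_map=config.omega_map,
            kappa=config.kappa,
            seed=rng,
            codon_frequencies=pi,
        )
        for v in config.varieties:
            if v in members:
                gid = f"{family}_{v}"
                per_variety_genes[v].append((gid, leaves[v], family))
                gene_family[gid] = family

    for v in config.varieties:
        for k in range(config.n_specific_genes):
            gid = f"S_{v}_{k + 1:04d}"
            n_codons = int(rng.integers(lo, hi + 1))
            per_variety_genes[v].append((gid, _random_cds(rng, n_codons, pi), None))
            family_labels[gid] = "specific"
            gene_family[gid] = gid

    dataset: dict[str, VarietyGenome] = {}
    truth = GroundTruth(
        family_labels=family_labels,
        gene_family=gene_family,
        gene_origin={},
        tree=config.tree,
        omega_map=config.omega_map,
    )
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    for v in config.varieties:
        entries = per_variety_genes[v]
        order = rng.permutation(len(entries))
        shuffled = [entries[i] for i in order]
        strands = rng.choice(["+", "-"], size=len(shuffled))
        layout: dict[str, list] = {c: [] for c in chrom_names}
        chunks = np.array_split(np.arange(len(shuffled)), config.n_chromosomes)
        for chrom, chunk in zip(chrom_names, chunks):
            for i in chunk:
                gid, cds, family = shuffled[i]
                layout[chrom].append((gid, cds, strands[i], family))
        genome = _materialize(v, layout, config.intergenic_length, rng)
        td = [(size, chrom) for vv, size, chrom in config.td_arrays if vv == v]
        wgd = [count for vv, count in config.wgd_blocks if vv == v]
        genome, dup = plant_duplications(
            genome,
            td,
            wgd,
            seed=rng,
            kappa=config.kappa,
            intergenic_length=config.intergenic_length,
        )
        for gid in dup.origin:
            base = gid.split("_td")[0].removesuffix("_wgd")
            gene_family.setdefault(gid, gene_family.get(base, base))
        truth.td_arrays[v] = dup.arrays
        truth.wgd_anchors[v] = dup.anchor_pairs
        truth.gene_origin.update(dup.origin)
        dataset[v] = genome

    for v, genome in dataset.items():
        for g in genome.genes:
            truth.gene_origin.setdefault(g.gene_id, "other")
    return dataset, truth


# ---------------------------------------------------------------------------
# on-disk dataset


def _write_fasta(path, records):
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records],
        str(path),
        "fasta",
    )


def write_dataset(dataset, truth: GroundTruth, directory, config=None) -> dict:
    """Write a dataset to ``directory``; returns a checksum manifest.

    Per variety: genome FASTA, GFF3 (gene/mRNA/CDS; 1-based inclusive), CDS
    FASTA and protein FASTA. Truth tables go to TSV, the configuration echo
    to YAML, and ``manifest.tsv`` lists the SHA-256 of every file.
    """
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for v, genome in sorted(dataset.items()):
        _write_fasta(out / f"{v}.genome.fa", sorted(genome.chromosomes.items()))
        _write_fasta(
            out / f"{v}.cds.fa", [(g.gene_id, g.cds) for g in genome.genes]
        )
        _write_fasta(
            out / f"{v}.faa", [(g.gene_id, g.protein) for g in genome.genes]
        )
        with open(out / f"{v}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in sorted(genome.genes, key=lambda g: (g.chromosome, g.start)):
                s, e = g.start + 1, g.end  # 1-based inclusive
                base = f"{g.chromosome}\tpanforge\t"
                tail = f"\t{s}\t{e}\t.\t{g.strand}\t"
                fh.write(base + "gene" + tail + f".\tID={g.gene_id}\n")
                fh.write(
                    base + "mRNA" + tail + f".\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
                )
                fh.write(base + "CDS" + tail + f"0\tID={g.gene_id}.cds;Parent={g.gene_id}.t1\n")
        written += [f"{v}.genome.fa", f"{v}.cds.fa", f"{v}.faa", f"{v}.gff3"]

    import pandas as pd

    pd.DataFrame(
        sorted(truth.family_labels.items()), columns=["family", "label"]
    ).to_csv(out / "family_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.gene_family.items()), columns=["gene", "family"]
    ).to_csv(out / "gene_family.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.gene_origin.items()), columns=["gene", "origin"]
    ).to_csv(out / "gene_origin.tsv", sep="\t", index=False)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(truth.tree.strip() + "\n")
    written += ["family_labels.tsv", "gene_family.tsv", "gene_origin.tsv", "tree.nwk"]

    if config is not None:
        from dataclasses import asdict

        def listify(x):
            if isinstance(x, (tuple, list)):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {
                    (k if isinstance(k, (str, int, float, bool)) else str(sorted(k))):
                    listify(v)
                    for k, v in x.items()
                }
            if isinstance(x, (frozenset, set)):
                return sorted(x)
            return x

        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(listify(asdict(config)), fh, default_flow_style=True)
        written.append("config.yaml")

    manifest = {}
    for name in sorted(written):
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(out / "manifest.tsv", "w") as fh:
        for name, digest in manifest.items():
            fh.write(f"{name}\t{digest}\n")
    return manifest


def read_dataset(directory) -> dict[str, VarietyGenome]:
    """Read back a written dataset (genomes + gene models).

    CDS sequences are re-extracted from the genome using the GFF3
    coordinates and strand, so round-trip equality genuinely checks the
    coordinate conventions.
    """
    from pathlib import Path

    import gffutils

    out = Path(directory)
    dataset = {}
    for gff in sorted(out.glob("*.gff3")):
        v = gff.name[: -len(".gff3")]
        chroms = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(out / f"{v}.genome.fa"), "fasta")
        }
        db = gffutils.create_db(
            str(gff), ":memory:", keep_order=True, merge_strategy="create_unique"
        )
        genes = []
        for feat in db.features_of_type("gene"):
            start, end = feat.start - 1, feat.end  # back to 0-based half-open
            raw = chroms[feat.seqid][start:end]
            cds = raw if feat.strand == "+" else str(Seq(raw).reverse_complement())
            genes.append(
                Gene(feat.id, v, feat.seqid, start, end, feat.strand, cds)
            )
        dataset[v] = VarietyGenome(v, chroms, genes)
    return dataset
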