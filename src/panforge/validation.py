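"""End-to-end validation experiments on synthetic data.

Each function here runs one self-contained experiment against planted
ground truth and returns plain numbers: worked-example arithmetic on
published marginal counts, full-pipeline recovery on a synthetic
five-variety pan-genome, statistical calibration of the branch-model
likelihood-ratio test, and phylogeny/dating recovery on the twelve-taxon
panel analog. The test-suite asserts on these numbers and the acceptance
script reports them.
"""

from __future__ import annotations

import numpy as np

from . import simulate
from .simulate import SimulationConfig, simulate_pangenome

# Five-taxon analog of the variety clade used for the codon-model
# calibration experiments: a short crown plus a long internal branch (the
# foreground, analogous to the ancestral branch of the variety clade).
CALIB_TREE = "(((a:0.05,b:0.05):0.15,c:0.08):0.05,d:0.1,e:0.13);"
CALIB_TREE_TAGGED = "(((a:0.05,b:0.05)#1:0.15,c:0.08):0.05,d:0.1,e:0.13);"
CALIB_FOREGROUND = frozenset({"a", "b"})


def composition_arithmetic() -> dict:
    """Worked-example arithmetic on published marginal counts.

    Feeds the classifier and the duplication summary the published cluster
    and gene counts (15,409 core + 11,063 dispensable clusters; 10,932
    WGD / 2,076 TD of 23,372 core genes; 898 WGD of 12,817 dispensable
    genes) and returns the percentages the pipeline computes from them.
    """
    from .duplication import summarize_by_class
    from .pangenome import pangenome_composition

    labels = {f"c{i:05d}": "core" for i in range(15_409)}
    labels.update({f"d{i:05d}": "dispensable" for i in range(11_063)})
    comp = pangenome_composition(labels)

    core = [f"g{i:05d}" for i in range(23_372)]
    disp = [f"h{i:05d}" for i in range(12_817)]
    origin = {}
    for i, g in enumerate(core):
        origin[g] = "WGD" if i < 10_932 else ("TD" if i < 10_932 + 2_076 else "other")
    for i, g in enumerate(disp):
        origin[g] = "WGD" if i < 898 else "other"
    table = summarize_by_class(origin, {"v": set(core)}, {"v": set(disp)})
    core_row = table[(table.variety == "v") & (table.category == "core")].iloc[0]
    disp_row = table[(table.variety == "v") & (table.category == "dispensable")].iloc[0]
    return {
        "pct_core": comp.pct_core,
        "pct_dispensable": comp.pct_dispensable,
        "core_wgd_pct": float(core_row.wgd_pct),
        "core_td_pct": float(core_row.td_pct),
        "dispensable_wgd_pct": float(disp_row.wgd_pct),
    }


def _pipeline_cluster_recovery(dataset, truth, clusters, unclustered):
    pred = {}
    for cl in clusters:
        members = frozenset(cl.members)
        for g in cl.members:
            pred[g] = members
    true_groups: dict[str, set] = {}
    for g, fam in truth.gene_family.items():
        true_groups.setdefault(fam, set()).add(g)
    ok = total = 0
    for genome in dataset.values():
        for gene in genome.genes:
            g = gene.gene_id
            want = frozenset(true_groups[truth.gene_family[g]])
            if len(want) == 1:
                ok += g not in pred
            else:
                ok += pred.get(g) == want
            total += 1
    return 100.0 * ok / total


def planted_recovery(seed: int = 1) -> dict:
    """Full pipeline on the standard synthetic pan-genome (~3,000 genes).

    Simulates five varieties with planted families, tandem arrays and
    duplicated blocks; runs similarity search, Markov clustering,
    core/dispensable classification and duplication-origin labelling; and
    scores each stage against the planted truth.
    """
    from .duplication import (
        anchors_from_pairs,
        classify_duplication_origin,
        collinear_blocks,
        detect_tandem_arrays,
        self_homolog_pairs,
    )
    from .orthology import SimilarityGraph, mcl_cluster, pairwise_similarity
    from .pangenome import classify_clusters, membership_matrix

    config = SimulationConfig(seed=seed).with_default_duplications()
    dataset, truth = simulate_pangenome(config)
    proteins, species = {}, {}
    for v, genome in dataset.items():
        for gene in genome.genes:
            proteins[gene.gene_id] = gene.protein
            species[gene.gene_id] = v

    edges = pairwise_similarity(proteins)
    graph = SimilarityGraph.build(edges, species)
    clusters, unclustered, _ = mcl_cluster(graph)
    cluster_recovery = _pipeline_cluster_recovery(dataset, truth, clusters, unclustered)

    # core/dispensable classification, given the clusters just recovered
    panel = sorted(dataset)
    matrix = membership_matrix(clusters, species, panel)
    labels = classify_clusters(matrix, panel)
    agree = total = 0
    for cl in clusters:
        fams = {truth.gene_family[g] for g in cl.members}
        if len(fams) != 1:
            total += 1
            continue
        # a variety-specific gene duplicated within its genome forms a real
        # single-variety cluster: like any non-core cluster, dispensable
        want = "core" if truth.family_labels[fams.pop()] == "core" else "dispensable"
        agree += labels[cl.cluster_id] == want
        total += 1
    classification_accuracy = 100.0 * agree / total if total else 0.0

    # duplication recovery per variety
    arrays_ok = arrays_total = 0
    blocks_ok = blocks_total = 0
    origin_ok = origin_total = 0
    for v in panel:
        genome = dataset[v]
        pairs = self_homolog_pairs(genome.proteins(), evalue_cutoff=1e-20)
        order = genome.gene_order()
        arrays = detect_tandem_arrays(pairs, order, max_gap=1)
        found = {tuple(a.members) for a in arrays}
        for planted in truth.td_arrays[v]:
            arrays_total += 1
            arrays_ok += tuple(planted) in found
        blocks = []
        for anchor_list in anchors_from_pairs(pairs, order, order).values():
            blocks += collinear_blocks(anchor_list, min_block=15, max_gap=1)
        anchor_sets = {frozenset(b.anchors) for b in blocks}
        blocks_total += 1
        blocks_ok += frozenset(truth.wgd_anchors[v]) in anchor_sets
        origin = classify_duplication_origin(
            [g.gene_id for g in genome.genes], arrays, blocks
        )
        for g, lab in origin.items():
            origin_total += 1
            origin_ok += lab == truth.gene_origin[g]

    return {
        "n_genes": len(proteins),
        "cluster_recovery_pct": round(cluster_recovery, 2),
        "classification_accuracy_pct": round(classification_accuracy, 2),
        "td_array_recovery_pct": round(100.0 * arrays_ok / arrays_total, 2),
        "wgd_block_recovery_pct": round(100.0 * blocks_ok / blocks_total, 2),
        "origin_label_accuracy_pct": round(100.0 * origin_ok / origin_total, 2),
    }


def lrt_type1(seed: int = 1, n_replicates: int = 200, n_codons: int = 666,
              alpha: float = 0.01) -> dict:
    """Type-I error of the branch-model LRT under the null.

    Simulates alignments with one omega on every branch, fits M0 and the
    two-ratio model, and reports the fraction of replicates with
    p < alpha.
    """
    from .selection import fit_model, lrt

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        aln = simulate.simulate_alignment(CALIB_TREE, n_codons, omega_map=0.2, seed=s)
        h0 = fit_model(aln, CALIB_TREE_TAGGED, "M0")
        h1 = fit_model(aln, CALIB_TREE_TAGGED, "branch_2ratio")
        hits += lrt(h0.lnL, h1.lnL, 1) < alpha
    rate = hits / n_replicates
    se = float(np.sqrt(alpha * (1 - alpha) / n_replicates))
    return {
        "type1_error_rate": rate,
        "n_replicates": n_replicates,
        "bound": alpha + 3 * se,
    }


def lrt_power(seed: int = 1, n_replicates: int = 50, n_codons: int = 1666,
              fg_omega: float = 0.8, bg_omega: float = 0.2,
              alpha: float = 0.01) -> dict:
    """Power of the fast-evolving screen at a foreground/background omega
    contrast, using the full three-model decision rule with BH correction
    across the replicate batch."""
    from .selection import classify_fast_evolving, fit_model

    rng = np.random.default_rng(seed)
    fits = {}
    for k in range(n_replicates):
        s = int(rng.integers(0, 2**31 - 1))
        aln = simulate.simulate_alignment(
            CALIB_TREE,
            n_codons,
            omega_map={"default": bg_omega, CALIB_FOREGROUND: fg_omega},
            seed=s,
        )
        fits[f"rep{k:03d}"] = {
            "H0": fit_model(aln, CALIB_TREE_TAGGED, "M0"),
            "H1": fit_model(aln, CALIB_TREE_TAGGED, "branch_2ratio"),
            "H2": fit_model(aln, CALIB_TREE_TAGGED, "branch_free"),
        }
    calls = classify_fast_evolving(fits, alpha=alpha)
    return {
        "power_pct": float(round(100.0 * calls["fast_evolving"].mean(), 2)),
        "n_replicates": n_replicates,
    }


def omega_recovery(seed: int = 1, n_replicates: int = 10,
                   n_codons: int = 3333, true_omegas=(0.2, 1.0, 2.0)) -> dict:
    """M0 omega recovery on two-taxon alignments (10 kb) at several true
    omegas; returns the mean estimate and 3-SE band check per omega."""
    from .selection import fit_model

    rng = np.random.default_rng(seed)
    out = {}
    for true_omega in true_omegas:
        ests = []
        for _ in range(n_replicates):
            s = int(rng.integers(0, 2**31 - 1))
            aln = simulate.simulate_alignment(
                "(a:0.1,b:0.1);", n_codons, omega_map=true_omega, seed=s
            )
            res = fit_model(aln, "(a:0.1,b:0.1);", "M0")
            ests.append(float(res.omega_estimates["all"]))
        mean = float(np.mean(ests))
        se = float(np.std(ests, ddof=1) / np.sqrt(len(ests)))
        out[true_omega] = {
            "mean": round(mean, 4),
            "se": round(se, 4),
            "within_3se": bool(abs(mean - true_omega) <= 3 * max(se, 1e-3)),
        }
    return out


def phylogeny_recovery(seed: int = 1, n_sites: int = 20_000,
                       n_dating_replicates: int = 20) -> dict:
    """Topology and divergence-time recovery on the 12-taxon panel analog.

    Topology: GTR data are simulated on the clock tree, distances +
    neighbor joining re-estimate the tree, and the Robinson-Foulds
    distance to the truth is reported. Dating: clock-like trees whose ages
    and rate are randomly rescaled per replicate are dated with the single
    monocot-analog interval calibration (40-53 MY around a true 46-MY
    node, scaled along), and the worst relative node-age error across
    replicates is reported. With one interval calibration and clock-like
    data the rate is identified only up to the interval, so this measures
    how the least-squares solver resolves that ridge, not sequence noise.
    """
    import dendropy
    from dendropy.calculate import treecompare

    from .phylo import gtr_distances, nj_tree, root_with, strict_clock_dating
    from ._trees import parse_newick

    nwk, true_ages = simulate.panel_tree(rate=0.002)
    aln = simulate.simulate_gtr_alignment(nwk, n_sites, seed=seed)
    tree = nj_tree(gtr_distances(aln))
    true = dendropy.Tree.get(
        data=nwk, schema="newick", taxon_namespace=tree.taxon_namespace
    )
    tree.encode_bipartitions()
    true.encode_bipartitions()
    rf = int(treecompare.symmetric_difference(tree, true))

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_dating_replicates):
        age_scale = float(rng.uniform(0.7, 1.3))
        rate = float(rng.uniform(0.001, 0.004))
        rep_nwk, rep_ages = simulate.panel_tree(rate=rate)
        rep_tree = parse_newick(rep_nwk)
        for e in rep_tree.preorder_edge_iter():
            if e.length:
                e.length *= age_scale
        calib = {
            frozenset({"osa", "zma"}): (40.0 * age_scale, 53.0 * age_scale)
        }
        dated = strict_clock_dating(rep_tree, calib)
        for clade, age in rep_ages.items():
            if len(clade) > 1:
                worst = max(
                    worst, abs(dated.ages[clade] - age * age_scale) / (age * age_scale)
                )
    calib = {frozenset({"osa", "zma"}): (40.0, 53.0)}
    # variety-clade ages from the sequence-estimated tree, for reference
    rooted = root_with(tree, ["osa", "zma"])
    dated_seq = strict_clock_dating(rooted, calib)
    swetha_split = dated_seq.ages[
        frozenset({"zz13", "yz11", "bzm", "mszm", "swetha"})
    ]
    return {
        "nj_rf_distance": rf,
        "dating_max_rel_error_pct": round(100.0 * worst, 3),
        "variety_crown_age_my": round(float(swetha_split), 2),
    }
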