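"""Alignment, column filtering, distances, NJ, fourfold sites, dating."""

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from panforge._trees import parse_newick
from panforge.errors import ConfigurationError, InputError
from panforge.phylo import (
    align_family,
    concatenate_alignments,
    filter_columns,
    fourfold_sites,
    gtr_distances,
    nj_tree,
    root_with,
    strict_clock_dating,
)
from panforge.simulate import (
    panel_tree,
    simulate_alignment,
    simulate_gtr_alignment,
)


class TestAlignFamily:
    def test_identical_sequences_unchanged(self):
        cds = "ATGGCTGAAACCGTT"
        out = align_family({"a": cds, "b": cds})
        assert out == {"a": cds, "b": cds}

    def test_extra_codon_gives_single_codon_gap(self):
        out = align_family({"a": "ATGGCTGCAAAA", "b": "ATGGCTAAA"})
        assert len(out["a"]) == 12
        assert out["a"] == "ATGGCTGCAAAA"
        assert out["b"].count("-") == 3
        assert "---" in out["b"]

    def test_simulator_output_passes_through(self):
        aln = simulate_alignment("((a:0.05,b:0.05):0.02,c:0.08);", 100, seed=4)
        assert align_family(aln) == aln

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError):
            align_family({"a": "ATGTAAGCT", "b": "ATGGCTGCT"})


class TestFilterColumns:
    def test_identity_on_clean_conserved_matrix(self):
        m = {"a": "AAAA", "b": "AAAA", "c": "AAAT"}
        out, kept = filter_columns(m)
        assert out == m and kept == [0, 1, 2, 3]

    def test_gap_column_removed_by_default(self):
        m = {"a": "A-CG", "b": "AACG", "c": "AACG"}
        out, kept = filter_columns(m)
        assert kept == [0, 2, 3]
        assert out["a"] == "ACG"

    def test_low_conservation_column_removed(self):
        m = {"a": "ACCC", "b": "CCCC", "c": "GCCC", "d": "TCCC"}
        out, kept = filter_columns(m, min_conservation=0.5)
        assert kept == [1, 2, 3]

    def test_refiltering_idempotent(self):
        rng = np.random.default_rng(1)
        m = {
            t: "".join(rng.choice(list("ACGT-"), size=60, p=[0.3, 0.2, 0.2, 0.25, 0.05]))
            for t in "abcd"
        }
        out1, _ = filter_columns(m)
        out2, kept2 = filter_columns(out1)
        assert out1 == out2
        assert kept2 == list(range(len(next(iter(out1.values())))))

    def test_matches_column_rule_oracle(self):
        rng = np.random.default_rng(2)
        m = {
            t: "".join(rng.choice(list("ACGT-"), size=100))
            for t in "abcde"
        }
        _, kept = filter_columns(m, max_gap_fraction=0.2, min_conservation=0.5)
        taxa = sorted(m)
        want = []
        for j in range(100):
            col = [m[t][j] for t in taxa]
            gaps = col.count("-")
            if gaps / len(col) > 0.2:
                continue
            residues = [c for c in col if c != "-"]
            top = max(residues.count(c) for c in set(residues))
            if top / len(residues) < 0.5:
                continue
            want.append(j)
        assert kept == want

    def test_all_removed_is_error(self):
        with pytest.raises(InputError):
            filter_columns({"a": "-", "b": "A"})


class TestGtrDistances:
    def test_identical_sequences_zero(self):
        D = gtr_distances({"a": "ACGTACGT" * 10, "b": "ACGTACGT" * 10})
        assert D.loc["a", "b"] == 0.0

    def test_symmetry_and_zero_diagonal(self):
        aln = simulate_gtr_alignment("(a:0.1,(b:0.05,c:0.07):0.03);", 2000, seed=3)
        D = gtr_distances(aln)
        assert np.allclose(D.values, D.values.T)
        assert np.all(np.diag(D.values) == 0)

    def test_recovers_simulated_distance(self):
        ests = []
        for seed in range(6):
            aln = simulate_gtr_alignment(
                "(a:0.1,b:0.1);", 100_000,
                rates=(1.2, 3.0, 0.8, 1.1, 2.5, 1.0),
                base_freqs=(0.3, 0.2, 0.2, 0.3), seed=20 + seed,
            )
            ests.append(gtr_distances(aln).loc["a", "b"])
        mean, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(6)
        assert abs(mean - 0.2) <= 3 * max(se, 0.002)


class TestNJ:
    def test_additive_four_taxon_topology(self):
        # distances from tree ((a:1,b:2):1,(c:3,d:4):1)
        import pandas as pd

        D = pd.DataFrame(
            [
                [0, 3, 6, 7],
                [3, 0, 7, 8],
                [6, 7, 0, 7],
                [7, 8, 7, 0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
            dtype=float,
        )
        tree = nj_tree(D)
        true = parse_newick("((a:1,b:2):1,(c:3,d:4):1);", rooted=False)
        true.migrate_taxon_namespace(tree.taxon_namespace)
        tree.encode_bipartitions()
        true.encode_bipartitions()
        assert treecompare.symmetric_difference(tree, true) == 0

    def test_three_taxon_siblings(self):
        import pandas as pd

        D = pd.DataFrame(
            [[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]],
            index=list("abc"), columns=list("abc"),
        )
        tree = root_with(nj_tree(D), "c")
        mrca_ab = tree.mrca(taxon_labels=["a", "b"])
        assert {lf.taxon.label for lf in mrca_ab.leaf_iter()} == {"a", "b"}

    def test_nonsymmetric_matrix_rejected(self):
        import pandas as pd

        D = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 2], [2, 2, 0]],
            index=list("abc"), columns=list("abc"),
        )
        with pytest.raises(InputError):
            nj_tree(D)

    def test_twelve_taxon_panel_recovery(self):
        nwk, _ = panel_tree(rate=0.002)
        aln = simulate_gtr_alignment(nwk, 20_000, seed=6)
        tree = nj_tree(gtr_distances(aln))
        true = dendropy.Tree.get(
            data=nwk, schema="newick", taxon_namespace=tree.taxon_namespace
        )
        tree.encode_bipartitions()
        true.encode_bipartitions()
        assert treecompare.symmetric_difference(tree, true) == 0
        # the Indian lineage is basal within the variety clade
        rooted = root_with(tree, ["osa", "zma"])
        ses = rooted.mrca(
            taxon_labels=["zz13", "yz11", "bzm", "mszm", "swetha"]
        )
        children = {
            frozenset(lf.taxon.label for lf in c.leaf_iter())
            for c in ses.child_nodes()
        }
        assert frozenset({"swetha"}) in children


class TestFourfoldSites:
    def test_alanine_box_extracted(self):
        m = {"a": "GCT", "b": "GCC", "c": "GCA"}
        out = fourfold_sites(m)
        assert out == {"a": "T", "b": "C", "c": "A"}

    def test_twofold_site_excluded(self):
        m = {"a": "AAA", "b": "AAG"}
        assert fourfold_sites(m) == {"a": "", "b": ""}

    def test_differing_prefix_excluded(self):
        m = {"a": "GCTTTA", "b": "GGTTTA"}
        out = fourfold_sites(m)
        assert out["a"] == "" and out["b"] == ""

    def test_matches_code_table_oracle(self):
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        rng = np.random.default_rng(8)
        aln = simulate_alignment("(a:0.2,b:0.2);", 300, seed=9)
        got = fourfold_sites(aln)
        want = {"a": [], "b": []}
        for i in range(0, len(aln["a"]), 3):
            ca, cb = aln["a"][i : i + 3], aln["b"][i : i + 3]
            if ca[:2] != cb[:2]:
                continue
            fam = {table.forward_table.get(ca[:2] + n) for n in "ACGT"}
            if None in fam or len(fam) != 1:
                continue
            want["a"].append(ca[2])
            want["b"].append(cb[2])
        assert got == {t: "".join(v) for t, v in want.items()}


class TestStrictClockDating:
    def test_consistent_clock_recovered(self):
        nwk, ages = panel_tree(rate=0.002)
        dated = strict_clock_dating(
            parse_newick(nwk), {frozenset({"osa", "zma"}): (40.0, 53.0)}
        )
        for clade, true_age in ages.items():
            if len(clade) > 1:
                assert dated.ages[clade] == pytest.approx(true_age, rel=0.05)

    def test_ultrametric_and_calibration_respected(self):
        nwk, _ = panel_tree(rate=0.002)
        calib = {
            frozenset({"osa", "zma"}): (40.0, 53.0),
            frozenset({"vvi", "ath"}): (110.0, 124.0),
        }
        dated = strict_clock_dating(parse_newick(nwk), calib)
        for taxa, (lo, hi) in calib.items():
            mrca_age = min(
                age for clade, age in dated.ages.items() if taxa <= clade
            )
            assert lo - 1e-6 <= mrca_age <= hi + 1e-6
        # parent older than child throughout
        for node in dated.tree.preorder_node_iter():
            for child in node.child_nodes():
                assert child.age <= node.age + 1e-9

    def test_scale_invariance(self):
        nwk, _ = panel_tree(rate=0.002)
        calib = {frozenset({"osa", "zma"}): (40.0, 53.0)}
        d1 = strict_clock_dating(parse_newick(nwk), calib)
        t2 = parse_newick(nwk)
        for e in t2.preorder_edge_iter():
            if e.length:
                e.length *= 2.5
        d2 = strict_clock_dating(t2, calib)
        assert d2.rate == pytest.approx(2.5 * d1.rate, rel=1e-6)
        for clade, age in d1.ages.items():
            assert d2.ages[clade] == pytest.approx(age, abs=1e-6)

    def test_noisy_clock_recovery_over_replicates(self):
        """Clock-like trees with mild branch-length noise: ages recovered
        within 5% across replicates (root 66 MY analog)."""
        rng = np.random.default_rng(10)
        base, ages = panel_tree(rate=0.002)
        worst = 0.0
        for rep in range(20):
            tree = parse_newick(base)
            for e in tree.preorder_edge_iter():
                if e.length:
                    e.length *= float(rng.normal(1.0, 0.01))
            dated = strict_clock_dating(
                tree, {frozenset({"osa", "zma"}): (40.0, 53.0)}
            )
            clade66 = frozenset(
                {"zz13", "yz11", "bzm", "mszm", "swetha", "ugibba"}
            )
            worst = max(
                worst, abs(dated.ages[clade66] - 66.1) / 66.1
            )
        assert worst <= 0.05

    def test_no_calibration_rejected(self):
        nwk, _ = panel_tree()
        with pytest.raises(ConfigurationError):
            strict_clock_dating(parse_newick(nwk), {})

    def test_infeasible_calibrations_rejected(self):
        nwk, _ = panel_tree()
        calib = {
            frozenset({"zz13", "yz11"}): (70.0, 80.0),  # child...
            frozenset({"zz13", "yz11", "bzm", "mszm", "swetha", "ugibba"}):
                (50.0, 60.0),  # ...required older than its ancestor allows
        }
        with pytest.raises(ConfigurationError):
            strict_clock_dating(parse_newick(nwk), calib)


def test_concatenate_alignments_offsets():
    a1 = {"a": "ATGGCT", "b": "ATGGCT"}
    a2 = {"a": "GCTGCTGCT", "b": "GCAGCAGCA"}
    matrix, offsets = concatenate_alignments([a1, a2])
    assert matrix["a"] == "ATGGCTGCTGCTGCT"
    assert offsets == {0: (0, 6), 1: (6, 15)}


def test_dated_tree_newick_carries_ages():
    nwk, _ = panel_tree(rate=0.002)
    dated = strict_clock_dating(
        parse_newick(nwk), {frozenset({"osa", "zma"}): (40.0, 53.0)}
    )
    text = dated.to_newick()
    assert text.endswith(";") and "[&age=" in text
    # the largest annotated age is the root age
    import re

    ages = [float(m) for m in re.findall(r"\[&age=([0-9.]+)\]", text)]
    root_clade = max(dated.ages, key=len)
    assert max(ages) == pytest.approx(dated.ages[root_clade], abs=1e-3)
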