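"""Core/dispensable classification, composition arithmetic, region partition."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from panforge.errors import InputError
from panforge.pangenome import (
    RegionBlock,
    classify_clusters,
    group_unique_sets,
    membership_matrix,
    pangenome_composition,
    partition_genome_regions,
)

PANEL = ["v1", "v2", "v3", "v4", "v5"]


def _matrix(rows: dict):
    return pd.DataFrame.from_dict(rows, orient="index", columns=PANEL).fillna(0)


class TestClassifyClusters:
    def test_all_present_is_core(self):
        labels = classify_clusters(_matrix({"c1": dict(zip(PANEL, [1] * 5))}), PANEL)
        assert labels == {"c1": "core"}

    def test_single_variety_is_dispensable(self):
        labels = classify_clusters(
            _matrix({"c1": dict(zip(PANEL, [2, 0, 0, 0, 0]))}), PANEL
        )
        assert labels == {"c1": "dispensable"}

    def test_all_presence_patterns_exhaustive(self):
        rows = {}
        patterns = []
        k = 0
        for r in range(1, 6):
            for subset in combinations(range(5), r):
                counts = [1 if i in subset else 0 for i in range(5)]
                rows[f"c{k}"] = dict(zip(PANEL, counts))
                patterns.append(tuple(counts))
                k += 1
        labels = classify_clusters(_matrix(rows), PANEL)
        n_core = sum(1 for v in labels.values() if v == "core")
        assert len(labels) == 31 and n_core == 1

    def test_empty_panel_rejected(self):
        with pytest.raises(InputError):
            classify_clusters(_matrix({"c1": dict(zip(PANEL, [1] * 5))}), [])

    def test_monotonicity_growing_panel(self):
        rng = np.random.default_rng(6)
        rows = {
            f"c{i}": dict(zip(PANEL, (rng.random(5) < 0.6).astype(int)))
            for i in range(50)
        }
        m = _matrix(rows)
        m = m[(m > 0).any(axis=1)]
        core_counts = []
        for k in range(1, 6):
            labels = classify_clusters(
                m[(m[PANEL[:k]] > 0).any(axis=1)], PANEL[:k]
            )
            core_counts.append(sum(1 for v in labels.values() if v == "core"))
        assert core_counts == sorted(core_counts, reverse=True)


class TestComposition:
    def test_printed_percentages_reproduced(self):
        """The classifier's arithmetic on a 15,409-core / 11,063-dispensable
        cluster set yields the published 58.21% / 41.79% split."""
        labels = {f"c{i}": "core" for i in range(15_409)}
        labels.update({f"d{i}": "dispensable" for i in range(11_063)})
        s = pangenome_composition(labels)
        assert s.n_clusters_total == 26_472
        assert s.pct_core == 58.21
        assert s.pct_dispensable == 41.79

    def test_degenerate_single_core(self):
        s = pangenome_composition({"c": "core"})
        assert s.pct_core == 100.0 and s.pct_dispensable == 0.0

    def test_per_variety_counts_include_unclustered(self):
        m = _matrix(
            {
                "c1": dict(zip(PANEL, [1, 1, 1, 1, 1])),
                "c2": dict(zip(PANEL, [2, 1, 0, 0, 0])),
            }
        )
        labels = classify_clusters(m, PANEL)
        s = pangenome_composition(labels, m, {"v1": 3})
        assert s.per_variety_core_genes["v1"] == 1
        assert s.per_variety_dispensable_genes["v1"] == 2 + 3
        assert s.n_variety_specific_genes == 3

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(8)
        labels = {
            f"c{i}": ("core" if rng.random() < 0.4 else "dispensable")
            for i in range(997)
        }
        s = pangenome_composition(labels)
        assert s.pct_core + s.pct_dispensable == pytest.approx(100.0, abs=0.01)


class TestRegionPartition:
    def test_all_shared_block_is_core(self):
        blk = RegionBlock("b1", {v: ("chr1", 0, 100) for v in PANEL})
        out = partition_genome_regions([blk], {v: 100 for v in PANEL}, PANEL)
        assert out == {"core_bp": 100, "dispensable_bp": 0, "pan_bp": 100}

    def test_subset_shared_block_is_dispensable(self):
        blk = RegionBlock("b1", {v: ("chr1", 0, 100) for v in PANEL[:2]})
        genome_lengths = {v: (100 if v in PANEL[:2] else 0) for v in PANEL}
        out = partition_genome_regions([blk], genome_lengths, PANEL)
        assert out == {"core_bp": 0, "dispensable_bp": 100, "pan_bp": 100}

    def test_unaligned_sequence_counted_dispensable(self):
        blk = RegionBlock("b1", {v: ("chr1", 0, 100) for v in PANEL})
        out = partition_genome_regions([blk], {v: 150 for v in PANEL}, PANEL)
        assert out["core_bp"] == 100
        assert out["dispensable_bp"] == 5 * 50
        assert out["pan_bp"] == out["core_bp"] + out["dispensable_bp"]

    def test_planted_lengths_recovered(self):
        rng = np.random.default_rng(10)
        blocks, lengths = [], {v: 0 for v in PANEL}
        planted_core = planted_disp = 0
        pos = {v: 0 for v in PANEL}
        for i in range(30):
            shared = PANEL if rng.random() < 0.5 else list(
                rng.choice(PANEL, size=rng.integers(1, 5), replace=False)
            )
            width = int(rng.integers(50, 500))
            spans = {}
            for v in shared:
                spans[v] = ("chr1", pos[v], pos[v] + width)
                pos[v] += width
            blocks.append(RegionBlock(f"b{i}", spans))
            if set(shared) == set(PANEL):
                planted_core += width
            else:
                planted_disp += width
        lengths = {v: pos[v] for v in PANEL}
        out = partition_genome_regions(blocks, lengths, PANEL)
        assert out["core_bp"] == planted_core
        assert out["dispensable_bp"] == planted_disp

    def test_block_exceeding_genome_rejected(self):
        blk = RegionBlock("b1", {"v1": ("chr1", 0, 200)})
        with pytest.raises(InputError):
            partition_genome_regions([blk], {v: 100 for v in PANEL}, PANEL)


class TestGroupUniqueSets:
    CULTIVARS = ["v1", "v2", "v3"]
    LANDRACES = ["v4", "v5"]

    def test_single_cultivar_family_unique_to_cultivars(self):
        m = _matrix({"c1": dict(zip(PANEL, [1, 0, 0, 0, 0]))})
        out = group_unique_sets(m, {}, self.CULTIVARS, self.LANDRACES)
        assert out["families_unique_to_a"] == ["c1"]
        assert out["families_unique_to_b"] == []

    def test_shared_family_unique_to_neither(self):
        m = _matrix({"c1": dict(zip(PANEL, [1, 0, 0, 1, 0]))})
        out = group_unique_sets(m, {}, self.CULTIVARS, self.LANDRACES)
        assert out["families_unique_to_a"] == []
        assert out["families_unique_to_b"] == []

    def test_overlapping_groups_rejected(self):
        m = _matrix({"c1": dict(zip(PANEL, [1, 0, 0, 0, 0]))})
        with pytest.raises(InputError):
            group_unique_sets(m, {}, ["v1", "v2"], ["v2", "v3"])

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(12)
        rows = {
            f"c{i:03d}": dict(zip(PANEL, (rng.random(5) < 0.4).astype(int)))
            for i in range(100)
        }
        m = _matrix(rows)
        m = m[(m > 0).any(axis=1)]
        unc = {v: int(rng.integers(0, 20)) for v in PANEL}
        out = group_unique_sets(m, unc, self.CULTIVARS, self.LANDRACES)
        want_a, want_b = [], []
        for cid, counts in m.iterrows():
            in_a = any(counts[v] > 0 for v in self.CULTIVARS)
            in_b = any(counts[v] > 0 for v in self.LANDRACES)
            if in_a and not in_b:
                want_a.append(cid)
            if in_b and not in_a:
                want_b.append(cid)
        assert out["families_unique_to_a"] == sorted(want_a)
        assert out["families_unique_to_b"] == sorted(want_b)
        assert out["specific_genes_in_a"] == sum(unc[v] for v in self.CULTIVARS)
        assert out["specific_genes_in_b"] == sum(unc[v] for v in self.LANDRACES)


def test_membership_matrix_from_clusters():
    from panforge.orthology import OrthoCluster

    clusters = [
        OrthoCluster("c1", ("a1", "b1"), ("A", "B")),
        OrthoCluster("c2", ("a2", "a3"), ("A",)),
    ]
    species = {"a1": "A", "b1": "B", "a2": "A", "a3": "A"}
    m = membership_matrix(clusters, species, ["A", "B"])
    assert m.loc["c1", "A"] == 1 and m.loc["c1", "B"] == 1
    assert m.loc["c2", "A"] == 2 and m.loc["c2", "B"] == 0


def test_read_blocks_maf(tmp_path):
    from panforge.pangenome import read_blocks_maf

    maf = tmp_path / "blocks.maf"
    maf.write_text(
        "##maf version=1\n"
        "a score=100.0\n"
        "s zz13.chr1 100 50 + 10000 ACGT\n"
        "s yz11.chr1 200 50 + 12000 ACGT\n"
        "s bzm.chr2 50 50 - 500 ACGT\n"
        "\n"
        "a score=10.0\n"
        "s zz13.chr2 0 30 + 900 ACGT\n"
    )
    b1, b2 = read_blocks_maf(maf)
    assert b1.spans["zz13"] == ("chr1", 100, 150)
    # minus strand converted to forward coordinates: 500 - 50 - 50 = 400
    assert b1.spans["bzm"] == ("chr2", 400, 450)
    assert b1.present_in == frozenset({"zz13", "yz11", "bzm"})
    assert b2.length == 30
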