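"""Codon models: rate matrix, pruning likelihood, fits, NG86, LRT screens."""

import numpy as np
import pytest

from panforge import _codon
from panforge.errors import ConfigurationError, InputError
from panforge.selection import (
    CodonModel,
    bh_adjust,
    build_codon_matrix,
    classify_fast_evolving,
    classify_positively_selected,
    combine_calls,
    fit_model,
    lrt,
    ng86_dnds,
    pruning_loglikelihood,
)
from panforge.simulate import simulate_alignment
from _oracles import ng86_counts

TREE = "(((a:0.05,b:0.05):0.15,c:0.08):0.05,d:0.1,e:0.13);"
TAGGED = "(((a:0.05,b:0.05)#1:0.15,c:0.08):0.05,d:0.1,e:0.13);"
FG = frozenset({"a", "b"})


class TestRateMatrix:
    PI = _codon.f1x4_frequencies((0.3, 0.2, 0.3, 0.2))

    def test_symmetric_limit_all_single_step_rates_equal(self):
        pi = np.ones(61) / 61
        Q = build_codon_matrix(1.0, 1.0, pi, scale=False)
        off = Q[(Q > 0)]
        assert np.allclose(off, off[0])

    def test_purifying_limit_zero_nonsyn_rates(self):
        Q = build_codon_matrix(2.0, 0.0, self.PI)
        for i, ci in enumerate(_codon.CODONS):
            for j, cj in enumerate(_codon.CODONS):
                if i != j and Q[i, j] > 0:
                    assert _codon.CODON_AA[ci] == _codon.CODON_AA[cj]

    def test_row_sums_zero_and_unit_scaling(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            kappa = float(rng.uniform(0.5, 8))
            omega = float(rng.uniform(0.05, 3))
            raw = rng.dirichlet(np.ones(61))
            Q = build_codon_matrix(kappa, omega, raw)
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
            assert -(raw * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            build_codon_matrix(2.0, 0.5, np.ones(61))


class TestPruning:
    def test_single_taxon_closed_form(self):
        aln = {"a": "ATGGCTAAACCC"}
        pi = _codon.empirical_codon_frequencies([aln["a"]], "F1x4")
        lnL = pruning_loglikelihood(aln, "a;", 2.0, 0.5, codon_frequencies=pi)
        states = _codon.encode_codons(aln["a"])
        assert lnL == pytest.approx(float(np.sum(np.log(pi[states]))))

    def test_two_identical_sequences_at_tiny_t(self):
        cds = "ATGGCTAAACCCGTT"
        pi = _codon.empirical_codon_frequencies([cds], "F1x4")
        single = float(np.sum(np.log(pi[_codon.encode_codons(cds)])))
        lnL = pruning_loglikelihood(
            {"a": cds, "b": cds}, "(a:1e-9,b:1e-9);", 2.0, 0.5,
            codon_frequencies=pi,
        )
        assert lnL == pytest.approx(single, abs=1e-4)

    def test_matches_bruteforce_marginalization(self):
        """Three-taxon, few-codon toys: pruning equals explicit summation
        over all internal-state assignments."""
        from _oracles import pruning_bruteforce

        rng = np.random.default_rng(1)
        for rep in range(3):
            aln = simulate_alignment(
                "(a:0.1,b:0.2,c:0.15);", 3, seed=50 + rep
            )
            pi = _codon.empirical_codon_frequencies(aln.values(), "F3x4")
            kappa, omega = float(rng.uniform(1, 4)), float(rng.uniform(0.1, 2))
            eig = _codon.CodonEigen(kappa, omega, pi)
            P = {
                "a": eig.transition_matrix(0.1),
                "b": eig.transition_matrix(0.2),
                "c": eig.transition_matrix(0.15),
            }
            want = pruning_bruteforce(aln, None, pi, P, _codon.CODON_INDEX)
            got = pruning_loglikelihood(
                aln, "(a:0.1,b:0.2,c:0.15);", kappa, omega,
                codon_frequencies=pi,
            )
            assert got == pytest.approx(want, abs=1e-9)

    def test_gap_codons_treated_as_missing(self):
        aln = {"a": "ATGGCT---", "b": "ATGGCTAAA", "c": "ATGGCTAAA"}
        lnL = pruning_loglikelihood(aln, "(a:0.1,b:0.1,c:0.1);", 2.0, 0.5)
        assert np.isfinite(lnL)


class TestFits:
    def test_m0_recovers_simulated_omega(self):
        ests = []
        for rep in range(4):
            aln = simulate_alignment(TREE, 1666, omega_map=0.3, seed=70 + rep)
            res = fit_model(aln, TREE, "M0")
            assert res.converged
            ests.append(res.omega_estimates["all"])
        mean, se = np.mean(ests), np.std(ests, ddof=1) / np.sqrt(4)
        assert abs(mean - 0.3) <= 3 * max(se, 0.01)

    def test_m0_agrees_with_ng86_on_pairwise_subset(self):
        """Dual-route omega check (ML fit vs pathway counting), run in the
        regime where both estimators share assumptions (kappa = 1; NG86 has
        a known downward bias under transition enrichment)."""
        aln = simulate_alignment(TREE, 1666, kappa=1.0, omega_map=0.3, seed=99)
        res = fit_model(aln, TREE, "M0")
        counting = ng86_dnds(aln["a"], aln["c"])
        assert abs(res.omega_estimates["all"] - counting["omega"]) <= 0.15 * max(
            counting["omega"], res.omega_estimates["all"]
        )

    def test_nested_likelihood_ordering(self):
        aln = simulate_alignment(TREE, 400, omega_map=0.3, seed=77)
        h0 = fit_model(aln, TAGGED, "M0")
        h1 = fit_model(aln, TAGGED, "branch_2ratio")
        h2 = fit_model(aln, TAGGED, "branch_free")
        assert h0.lnL <= h1.lnL + 1e-4
        assert h1.lnL <= h2.lnL + 1e-4
        null = fit_model(aln, TAGGED, "branchsite_null")
        alt = fit_model(aln, TAGGED, "branchsite_alt")
        assert null.lnL <= alt.lnL + 1e-4

    def test_equal_omegas_under_null_two_ratio(self):
        aln = simulate_alignment(TREE, 1000, omega_map=0.25, seed=80)
        h0 = fit_model(aln, TAGGED, "M0")
        h1 = fit_model(aln, TAGGED, "branch_2ratio")
        assert h1.omega_estimates["foreground"] == pytest.approx(
            h1.omega_estimates["background"], abs=0.35
        )
        assert 2 * (h1.lnL - h0.lnL) < 6.0

    def test_missing_foreground_rejected(self):
        aln = simulate_alignment(TREE, 50, seed=81)
        with pytest.raises(ConfigurationError):
            CodonModel(aln, TREE, model="branch_2ratio")

    def test_summary_mentions_key_quantities(self):
        aln = simulate_alignment(TREE, 200, seed=82)
        res = fit_model(aln, TREE, "M0")
        text = res.summary()
        assert "lnL" in text and "kappa" in text and "omega" in text


class TestNG86:
    def test_identity_zero(self):
        out = ng86_dnds("ATGGCTAAA", "ATGGCTAAA")
        assert out["dN"] == 0.0 and out["dS"] == 0.0 and out["undefined"]

    def test_single_synonymous_change(self):
        out = ng86_dnds("TTT", "TTC")
        assert out["Sd"] == 1.0 and out["Nd"] == 0.0

    def test_matches_pathway_enumerator_oracle(self):
        rng = np.random.default_rng(3)
        codons = [c for c in _codon.CODONS]
        for _ in range(200):
            ca, cb = rng.choice(codons, size=2)
            sa, sb, sd, nd = ng86_counts(ca, cb)
            out = ng86_dnds(ca, cb)
            assert out["S"] == pytest.approx((sa + sb) / 2)
            assert out["Sd"] == pytest.approx(sd)
            assert out["Nd"] == pytest.approx(nd)

    def test_internal_stop_rejected(self):
        with pytest.raises(InputError):
            ng86_dnds("TAAGCT", "TTAGCT")


class TestLRT:
    def test_chi2_critical_value(self):
        assert lrt(0.0, 3.841 / 2, 1) == pytest.approx(0.05, abs=5e-4)

    def test_zero_statistic_p_one(self):
        assert lrt(-100.0, -100.0, 1) == 1.0

    def test_bad_df_rejected(self):
        with pytest.raises(InputError):
            lrt(0.0, 1.0, 0)

    def test_bh_monotone_in_raw_pvalues(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestScreens:
    @pytest.fixture(scope="class")
    def null_families(self):
        fits = {}
        for k in range(4):
            aln = simulate_alignment(TREE, 400, omega_map=0.2, seed=500 + k)
            fits[f"fam{k}"] = {
                "H0": fit_model(aln, TAGGED, "M0"),
                "H1": fit_model(aln, TAGGED, "branch_2ratio"),
                "H2": fit_model(aln, TAGGED, "branch_free"),
            }
        return fits

    def test_fast_evolving_detected_under_strong_signal(self):
        fits = {}
        for k in range(3):
            aln = simulate_alignment(
                TREE, 1000, omega_map={"default": 0.2, FG: 0.9}, seed=600 + k
            )
            fits[f"fam{k}"] = {
                "H0": fit_model(aln, TAGGED, "M0"),
                "H1": fit_model(aln, TAGGED, "branch_2ratio"),
                "H2": fit_model(aln, TAGGED, "branch_free"),
            }
        calls = classify_fast_evolving(fits, alpha=0.01)
        assert calls["fast_evolving"].mean() >= 2 / 3

    def test_null_families_mostly_not_called(self, null_families):
        calls = classify_fast_evolving(null_families, alpha=0.01)
        assert calls["fast_evolving"].sum() <= 1

    def test_direction_rule_blocks_slow_foreground(self):
        fits = {}
        aln = simulate_alignment(
            TREE, 1000, omega_map={"default": 0.8, FG: 0.1}, seed=700
        )
        fits["fam"] = {
            "H0": fit_model(aln, TAGGED, "M0"),
            "H1": fit_model(aln, TAGGED, "branch_2ratio"),
            "H2": fit_model(aln, TAGGED, "branch_free"),
        }
        calls = classify_fast_evolving(fits, alpha=0.5)
        row = calls.iloc[0]
        assert row.omega_foreground < row.omega_background
        assert not row.fast_evolving

    def test_branch_site_positive_selection_detected(self):
        classes = [
            (0.6, {"default": 0.1}),
            (0.2, {"default": 1.0}),
            (0.2, {"default": 0.1, FG: 6.0}),
        ]
        fits = {}
        for k in range(2):
            aln = simulate_alignment(
                TREE, 1200, site_classes=classes, seed=800 + k
            )
            fits[f"fam{k}"] = {
                "null": fit_model(aln, TAGGED, "branchsite_null"),
                "alt": fit_model(aln, TAGGED, "branchsite_alt"),
            }
        calls = classify_positively_selected(fits, alpha=0.01)
        assert calls["positively_selected"].sum() >= 1
        assert (calls["omega2"] > 1).all()

    def test_combined_calls_intersection(self):
        import pandas as pd

        fast = pd.DataFrame(
            {"family_id": ["f1", "f2", "f3"], "fast_evolving": [True, True, False]}
        )
        ps = pd.DataFrame(
            {
                "family_id": ["f1", "f2", "f3"],
                "positively_selected": [True, False, True],
            }
        )
        calls = combine_calls(fast, ps)
        assert dict(zip(calls.family_id, calls.call)) == {
            "f1": "both",
            "f2": "fast_evolving",
            "f3": "positively_selected",
        }
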