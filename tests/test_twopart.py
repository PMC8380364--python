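import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microlmp as m
from microlmp.twopart import meta_combine


class TestBinaryAssociation:
    def test_worked_example_matches_two_sample_t(self):
        fit = m.binary_association([1, 2, 3, 4], [0, 0, 1, 1])
        assert fit.beta1 == pytest.approx(2.0)
        # oracle: pooled-variance two-sample t with df = 2
        t_oracle = stats.ttest_ind([3, 4], [1, 2], equal_var=True)
        assert fit.p_binary == pytest.approx(t_oracle.pvalue, abs=1e-12)
        assert fit.p_binary == pytest.approx(0.1056, abs=2e-4)

    def test_equal_group_means_give_zero_effect(self):
        fit = m.binary_association([1.0, 3.0, 2.0, 2.0], [0, 0, 1, 1])
        assert fit.beta1 == pytest.approx(0.0)

    def test_single_class_undefined(self):
        fit = m.binary_association([1, 2, 3, 4], [1, 1, 1, 1])
        assert not fit.defined
        assert np.isnan(fit.beta1)


class TestQuantitativeAssociation:
    def test_constant_abundance_undefined(self):
        fit = m.quantitative_association([1, 2, 3, 4], [0.5, 0.5, 0.5, 0.5])
        assert not fit.defined

    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(1)
        ab = rng.uniform(0.01, 0.5, 10)
        y = 2.0 * np.log10(ab)
        fit = m.quantitative_association(y, ab)
        assert fit.p_quant < 1e-8
        assert fit.beta2 > 0

    def test_restricted_to_detected(self):
        # undetected samples' phenotypes must not influence the fit
        ab = np.array([0.0, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([999.0, -999.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        fit = m.quantitative_association(y, ab)
        y2 = y.copy()
        y2[:2] = 0.0
        fit2 = m.quantitative_association(y2, ab)
        assert fit.beta2 == pytest.approx(fit2.beta2)
        assert fit.n_used == 5

    def test_null_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            ab = rng.uniform(0.001, 0.1, 300)
            y = rng.standard_normal(300)
            ps.append(m.quantitative_association(y, ab).p_quant)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestMetaCombine:
    def test_single_part_identity(self):
        res = meta_combine([0.05], [+1])
        assert res.Z == pytest.approx(stats.norm.isf(0.025), abs=1e-4)
        assert res.p_meta == pytest.approx(0.05, abs=1e-9)

    def test_half_p_values(self):
        # p = 0.5 each: z_i = Phi^-1(0.75) = 0.6745
        res = meta_combine([0.5, 0.5], [+1, +1])
        assert res.Z == pytest.approx(2 * 0.674490 / np.sqrt(2), abs=1e-4)
        assert res.p_meta == pytest.approx(0.3402, abs=2e-4)
        res_opp = meta_combine([0.5, 0.5], [+1, -1])
        assert res_opp.Z == pytest.approx(0.0, abs=1e-12)
        assert res_opp.p_meta == pytest.approx(1.0)

    def test_concordant_small_p(self):
        res = meta_combine([0.05, 0.05], [+1, +1])
        assert res.Z == pytest.approx(2 * 1.959964 / np.sqrt(2), abs=1e-4)
        assert res.p_meta == pytest.approx(0.0056, abs=1e-4)

    def test_boundary_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = meta_combine([0.0, 1.0], [+1, +1])
        assert np.isfinite(res.Z)

    def test_literal_mode_is_sign_blind(self):
        res = meta_combine([0.05, 0.05], [+1, -1], signed=False)
        # literal z_i = Phi^-1(0.05) = -1.645 each regardless of direction
        assert res.Z == pytest.approx(2 * stats.norm.ppf(0.05) / np.sqrt(2), abs=1e-4)


class TestTwoPartScan:
    def test_always_present_taxon_skips_binary(self):
        cfg = m.SimulationConfig(
            n_samples=80, n_taxa=20, sequencing_depth=10_000,
            zero_inflation=0.0, seed=13,
        )
        table, tax, metadata, truth = m.simulate_dataset(cfg)
        md = m.adjust_phenotype(metadata)
        rel = m.to_relative(table)
        always = [t for t in rel.taxon_ids if (rel.data[t] > 0).all()]
        assert always, "dropout-free cohort should have an always-detected taxon"
        assoc = m.two_part_scan(rel, md)
        row = assoc.loc[always[0]]
        assert np.isnan(row["p_binary"]) and np.isnan(row["p_meta"])
        assert row["p_final"] == pytest.approx(row["p_quant"])

    def test_rowwise_consistency_with_single_taxon_functions(
        self, fixture_dataset, adjusted_metadata
    ):
        _, table, _, _, _ = fixture_dataset
        rel = m.to_relative(table)
        assoc = m.two_part_scan(rel, adjusted_metadata)
        y = adjusted_metadata.loc[rel.sample_ids, "adj_p"].to_numpy()
        for taxon in rel.taxon_ids[:10]:
            ab = rel.data[taxon].to_numpy()
            bfit = m.binary_association(y, ab > 0)
            qfit = m.quantitative_association(y, ab)
            row = assoc.loc[taxon]
            if bfit.defined:
                assert row["beta1"] == pytest.approx(bfit.beta1, abs=1e-10)
                assert row["p_binary"] == pytest.approx(bfit.p_binary, abs=1e-10)
            if qfit.defined:
                assert row["beta2"] == pytest.approx(qfit.beta2, abs=1e-10)
                assert row["p_quant"] == pytest.approx(qfit.p_quant, abs=1e-10)
            if bfit.defined and qfit.defined:
                mres = meta_combine(
                    [bfit.p_binary, qfit.p_quant],
                    [np.sign(bfit.beta1), np.sign(qfit.beta2)],
                )
                assert row["Z"] == pytest.approx(mres.Z, abs=1e-8)
                assert row["p_final"] == pytest.approx(
                    min(bfit.p_binary, qfit.p_quant, mres.p_meta), abs=1e-10
                )

    def test_sample_mismatch_rejected(self, fixture_dataset, adjusted_metadata):
        _, table, _, _, _ = fixture_dataset
        rel = m.to_relative(table)
        with pytest.raises(ValueError, match="mismatch"):
            m.two_part_scan(rel, adjusted_metadata.iloc[:-3])

    def test_min_p_is_anticonservative_under_null(self):
        # motivates the permutation calibration: min over three dependent
        # tests rejects more than alpha of the time
        rng = np.random.default_rng(3)
        frac = 0
        total = 0
        for rep in range(50):
            cfg = m.SimulationConfig(
                n_samples=150, n_taxa=50, sequencing_depth=5000,
                zero_inflation=0.3, seed=40000 + rep,
            )
            table, tax, metadata, truth = m.simulate_dataset(cfg)
            md = m.adjust_phenotype(metadata)
            assoc = m.two_part_scan(m.to_relative(table), md)
            frac += (assoc["p_final"] < 0.05).sum()
            total += len(assoc)
        assert frac / total > 0.05


class TestPermutationFdr:
    def test_determinism(self, fixture_dataset, adjusted_metadata):
        _, table, _, _, _ = fixture_dataset
        rel = m.filter_otus(m.to_relative(table), 0.0005, 0.01)
        assoc = m.two_part_scan(rel, adjusted_metadata)
        q1 = m.permutation_fdr(assoc, rel, adjusted_metadata, B=100, seed=5)
        q2 = m.permutation_fdr(assoc, rel, adjusted_metadata, B=100, seed=5)
        pd.testing.assert_series_equal(q1["q_perm"], q2["q_perm"])

    def test_monotone_in_p_final(self, fixture_dataset, adjusted_metadata):
        _, table, _, _, _ = fixture_dataset
        rel = m.filter_otus(m.to_relative(table), 0.0005, 0.01)
        assoc = m.two_part_scan(rel, adjusted_metadata)
        out = m.permutation_fdr(assoc, rel, adjusted_metadata, B=100, seed=5)
        s = out.sort_values("p_final")
        assert (np.diff(s["q_perm"].to_numpy()) >= -1e-12).all()
        assert (out["q_perm"] <= 1.0).all()

    def test_small_b_rejected(self, fixture_dataset, adjusted_metadata):
        _, table, _, _, _ = fixture_dataset
        rel = m.to_relative(table)
        assoc = m.two_part_scan(rel, adjusted_metadata)
        with pytest.raises(ValueError, match="B"):
            m.permutation_fdr(assoc, rel, adjusted_metadata, B=50)


class TestShannon:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([0, 7, 0], 0.0),
            ([0.5, 0.25, 0.25], 1.0397),
        ],
    )
    def test_values(self, vec, expected):
        assert m.shannon_index(vec) == pytest.approx(expected, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            m.shannon_index([0, 0])


class TestGroupCompare:
    def test_identical_groups_not_significant(self):
        stat, p = m.group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert p > 0.99

    def test_exact_minimal_p_for_three_vs_three(self):
        # complete separation, n=3 vs 3: exact two-sided p = 2/C(6,3) = 0.1
        _, p = m.group_compare([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_bh_step_up_worked_example(self):
        adj = m.bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            m.group_compare([1, 2, 3], ["a", "a", "a"])
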