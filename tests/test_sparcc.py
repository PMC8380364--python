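import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import microlmp as m
from microlmp.enterotype import DistanceMatrix
from microlmp.sparcc import correlation_dissimilarity


def _block_dataset(seed=0, rho=0.7, members=(0, 1, 2), n=500, d=30):
    cfg = m.SimulationConfig(
        n_samples=n, n_taxa=d, sequencing_depth=20_000, log_mean_sd=1.0,
        zero_inflation=0.0, correlation_blocks=[(list(members), rho)], seed=seed,
    )
    return m.simulate_counts(cfg)


class TestSparcc:
    def test_too_few_taxa_rejected(self):
        cfg = m.SimulationConfig(n_samples=30, n_taxa=3, sequencing_depth=1000, seed=0)
        table, _ = m.simulate_counts(cfg)
        with pytest.raises(ValueError, match="3 taxa"):
            m.sparcc(table)

    def test_planted_block_recovered(self):
        table, truth = _block_dataset(seed=1)
        res = m.sparcc(table, n_resamples=20, seed=2)
        r = res.rho.to_numpy()
        block = r[np.ix_([0, 1, 2], [0, 1, 2])][np.triu_indices(3, 1)]
        np.testing.assert_allclose(block, 0.7, atol=0.1)

    def test_independent_taxa_near_zero(self):
        cfg = m.SimulationConfig(
            n_samples=500, n_taxa=30, sequencing_depth=20_000,
            log_mean_sd=1.0, zero_inflation=0.0, seed=3,
        )
        table, _ = m.simulate_counts(cfg)
        res = m.sparcc(table, n_resamples=20, seed=4)
        off = res.rho.to_numpy()[np.triu_indices(30, 1)]
        assert abs(off.mean()) < 0.02

    def test_scale_invariance_exact_mode(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 500, size=(40, 10))
        ids = [f"s{i}" for i in range(40)]
        cols = [f"t{j}" for j in range(10)]
        t1 = m.OtuTable(pd.DataFrame(counts, index=ids, columns=cols))
        scaled = counts.copy().astype(np.int64)
        scaled[0] *= 7  # one sample sequenced 7x deeper
        t2 = m.OtuTable(pd.DataFrame(scaled, index=ids, columns=cols))
        r1 = m.sparcc(t1, n_resamples=0)
        r2 = m.sparcc(t2, n_resamples=0)
        np.testing.assert_allclose(r1.t_matrix, r2.t_matrix, atol=1e-12)
        pd.testing.assert_frame_equal(r1.rho, r2.rho)

    def test_exact_mode_requires_zero_free(self):
        counts = np.ones((30, 6), dtype=int)
        counts[0, 0] = 0
        t = m.OtuTable(pd.DataFrame(
            counts, index=[f"s{i}" for i in range(30)], columns=[f"t{j}" for j in range(6)]
        ))
        with pytest.raises(ValueError, match="zero-free"):
            m.sparcc(t, n_resamples=0)

    def test_deterministic_under_seed(self):
        table, _ = _block_dataset(seed=6, n=100)
        r1 = m.sparcc(table, n_resamples=5, seed=9)
        r2 = m.sparcc(table, n_resamples=5, seed=9)
        pd.testing.assert_frame_equal(r1.rho, r2.rho)


class TestClusterCags:
    def _perfect_rho(self):
        blocks = [range(0, 4), range(4, 8), range(8, 12)]
        rho = np.eye(12) * 0.0
        for b in blocks:
            for i in b:
                for j in b:
                    rho[i, j] = 0.9
        np.fill_diagonal(rho, 1.0)
        ids = [f"t{i}" for i in range(12)]
        return pd.DataFrame(rho, index=ids, columns=ids)

    def test_perfect_blocks_recovered(self):
        assign = m.cluster_cags(self._perfect_rho(), 3)
        truth = [0] * 4 + [1] * 4 + [2] * 4
        assert adjusted_rand_score(truth, assign.labels.to_numpy()) == 1.0

    def test_single_cag(self):
        assign = m.cluster_cags(pd.DataFrame(np.eye(5)), 1)
        assert assign.n_cags == 1

    def test_estimated_blocks_recovered(self):
        cfg = m.SimulationConfig(
            n_samples=500, n_taxa=30, sequencing_depth=20_000, log_mean_sd=1.0,
            zero_inflation=0.0,
            correlation_blocks=[
                (list(range(0, 5)), 0.7),
                (list(range(5, 10)), 0.7),
                (list(range(10, 13)), -0.5),
            ],
            seed=7,
        )
        table, truth = m.simulate_counts(cfg)
        res = m.sparcc(table, n_resamples=20, seed=8)
        assign = m.cluster_cags(res.rho, 3)
        blocked = truth.block_labels >= 0
        ari = adjusted_rand_score(
            truth.block_labels[blocked], assign.labels.to_numpy()[blocked]
        )
        assert ari >= 0.8

    def test_nan_rows_become_singletons(self):
        rho = self._perfect_rho()
        rho.iloc[0, :] = np.nan
        rho.iloc[:, 0] = np.nan
        with pytest.warns(UserWarning, match="singleton"):
            assign = m.cluster_cags(rho, 3)
        sizes = assign.labels.value_counts()
        assert sizes[assign.labels.iloc[0]] == 1

    def test_deterministic(self):
        rho = self._perfect_rho()
        a1 = m.cluster_cags(rho, 3)
        a2 = m.cluster_cags(rho, 3)
        pd.testing.assert_series_equal(a1.labels, a2.labels)


class TestPermanova:
    def _dist(self, x):
        from scipy.spatial.distance import cdist

        d = cdist(x, x)
        return DistanceMatrix([f"s{i}" for i in range(len(x))], d)

    def test_fully_separated_groups_minimal_p(self):
        x = np.vstack([np.zeros((15, 2)), np.ones((15, 2)) * 100])
        groups = ["a"] * 15 + ["b"] * 15
        f, p = m.permanova(self._dist(x), groups, n_perm=999, seed=0)
        assert p == pytest.approx(1 / 1000)
        assert f > 100

    def test_null_p_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            x = rng.standard_normal((24, 3))
            groups = rng.permutation(["a"] * 12 + ["b"] * 12)
            _, p = m.permanova(self._dist(x), groups, n_perm=199,
                               seed=int(rng.integers(2**31)))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_matches_scikit_bio_pseudo_f(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(2)
        x = rng.standard_normal((30, 4))
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        dm = self._dist(x)
        f_ours, _ = m.permanova(dm, groups, n_perm=99, seed=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dm.d, ids=dm.ids), grouping=list(groups), permutations=99
        )
        assert f_ours == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((20, 3))
        dm = self._dist(x)
        g1 = ["a"] * 10 + ["b"] * 10
        g2 = ["zebra"] * 10 + ["ant"] * 10
        f1, p1 = m.permanova(dm, g1, n_perm=99, seed=4)
        f2, p2 = m.permanova(dm, g2, n_perm=99, seed=4)
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_singleton_group_rejected(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError, match="size 1"):
            m.permanova(self._dist(x), ["a", "a", "a", "a", "b"])


class TestCagAbundance:
    def _rel(self, rows):
        rows = np.asarray(rows, dtype=float)
        return m.OtuTable(
            pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                         columns=[f"t{j}" for j in range(rows.shape[1])]),
            kind="relative", check_sums=False,
        )

    def _assign(self, labels, ids):
        from microlmp.sparcc import CagAssignment

        return CagAssignment(
            labels=pd.Series(labels, index=ids), n_cags=len(set(labels)),
            linkage_height_cut=0.0,
        )

    def test_single_cag_gives_row_of_ones(self):
        t = self._rel([[0.4, 0.6], [0.1, 0.9]])
        out = m.cag_abundance(t, self._assign([1, 1], t.taxon_ids))
        np.testing.assert_allclose(out.to_numpy().ravel(), 1.0)

    def test_two_cags_split(self):
        t = self._rel([[0.3, 0.7]])
        out = m.cag_abundance(t, self._assign([1, 2], t.taxon_ids))
        np.testing.assert_allclose(out.loc["s0"].to_numpy(), [0.3, 0.7])

    def test_mass_conserved_on_fixture(self, fixture_dataset):
        _, table, _, _, _ = fixture_dataset
        rel = m.to_relative(table)
        labels = [1 + (i % 4) for i in range(rel.n_taxa)]
        out = m.cag_abundance(rel, self._assign(labels, rel.taxon_ids))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)


class TestCagPhenotypeCorrelation:
    def test_perfect_rank_agreement(self):
        n = 20
        adj = pd.Series(np.arange(n, dtype=float), index=[f"s{i}" for i in range(n)])
        cag = pd.DataFrame({"CAG1": np.arange(n) * 0.01 + 0.1}, index=adj.index)
        out = m.cag_phenotype_correlation(cag, adj)
        assert out.loc["CAG1", "rho"] == pytest.approx(1.0)

    def test_constant_cag_undefined(self):
        n = 10
        adj = pd.Series(np.random.default_rng(0).normal(size=n),
                        index=[f"s{i}" for i in range(n)])
        cag = pd.DataFrame({"CAG1": np.ones(n), "CAG2": np.arange(n, dtype=float)},
                           index=adj.index)
        out = m.cag_phenotype_correlation(cag, adj)
        assert np.isnan(out.loc["CAG1", "rho"])
        assert np.isfinite(out.loc["CAG2", "p_adj"])

    def test_planted_negative_effect_cag_detected(self):
        # a CAG whose member abundances depress the phenotype
        cfg = m.SimulationConfig(
            n_samples=300, n_taxa=30, sequencing_depth=10_000, zero_inflation=0.0,
            correlation_blocks=[(list(range(0, 4)), 0.7)],
            effect_taxa=[(i, 0.0, -0.8) for i in range(4)],
            residual_sd=0.5, seed=9,
        )
        table, tax, metadata, truth = m.simulate_dataset(cfg)
        md = m.adjust_phenotype(metadata)
        rel = m.to_relative(table)
        labels = [1 if i < 4 else 2 for i in range(30)]
        from microlmp.sparcc import CagAssignment

        assign = CagAssignment(
            labels=pd.Series(labels, index=rel.taxon_ids), n_cags=2,
            linkage_height_cut=0.0,
        )
        out = m.cag_phenotype_correlation(m.cag_abundance(rel, assign), md["adj_p"])
        assert out.loc["CAG1", "rho"] < 0
        assert out.loc["CAG1", "p_adj"] < 0.05
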