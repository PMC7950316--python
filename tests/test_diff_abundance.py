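"""Moderated statistics: ratio matrix, variance prior, q-values, classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ligandscape import diff_abundance as da
from ligandscape import synth


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["peptide", "replicate", "heavy_intensity", "light_intensity", "flags"],
    )


class TestLogRatioMatrix:
    def test_ratio_cells(self):
        recs = _records(
            [
                ("AAAAAAAAA", "R1", 1000.0, 1000.0, ""),
                ("CCCCCCCCC", "R1", 1000.0, 4000.0, ""),
            ]
        )
        m = da.build_log_ratio_matrix(recs)
        assert m.data.loc["AAAAAAAAA", "R1"] == pytest.approx(0.0)
        assert m.data.loc["CCCCCCCCC", "R1"] == pytest.approx(2.0)

    def test_ko_enriched_peptide_gets_positive_cell(self):
        # a peptide destroyed by the peptidase is ~6-fold higher in KO
        recs = _records([("VTLTCAFRY", "R1", 1000.0, 1000.0 * 2**2.45, "")])
        m = da.build_log_ratio_matrix(recs)
        assert m.data.loc["VTLTCAFRY", "R1"] == pytest.approx(2.45)

    def test_single_channel_rows_reported_separately(self):
        recs = _records(
            [
                ("AAAAAAAAA", "R1", 1000.0, np.nan, ""),
                ("AAAAAAAAA", "R2", 1000.0, np.nan, ""),
                ("CCCCCCCCC", "R1", 1000.0, 2000.0, ""),
            ]
        )
        m = da.build_log_ratio_matrix(recs)
        assert m.single_channel == ["AAAAAAAAA"]
        assert list(m.data.index) == ["CCCCCCCCC"]

    def test_non_positive_intensity_raises(self):
        recs = _records([("AAAAAAAAA", "R1", -5.0, 100.0, "")])
        with pytest.raises(ValueError):
            da.build_log_ratio_matrix(recs)


class TestMedianNormalize:
    def _matrix(self, values):
        df = pd.DataFrame(values, columns=["R1"])
        df.index = [f"P{i}AAAAAAAA" for i in range(len(df))]
        return da.QuantMatrix(data=df)

    def test_median_shift(self):
        m = da.median_normalize(self._matrix([0.1, 0.3, 0.5]))
        assert m.data["R1"].median() == pytest.approx(0.0)
        assert m.offsets["R1"] == pytest.approx(0.3)

    def test_already_centered_unchanged(self):
        m0 = self._matrix([-1.0, 0.0, 1.0])
        m = da.median_normalize(m0)
        assert np.allclose(m.data["R1"], m0.data["R1"])

    def test_rank_order_preserved(self):
        vals = np.random.default_rng(0).normal(size=50)
        m = da.median_normalize(self._matrix(list(vals)))
        rho = stats.spearmanr(vals, m.data["R1"]).statistic
        assert rho == pytest.approx(1.0)


class TestVariancePrior:
    def test_constant_variances_give_infinite_prior_df(self):
        s2 = np.full(200, 0.25)
        d0, s0sq = da.fit_variance_prior(s2, 1.0)
        assert np.isinf(d0)
        assert s0sq == pytest.approx(0.25, rel=1e-6)
        s2t, *_ = da.moderated_test(np.zeros(200), s2, 1.0, d0, s0sq, 2.0)
        assert np.allclose(s2t, 0.25)

    def test_parametric_recovery(self):
        # s^2 ~ s0^2 * F(d, d0) is the marginal of the hierarchical model
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 4.0, 0.09, 1.0
        s2 = s0_true * rng.f(d, d0_true, size=5000)
        d0, s0sq = da.fit_variance_prior(s2, d)
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s0sq - s0_true) / s0_true < 0.10

    def test_few_peptides_warn(self):
        with pytest.warns(UserWarning, match="< 10"):
            da.fit_variance_prior(np.array([0.1, 0.2, 0.3, 0.4, 0.5]), 1.0)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            da.fit_variance_prior(np.zeros(100), 1.0)


class TestModeratedTest:
    def test_zero_mean_gives_t0_p1(self):
        s2t, t, df, p = da.moderated_test(0.0, 0.1, 1.0, 4.0, 0.09, 2.0)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_moderation_limit_is_ordinary_t(self):
        rng = np.random.default_rng(3)
        cells = rng.normal(0.4, 0.5, size=(50, 3))
        mean, s2 = cells.mean(axis=1), cells.var(axis=1, ddof=1)
        _, t_mod, df, p_mod = da.moderated_test(mean, s2, 2.0, 0.0, 0.5, 3.0)
        t_ref, p_ref = stats.ttest_1samp(cells, 0.0, axis=1).statistic, stats.ttest_1samp(
            cells, 0.0, axis=1
        ).pvalue
        assert np.max(np.abs(t_mod - t_ref)) < 1e-12
        assert np.max(np.abs(p_mod - p_ref)) < 1e-12

    def test_infinite_prior_limit_is_pooled_z(self):
        rng = np.random.default_rng(4)
        cells = rng.normal(0.2, 0.3, size=(100, 2))
        mean, s2 = cells.mean(axis=1), cells.var(axis=1, ddof=1)
        s0sq = 0.09
        _, t_large, _, _ = da.moderated_test(mean, s2, 1.0, 1e8, s0sq, 2.0)
        z = mean / np.sqrt(s0sq / 2.0)
        assert np.max(np.abs(t_large - z)) < 1e-7

    def test_null_pvalues_uniform(self):
        spec = synth.make_allele("uni", 9)
        peps = synth.sample_ligands(spec, 2000, seed=5)
        design = synth.EffectDesign(
            frac_sensitive=0.0, frac_dependent=0.0, delta=0.0, flag_rate=0.0, seed=6
        )
        records, _ = synth.build_silac_experiment(peps, design)
        m = da.median_normalize(da.build_log_ratio_matrix(records))
        results, _ = da.moderate(m)
        ks = stats.kstest(results["p"], "uniform").statistic
        assert ks < 0.035


class TestStoreyQvalues:
    def test_all_ones(self):
        q, pi0 = da.storey_qvalues(np.ones(50))
        assert np.all(q == 1.0)
        assert pi0 == 1.0

    def test_pi0_one_equals_benjamini_hochberg(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        q, _ = da.storey_qvalues(p, pi0=1.0)
        bh = stats.false_discovery_control(p, method="bh")
        assert np.max(np.abs(q - bh)) < 1e-12

    def test_hand_computed_five_values(self):
        p = np.array([0.001, 0.01, 0.02, 0.8, 0.9])
        q, _ = da.storey_qvalues(p, pi0=1.0)
        expected = np.array([0.005, 0.025, 0.02 * 5 / 3, 0.9, 0.9])
        assert np.allclose(q, expected, atol=1e-12)

    def test_monotone_in_p_and_order_invariant(self):
        rng = np.random.default_rng(8)
        p = np.concatenate([rng.uniform(size=300), rng.uniform(0, 0.01, size=50)])
        q, _ = da.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        perm = rng.permutation(len(p))
        q_perm, _ = da.storey_qvalues(p[perm])
        assert np.allclose(q_perm, q[perm])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            da.storey_qvalues(np.array([0.5, 1.2]))


class TestClassify:
    @pytest.mark.parametrize(
        "q,logfc,expected",
        [
            (0.005, 2.45, "sensitive"),  # destroyed by the peptidase
            (0.5, 3.0, "unaffected"),
            (0.005, -1.0, "dependent"),
        ],
    )
    def test_three_way_call(self, q, logfc, expected):
        assert da.classify([q], [logfc])[0] == expected


class TestPlantedPower:
    def test_large_effects_nearly_all_called(self):
        # strong planted effect at the printed S-antigen scale
        spec = synth.hla_a29_like()
        peps = synth.sample_ligands(spec, 5000, seed=9)
        design = synth.EffectDesign(delta=2.45, flag_rate=0.0, seed=10)
        records, truth = synth.build_silac_experiment(peps, design)
        m = da.median_normalize(da.build_log_ratio_matrix(records))
        results, _ = da.moderate(m)
        merged = results.join(truth.drop_duplicates("peptide").set_index("peptide"))
        planted = merged[merged["true_class"] != "unaffected"]
        called = (planted["q"] < 0.01) & (
            np.sign(planted["mean_logFC"]) == np.sign(planted["true_log2fc"])
        )
        assert called.mean() >= 0.95
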