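"""Unit and property tests for the NB differential-expression machinery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctvtreg.count_model import (
    CountMatrix,
    SampleDesign,
    ContrastResult,
    adjust_bh,
    build_design_paired,
    call_significant,
    estimate_dispersions,
    estimate_size_factors,
    filter_low_expression,
    fit_contrasts,
    interaction_test,
)
from ctvtreg.synthetic_data import SimulationConfig, simulate_counts


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = CountMatrix(["g1", "g2"], ["A", "B"], np.array([[5, 5], [9, 9]]))
        np.testing.assert_allclose(estimate_size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_has_double_factor(self, toy_counts):
        sf = estimate_size_factors(toy_counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_median_of_ratios_hand_oracle(self, toy_counts):
        # per-gene geometric means (sqrt(2), 2*sqrt(2), 4*sqrt(2)); every ratio
        # in sample A is 1/sqrt(2) and in sample B sqrt(2)
        sf = estimate_size_factors(toy_counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_geometric_mean_is_one(self, strong_config):
        cm, _, _ = simulate_counts(strong_config)
        sf = estimate_size_factors(cm)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0)

    def test_all_zero_matrix_rejected(self):
        cm = CountMatrix(["g"], ["A", "B"], np.zeros((1, 2), int))
        with pytest.raises(ValueError):
            estimate_size_factors(cm)

    def test_scaling_one_sample_scales_its_factor(self, strong_config):
        cm, _, _ = simulate_counts(strong_config)
        sf = estimate_size_factors(cm)
        k2 = cm.counts.copy()
        k2[:, 0] *= 3
        sf2 = estimate_size_factors(CountMatrix(cm.genes, cm.samples, k2))
        # equivariance up to the geometric-mean-1 renormalisation
        ratio = (sf2[0] / sf[0]) / (sf2[1] / sf[1])
        assert ratio == pytest.approx(3.0, rel=1e-9)


# ---------------------------------------------------------------------------
# low-expression filter


class TestFilter:
    def test_lowest_40_percent_removed(self):
        # row sums 1..10 at q=0.40: sums 5..10 survive
        cm = CountMatrix([f"g{i}" for i in range(10)], ["A", "B"],
                         np.column_stack([np.arange(1, 11), np.zeros(10, int)]))
        kept = filter_low_expression(cm, 0.40)
        assert len(kept) == 6
        assert kept == [f"g{i}" for i in range(4, 10)]

    def test_constant_row_sums_all_retained(self):
        cm = CountMatrix(["a", "b", "c"], ["A", "B"], np.full((3, 2), 7))
        assert filter_low_expression(cm, 0.40) == ["a", "b", "c"]

    def test_quantile_zero_keeps_everything(self):
        cm = CountMatrix(["a", "b"], ["A", "B"], np.array([[0, 1], [5, 5]]))
        assert filter_low_expression(cm, 0.0) == ["a", "b"]


# ---------------------------------------------------------------------------
# BH adjustment


def _bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: padj_i = min over j with p_(j) >= p_i of n p_(j) / j."""
    n = len(p)
    order = np.argsort(p)
    padj = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, n * p[i] / rank)
        padj[i] = min(running, 1.0)
    return padj


class TestBH:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.01, 0.02, 0.03, 0.04])),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.3])), [0.3])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh(np.array([0.5, 1.5]))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_bruteforce_oracle(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(adjust_bh(p), _bh_bruteforce(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_p(self, pvals):
        p = np.array(pvals)
        padj = adjust_bh(p)
        order = np.argsort(p)
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= p - 1e-12).all()


# ---------------------------------------------------------------------------
# GLM fitting


class TestFitContrasts:
    def test_matches_statsmodels_per_gene(self, strong_config):
        """The vectorised IRLS must agree with an independent per-gene GLM fit."""
        import statsmodels.api as sm

        cm, design, _ = simulate_counts(strong_config)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, design, sf)
        res = fit_contrasts(cm, design, "paired", size_factors=sf,
                            dispersions=disp, filter_quantile=None)["S_vs_P"]
        X, names = build_design_paired(design)
        offset = np.log(sf)
        c = np.zeros(len(names))
        c[names.index("biopsy[2]")] = 1.0
        rng = np.random.default_rng(0)
        for gi in rng.choice(len(cm.genes), size=15, replace=False):
            g = cm.genes[gi]
            fam = sm.families.NegativeBinomial(alpha=float(disp.alpha[g]))
            fit = sm.GLM(cm.counts[gi], X, family=fam, offset=offset).fit()
            est_sm = float(c @ fit.params) / np.log(2)
            se_sm = float(np.sqrt(c @ fit.cov_params() @ c)) / np.log(2)
            assert res.table.loc[g, "log2fc"] == pytest.approx(est_sm, abs=1e-4)
            assert res.table.loc[g, "se"] == pytest.approx(se_sm, rel=1e-3, abs=1e-4)

    def test_null_log2fc_near_zero_and_p_uniform(self):
        cfg = SimulationConfig(n_genes=1500, n_dogs_regressive=3, n_dogs_nonregressive=0,
                               biopsies_per_dog=2, frac_early=0, frac_late=0,
                               frac_progressive=0, frac_non_expressed=0, seed=21)
        cm, design, _ = simulate_counts(cfg)
        res = fit_contrasts(cm, design, "paired", filter_quantile=None)["S_vs_P"].tested()
        assert abs(res["log2fc"].mean()) < 0.05
        from scipy import stats
        ks = stats.kstest(res["p"].to_numpy(), "uniform")
        # approximate uniformity: bounded KS distance, not a sharp test at this n
        assert ks.statistic < 0.1

    def test_planted_effect_recovered(self):
        cfg = SimulationConfig(n_genes=800, n_dogs_regressive=6, n_dogs_nonregressive=0,
                               biopsies_per_dog=2,
                               baseline_log_mean_range=(np.log(100), np.log(1000)),
                               frac_early=0.1, frac_late=0, frac_progressive=0,
                               frac_non_expressed=0, seed=22)
        cm, design, truth = simulate_counts(cfg)
        res = fit_contrasts(cm, design, "paired", filter_quantile=None)["S_vs_P"]
        planted = truth.genes.index[truth.genes["true_class"] != "NONE"]
        est = res.table.loc[planted, "log2fc"].abs()
        assert (np.abs(est - 4.0) <= 0.3).mean() >= 0.9

    def test_all_zero_gene_marked_not_tested(self, paired_design):
        rng = np.random.default_rng(3)
        k = rng.poisson(100, size=(5, 9))
        k[2] = 0
        cm = CountMatrix([f"g{i}" for i in range(5)], paired_design.samples, k)
        res = fit_contrasts(cm, paired_design, "paired", filter_quantile=None)["S_vs_P"]
        assert not res.table.loc["g2", "tested"]
        assert np.isnan(res.table.loc["g2", "p"])

    def test_filtered_genes_not_in_bh_denominator(self, paired_design):
        rng = np.random.default_rng(4)
        k = rng.poisson(100, size=(10, 9))
        k[0] = rng.poisson(1, size=9)
        cm = CountMatrix([f"g{i}" for i in range(10)], paired_design.samples, k)
        res = fit_contrasts(cm, paired_design, "paired", filter_quantile=0.2)["S_vs_P"]
        assert not res.table.loc["g0", "tested"]
        tested = res.tested()
        np.testing.assert_allclose(tested["padj"], adjust_bh(tested["p"].to_numpy()))

    def test_contrast_length_mismatch_rejected(self, strong_config):
        cm, design, _ = simulate_counts(strong_config)
        with pytest.raises(ValueError, match="length"):
            fit_contrasts(cm, design, "paired", contrasts={"bad": np.ones(2)})

    def test_aliased_design_rejected(self):
        rows = [
            {"sample_id": "a1", "dog": "A", "biopsy": 1, "regression_status": "REGRESSIVE"},
            {"sample_id": "a2", "dog": "A", "biopsy": 2, "regression_status": "REGRESSIVE"},
            {"sample_id": "b1", "dog": "B", "biopsy": 3, "regression_status": "REGRESSIVE"},
            {"sample_id": "b2", "dog": "B", "biopsy": 3, "regression_status": "REGRESSIVE"},
        ]
        design = SampleDesign(pd.DataFrame(rows).set_index("sample_id"))
        with pytest.raises(ValueError, match="(aliased|full rank)"):
            build_design_paired(design)


class TestDispersions:
    def test_poisson_data_yields_tiny_alpha(self, paired_design):
        rng = np.random.default_rng(5)
        mu = rng.uniform(50, 500, size=600)
        k = rng.poisson(mu[:, None], size=(600, 9))
        cm = CountMatrix([f"g{i}" for i in range(600)], paired_design.samples, k)
        disp = estimate_dispersions(cm, paired_design)
        assert disp.alpha.median() <= 0.01

    def test_true_alpha_recovered_within_band(self):
        cfg = SimulationConfig(n_genes=800, n_dogs_regressive=6, n_dogs_nonregressive=0,
                               biopsies_per_dog=2,
                               baseline_log_mean_range=(np.log(100), np.log(1000)),
                               frac_early=0, frac_late=0, frac_progressive=0,
                               frac_non_expressed=0, dispersion=0.2, seed=6)
        cm, design, _ = simulate_counts(cfg)
        disp = estimate_dispersions(cm, design)
        assert 0.1 <= disp.alpha.median() <= 0.4

    def test_constant_gene_gets_trend_value_without_error(self, paired_design):
        rng = np.random.default_rng(7)
        k = rng.poisson(100, size=(50, 9))
        k[0] = 100  # zero variance
        cm = CountMatrix([f"g{i}" for i in range(50)], paired_design.samples, k)
        disp = estimate_dispersions(cm, paired_design)
        assert np.isfinite(disp.alpha["g0"]) and disp.alpha["g0"] >= 0


class TestCallSignificant:
    @staticmethod
    def _result(log2fc, padj):
        tab = pd.DataFrame({
            "base_mean": 100.0, "log2fc": log2fc, "se": 0.1, "stat": 1.0,
            "p": padj, "padj": padj, "tested": True,
        }, index=[f"g{i}" for i in range(len(log2fc))])
        return ContrastResult("toy", tab)

    def test_threshold_is_strict_on_both_axes(self):
        res = self._result(
            log2fc=[3.5, np.log2(9.99), np.log2(100.0)],
            padj=[0.005, 1e-6, 0.02],
        )
        called = call_significant(res)
        assert called == {"g0": 1}  # FC about 11.3 up; others fail one strict cut

    def test_direction_sign(self):
        res = self._result(log2fc=[-4.0], padj=[1e-5])
        assert call_significant(res) == {"g0": -1}

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(8)
        res = self._result(log2fc=list(rng.normal(0, 4, 50)), padj=list(rng.uniform(0, 0.05, 50)))
        loose = set(call_significant(res, fc_threshold=5, alpha=0.02))
        tight_fc = set(call_significant(res, fc_threshold=12, alpha=0.02))
        tight_alpha = set(call_significant(res, fc_threshold=5, alpha=0.002))
        assert tight_fc <= loose and tight_alpha <= loose


class TestInteraction:
    def test_single_status_design_rejected(self, strong_config):
        cm, design, _ = simulate_counts(strong_config)
        with pytest.raises(ValueError, match="REGRESSIVE"):
            interaction_test(cm, design)

    def test_planted_interaction_detected(self):
        cfg = SimulationConfig(n_genes=600, n_dogs_regressive=3, n_dogs_nonregressive=3,
                               biopsies_per_dog=2,
                               baseline_log_mean_range=(np.log(100), np.log(1000)),
                               frac_early=0.1, frac_late=0, frac_progressive=0,
                               frac_non_expressed=0, seed=30)
        cm, design, truth = simulate_counts(cfg)
        res = interaction_test(cm, design, filter_quantile=None)
        planted = truth.genes.index[truth.genes["true_class"] != "NONE"]
        pvals = res.table.loc[planted, "p"]
        assert (pvals < 0.05).mean() >= 0.9

    def test_dog_offsets_absorbed_by_pairing(self):
        """Huge per-dog baselines must not bias the contrast estimates."""
        cfg = SimulationConfig(n_genes=800, n_dogs_regressive=3, n_dogs_nonregressive=0,
                               biopsies_per_dog=2,
                               baseline_log_mean_range=(np.log(200), np.log(400)),
                               frac_early=0, frac_late=0, frac_progressive=0,
                               frac_non_expressed=0, dog_offset_sd=1.5, seed=31)
        cm, design, _ = simulate_counts(cfg)
        res = fit_contrasts(cm, design, "paired", filter_quantile=None)["S_vs_P"].tested()
        assert abs(res["log2fc"].mean()) < 0.05
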