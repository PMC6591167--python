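"""Three-step DNB selection, I_s/I_r scores, correction term, robustness."""

import math

import numpy as np
import pandas as pd
import pytest

from dnbkit import (
    SyntheticConfig,
    control_swap,
    correction_term,
    correction_term_mc,
    generate_dataset,
    leave_one_out,
    relative_recovery_rate,
    score_ir,
    score_is,
    score_series,
    select_dnb,
    sweep_parameters,
    top_fraction,
    variance_ratio,
)
from dnbkit.dnb import correlation_gain_within, nonspecific_gain_outside

from _naive import naive_ir, naive_is, naive_v1, naive_v2, naive_v3
from conftest import make_slice


class TestOracleEquivalence:
    """Vectorized statistics match loop-based reimplementations of the formulas."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_v_statistics_and_scores(self, seed):
        rng = np.random.default_rng(seed)
        n_genes, n_samples = rng.integers(8, 21), rng.integers(4, 7)
        X = make_slice(rng.normal(0, 1, (n_genes, n_samples)))
        Y = make_slice(rng.normal(0, 1, (n_genes, n_samples)), group="control")
        xa, ya = X.values.to_numpy(), Y.values.to_numpy()

        v1, excluded = variance_ratio(X, Y)
        assert len(excluded) == 0
        np.testing.assert_allclose(v1.to_numpy(), naive_v1(xa, ya), atol=1e-10)

        s1 = top_fraction(v1, 50.0)
        pos = [X.gene_ids.get_loc(g) for g in s1]
        v2 = correlation_gain_within(X, Y, s1)
        v3 = nonspecific_gain_outside(X, Y, s1)
        nv2 = naive_v2(xa, ya, pos)
        nv3 = naive_v3(xa, ya, range(n_genes), pos)
        np.testing.assert_allclose(v2.to_numpy(), [nv2[i] for i in pos], atol=1e-10)
        np.testing.assert_allclose(v3.to_numpy(), [nv3[i] for i in pos], atol=1e-10)

        genes = list(X.gene_ids[:5])
        c = correction_term(n_samples)
        assert score_is(X, genes) == pytest.approx(naive_is(xa, range(5)), abs=1e-10)
        assert score_ir(X, genes) == pytest.approx(naive_ir(xa, range(5), c), abs=1e-10)


class TestCorrectionTerm:
    def test_tabulated_constants(self):
        assert correction_term(4) == pytest.approx(0.5, abs=1e-12)
        assert correction_term(5) == pytest.approx(4 / (3 * math.pi), abs=1e-12)
        assert round(correction_term(5), 2) == 0.42

    def test_monte_carlo_agreement(self):
        for m in (4, 5, 8):
            mc = correction_term_mc(m, n_pairs=200_000, seed=0)
            assert mc == pytest.approx(correction_term(m), abs=0.005)

    def test_strictly_decreasing_to_zero(self):
        values = [correction_term(m) for m in range(3, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert correction_term(400) < 0.05

    def test_small_sample_error(self):
        with pytest.raises(ValueError):
            correction_term(2)


class TestTopFraction:
    def test_count_rule(self):
        scores = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        assert len(top_fraction(scores, 10)) == 1
        scores25 = pd.Series(np.arange(25.0), index=[f"g{i:02d}" for i in range(25)])
        assert len(top_fraction(scores25, 10)) == 2  # floor(2.5)
        assert len(top_fraction(scores25, 100)) == 25

    def test_selects_largest(self):
        scores = pd.Series([5.0, 1.0, 3.0], index=["a", "b", "c"])
        assert list(top_fraction(scores, 67)) == ["a", "c"]

    def test_tiebreak_ascending_gene_id(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=["d", "b", "c", "a"])
        assert list(top_fraction(scores, 50)) == ["a", "b"]

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            top_fraction(pd.Series([1.0], index=["a"]), 0)


class TestVStatistics:
    def test_v1_identity_and_ratio(self):
        X = make_slice([[1.0, 2.0, 3.0], [0.0, 2.0, 4.0]])
        Y = make_slice([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], group="control")
        v1, _ = variance_ratio(X, Y)
        np.testing.assert_allclose(v1.to_numpy(), [1.0, 2.0])

    def test_zero_sd_genes_excluded_and_reported(self):
        X = make_slice([[1.0, 1.0, 1.0], [0.0, 2.0, 4.0]])
        Y = make_slice([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], group="control")
        v1, excluded = variance_ratio(X, Y)
        assert list(excluded) == ["g000"]
        assert list(v1.index) == ["g001"]

    def test_v2_two_gene_case(self):
        # perfectly correlated pair in X, uncorrelated in Y: v2 = 1 each
        X = make_slice([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        Y = make_slice([[1.0, 2.0, 3.0], [1.0, -2.0, 1.0]], group="control")
        v2 = correlation_gain_within(X, Y, X.gene_ids)
        np.testing.assert_allclose(v2.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_v2_v3_vanish_when_slices_equal(self):
        rng = np.random.default_rng(5)
        arr = rng.normal(0, 1, (8, 5))
        X = make_slice(arr)
        Y = make_slice(arr, group="control")
        s1 = X.gene_ids[:4]
        assert np.allclose(correlation_gain_within(X, Y, s1), 0.0)
        assert np.allclose(nonspecific_gain_outside(X, Y, s1), 0.0)

    def test_v3_counts_outside_correlations(self):
        # gene 0 duplicated by all 5 outside genes in X (|r|=1), orthogonal in Y
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([base, -base] + [base * (i + 2) for i in range(5)])
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, X.shape)
        Xs, Ys = make_slice(X), make_slice(Y, group="control")
        s1 = Xs.gene_ids[:2]
        v3 = nonspecific_gain_outside(Xs, Ys, s1)
        expected_noise = np.abs(np.corrcoef(Y))[np.ix_([0, 1], range(2, 7))].sum(axis=1)
        np.testing.assert_allclose(v3.to_numpy(), 5.0 - expected_noise, atol=1e-10)


class TestSelection:
    def test_set_algebra_and_sizes(self, planted):
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        sel = select_dnb(X, Y)
        assert set(sel.s1) <= set(sel.s0)
        assert set(sel.s2) <= set(sel.s1) and set(sel.s3) <= set(sel.s1)
        assert set(sel.s_star) == set(sel.s2) - set(sel.s3)
        assert len(sel.s1) == math.floor(0.10 * 500)
        assert len(sel.s2) == math.floor(0.50 * len(sel.s1))
        assert len(sel.s3) == math.floor(0.80 * len(sel.s1))

    def test_planted_module_drives_first_two_steps(self, planted):
        """S1 and S2 are dominated by planted genes; S* stays precise."""
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        sel = select_dnb(X, Y)
        planted_set = set(truth.dnb_gene_ids)
        assert len(planted_set & set(sel.s1)) / len(sel.s1) >= 0.5
        assert len(planted_set & set(sel.s2)) / len(sel.s2) >= 0.8
        if len(sel.s_star):
            assert len(planted_set & set(sel.s_star)) / len(sel.s_star) >= 0.6

    def test_degenerate_equal_slices_deterministic(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(0, 1, (20, 5))
        X = make_slice(arr)
        Y = make_slice(arr, group="control")
        sel1 = select_dnb(X, Y)
        sel2 = select_dnb(X, Y)
        assert np.allclose(sel1.v1, 1.0)
        assert np.allclose(sel1.v2, 0.0) and np.allclose(sel1.v3, 0.0)
        assert list(sel1.s_star) == list(sel2.s_star)

    def test_scale_robustness(self):
        rng = np.random.default_rng(9)
        xa, ya = rng.normal(0, 1, (15, 5)), rng.normal(0, 1, (15, 5))
        sel = select_dnb(make_slice(xa), make_slice(ya, group="control"), 40, 50, 80)
        xa2, ya2 = xa.copy(), ya.copy()
        xa2[3] *= 7.5
        ya2[3] *= 7.5
        sel2 = select_dnb(make_slice(xa2), make_slice(ya2, group="control"), 40, 50, 80)
        pd.testing.assert_series_equal(sel.v1, sel2.v1)
        assert list(sel.s_star) == list(sel2.s_star)

    def test_gene_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        xa, ya = rng.normal(0, 1, (15, 5)), rng.normal(0, 1, (15, 5))
        ids = [f"g{i:03d}" for i in range(15)]
        sel = select_dnb(
            make_slice(xa, gene_ids=ids), make_slice(ya, group="control", gene_ids=ids), 40, 50, 80
        )
        perm = rng.permutation(15)
        sel_p = select_dnb(
            make_slice(xa[perm], gene_ids=[ids[i] for i in perm]),
            make_slice(ya[perm], group="control", gene_ids=[ids[i] for i in perm]),
            40, 50, 80,
        )
        assert list(sel.s_star) == list(sel_p.s_star)
        assert list(sel.s1) == list(sel_p.s1)

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(11)
        xa, ya = rng.normal(0, 1, (15, 5)), rng.normal(0, 1, (15, 5))
        sel = select_dnb(make_slice(xa), make_slice(ya, group="control"), 40, 50, 80)
        sel_p = select_dnb(
            make_slice(xa[:, ::-1]), make_slice(ya[:, [2, 0, 1, 4, 3]], group="control"), 40, 50, 80
        )
        assert list(sel.s_star) == list(sel_p.s_star)


class TestScores:
    def test_score_is_examples(self):
        Z = make_slice([[0.0, 1.0, 2.0], [0.0, 3.0, 6.0]])
        assert score_is(Z, Z.gene_ids) == pytest.approx(2.0)  # SDs 1 and 3
        const = make_slice([[5.0, 5.0, 5.0]])
        assert score_is(const, const.gene_ids) == 0.0

    def test_score_ir_perfect_pair_with_rounded_correction(self):
        Z = make_slice(np.vstack([np.arange(5.0), 2 * np.arange(5.0)]))
        assert score_ir(Z, Z.gene_ids, correction=0.42) == pytest.approx(0.58)
        assert score_ir(Z, Z.gene_ids) == pytest.approx(1 - 4 / (3 * math.pi))

    def test_four_sample_slice_uses_half_correction(self, planted):
        config, dataset, truth = planted
        small = SyntheticConfig(n_genes=50, n_dnb=5, deg_cluster_size=5, replicates=4, seed=2)
        ds4, _ = generate_dataset(small)
        series = score_series(ds4, list(ds4.gene_ids[:10]))
        np.testing.assert_allclose(series.table["c"], 0.5, atol=1e-12)
        assert (series.table["M"] == 4).all()

    def test_ir_null_calibrated_near_zero(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(60):
            Z = make_slice(rng.normal(0, 1, (30, 5)))
            vals.append(score_ir(Z, Z.gene_ids))
        assert abs(np.mean(vals)) < 0.05

    def test_series_peaks_at_planted_week_for_true_module(self, planted):
        config, dataset, truth = planted
        series = score_series(dataset, truth.dnb_gene_ids)
        assert series.peak_week("case", "I_s") == config.peak_week
        assert series.peak_week("case", "I_r") == config.peak_week
        # no systematic control peak: case peak contrast dominates
        case = series.for_group("case")
        ctrl = series.for_group("control")
        case_contrast = case["I_s"].max() - case["I_s"].median()
        ctrl_contrast = ctrl["I_s"].max() - ctrl["I_s"].median()
        assert case_contrast > ctrl_contrast

    def test_flat_series_on_homogeneous_null(self, null_dataset):
        _, dataset, _ = null_dataset
        series = score_series(dataset, list(dataset.gene_ids))
        assert series.table["I_s"].std() < 0.05
        assert series.table["I_r"].abs().max() < 0.1


class TestSweep:
    def test_single_triple_grid(self, planted):
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        table = sweep_parameters(X, Y, dataset, [10.0], [50.0], [80.0], target_week=5)
        assert len(table) == 1 and table.loc[0, "rank"] == 1

    def test_ranked_descending_with_nan_last(self, planted):
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        table = sweep_parameters(
            X, Y, dataset, [5.0, 10.0], [25.0, 50.0], [60.0, 80.0], target_week=5
        )
        sharp = table["sharpness"].to_numpy()
        valid = sharp[~np.isnan(sharp)]
        assert (np.diff(valid) <= 1e-12).all()
        if np.isnan(sharp).any():
            assert np.isnan(sharp[len(valid):]).all()

    def test_planted_data_outranks_null_data(self, planted, null_dataset):
        config, dataset, _ = planted
        _, null_ds, _ = null_dataset
        grids = ([10.0], [50.0], [80.0])
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        planted_sharp = sweep_parameters(X, Y, dataset, *grids, target_week=5)[
            "sharpness"
        ].iloc[0]
        Xn = null_ds.condition_slice("case", 5)
        Yn = null_ds.condition_slice("control", 5)
        null_sharp = sweep_parameters(Xn, Yn, null_ds, *grids, target_week=5)[
            "sharpness"
        ].iloc[0]
        assert np.isnan(null_sharp) or planted_sharp > null_sharp


class TestRobustness:
    def test_loo_exact_on_duplicated_samples(self):
        """With 2 distinct samples each duplicated, dropping one copy leaves
        every K-1 statistic unchanged, so each drop returns the reference set."""
        rng = np.random.default_rng(13)
        xa = rng.normal(0, 1, (20, 2))
        ya = rng.normal(0, 1, (20, 2))
        X = make_slice(np.repeat(xa, 2, axis=1))
        Y = make_slice(np.repeat(ya, 2, axis=1), group="control")
        ref = select_dnb(X, Y).s_star
        result = leave_one_out(X, Y, reference_set=ref)
        assert result["mean_overlap"] == len(ref)
        assert result["sem_overlap"] == 0.0

    def test_loo_stable_for_strong_module(self):
        config = SyntheticConfig(
            n_genes=200, n_dnb=30, sd_ratio=6.0, target_abs_corr=0.9,
            replicates=8, n_deg_clusters=0, seed=23,
        )
        dataset, truth = generate_dataset(config)
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        # small theta3 keeps the exclusion step from eroding the module
        thetas = (15.0, 50.0, 10.0)
        ref = select_dnb(X, Y, *thetas).s_star
        result = leave_one_out(X, Y, thetas=thetas, reference_set=ref)
        assert len(ref) >= 10
        assert result["mean_overlap"] / len(ref) >= 0.8

    def test_control_swap_identity(self, planted):
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        Y = dataset.condition_slice("control", config.peak_week)
        ref = select_dnb(X, Y).s_star
        result = control_swap(X, Y, reference_set=ref)
        assert result["overlap"] == len(ref)
        assert result["alt_s_star"] == sorted(ref)

    def test_control_swap_against_early_case_week(self, planted):
        """Using the case strain's first week as control still finds the module."""
        config, dataset, truth = planted
        X = dataset.condition_slice("case", config.peak_week)
        alt = dataset.condition_slice("case", 3)
        ref = select_dnb(X, dataset.condition_slice("control", config.peak_week)).s_star
        result = control_swap(X, alt, reference_set=ref)
        sel = result["selection"]
        planted_set = set(truth.dnb_gene_ids)
        assert len(planted_set & set(sel.s2)) / len(sel.s2) >= 0.8
        if result["n_alt"] and result["overlap"]:
            assert result["fisher_p"] < 0.05


class TestRecoveryRate:
    def test_identity_covariance_and_scaling(self):
        # two orthogonal rows with unit sample variance -> covariance = I
        z = np.array([[-1.0, 0.0, 1.0], [1.0, -2.0, 1.0] / np.sqrt(3)])
        Z = make_slice(z)
        assert relative_recovery_rate(Z, Z.gene_ids) == pytest.approx(1.0)
        Z2 = make_slice(z * np.sqrt(2))
        assert relative_recovery_rate(Z2, Z2.gene_ids) == pytest.approx(0.5)

    def test_minimum_at_planted_week(self, planted):
        config, dataset, truth = planted
        rates = {
            week: relative_recovery_rate(
                dataset.condition_slice("case", week), truth.dnb_gene_ids
            )
            for week in dataset.weeks
        }
        assert min(rates, key=rates.get) == config.peak_week
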