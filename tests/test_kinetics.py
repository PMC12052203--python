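import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import binom, spearmanr

from slamkin.conversions import ConversionTable
from slamkin.kinetics import (
    KineticsError,
    RateParams,
    estimate_background,
    estimate_fraction_new,
    estimate_pc_global,
    fit_gene_kinetics,
    half_life,
    kdeg_from_fraction,
)

PARAMS = RateParams(p_e=0.001, p_c=0.05)


def grid_search_mle(n, k, w, params, points=10_000):
    """Brute-force argmax of the mixture likelihood on a dense grid."""
    f_grid = np.linspace(1e-4, 1 - 1e-4, points)
    ll = np.zeros_like(f_grid)
    for ni, ki, wi in zip(n, k, w):
        a = binom.pmf(ki, ni, params.p_c)
        b = binom.pmf(ki, ni, params.p_e)
        ll += wi * np.log(f_grid * a + (1 - f_grid) * b)
    return f_grid[np.argmax(ll)]


def simulate_histogram(rng, f, n_reads=200, n_T=20, params=PARAMS):
    new = rng.random(n_reads) < f
    k = np.where(
        new,
        rng.binomial(n_T, params.p_c, n_reads),
        rng.binomial(n_T, params.p_e, n_reads),
    )
    vals, counts = np.unique(k, return_counts=True)
    return np.full(len(vals), n_T), vals, counts


def table_from_counts(rows):
    return ConversionTable(
        pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "n_T", "k", "n_reads"])
    )


class TestClosedForms:
    def test_half_life_of_ln2_rate_is_one_hour(self):
        assert half_life(math.log(2)) == pytest.approx(1.0, abs=1e-12)

    def test_half_life_direct_value(self):
        assert half_life(0.2166) == pytest.approx(3.2, abs=5e-3)

    def test_kdeg_direct_values(self):
        assert kdeg_from_fraction(0.5, 1.0) == pytest.approx(math.log(2), abs=1e-12)
        assert kdeg_from_fraction(0.9, 4.0) == pytest.approx(0.5756, abs=1e-4)

    def test_kdeg_small_fraction_limit(self):
        # first-order expansion: k ~ f/t for f -> 0
        assert kdeg_from_fraction(1e-4, 4.0) == pytest.approx(2.5e-5, rel=1e-3)

    @pytest.mark.parametrize("t", [0.1, 1.0, 4.0, 24.0])
    def test_composition_identity(self, t):
        # fraction-new 1/2 after a pulse of length t means t_half == t
        assert half_life(kdeg_from_fraction(0.5, t)) == pytest.approx(t, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(KineticsError):
            kdeg_from_fraction(0.0, 4.0)
        with pytest.raises(KineticsError):
            kdeg_from_fraction(1.0, 4.0)
        with pytest.raises(KineticsError):
            kdeg_from_fraction(0.5, 0.0)
        with pytest.raises(KineticsError):
            half_life(0.0)


class TestBackgroundRate:
    def test_pseudocount_floor(self):
        table = table_from_counts([["g", "c", 1, 20, 0, 500]])  # sum_T = 10000, sum_k = 0
        assert estimate_background(table) == pytest.approx(0.5 / 10_001)

    def test_direct_formula(self):
        table = table_from_counts(
            [["g", "c", 1, 20, 0, 490], ["g", "c", 1, 20, 1, 10]]
        )  # sum_T = 10000, sum_k = 10
        assert estimate_background(table) == pytest.approx(10.5 / 10_001)

    def test_recovers_simulated_background(self):
        rng = np.random.default_rng(12)
        n_reads, n_T, p_e = 5_000, 20, 0.001  # 1e5 T positions
        k = rng.binomial(n_T, p_e, n_reads)
        vals, counts = np.unique(k, return_counts=True)
        table = table_from_counts(
            [["g", "c", 1, n_T, int(v), int(c)] for v, c in zip(vals, counts)]
        )
        se = math.sqrt(p_e * (1 - p_e) / (n_reads * n_T))
        assert abs(estimate_background(table) - p_e) < 3 * se

    def test_empty_control_errors(self):
        with pytest.raises(KineticsError):
            estimate_background(ConversionTable())


class TestPcEstimation:
    def test_recovery_within_ten_percent(self):
        rng = np.random.default_rng(3)
        rows = []
        for g in range(200):
            f = rng.uniform(0.1, 0.9)
            n_T, vals, counts = simulate_histogram(rng, f, n_reads=200)
            rows += [
                [f"g{g}", "igg", 1, 20, int(v), int(c)] for v, c in zip(vals, counts)
            ]
        p_c = estimate_pc_global(table_from_counts(rows), p_e=0.001)
        assert abs(p_c - 0.05) / 0.05 < 0.10

    def test_all_old_reads_unidentifiable(self):
        rng = np.random.default_rng(4)
        rows = []
        for g in range(20):
            n_T, vals, counts = simulate_histogram(rng, f=0.0, n_reads=300)
            rows += [
                [f"g{g}", "igg", 1, 20, int(v), int(c)] for v, c in zip(vals, counts)
            ]
        with pytest.raises(KineticsError, match="p_c|unidentifiable"):
            estimate_pc_global(table_from_counts(rows), p_e=0.001)

    def test_no_qualifying_genes_errors(self):
        table = table_from_counts([["g", "igg", 1, 20, 1, 10]])
        with pytest.raises(KineticsError, match="fixed p_c"):
            estimate_pc_global(table, p_e=0.001, min_reads=50)

    def test_invalid_rate_params_rejected(self):
        with pytest.raises(KineticsError):
            RateParams(p_e=0.05, p_c=0.05)


class TestFractionNewMLE:
    def test_all_zero_conversions_clamps_to_floor(self):
        params = RateParams(p_e=0.0, p_c=0.05)
        n = np.array([20]); k = np.array([0]); w = np.array([100])
        f_hat, _, flag = estimate_fraction_new((n, k, w), params)
        assert f_hat == pytest.approx(1e-4, rel=1e-2)
        assert flag == "boundary"

    def test_matches_grid_search_on_fixed_histogram(self):
        n = np.array([20, 20]); k = np.array([1, 0]); w = np.array([50, 50])
        f_hat, _, _ = estimate_fraction_new((n, k, w), PARAMS)
        f_grid = grid_search_mle(n, k, w, PARAMS)
        assert abs(f_hat - f_grid) < 1e-3

    def test_matches_grid_search_on_random_histograms(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            f = rng.uniform(0.05, 0.95)
            n, k, w = simulate_histogram(rng, f, n_reads=int(rng.integers(60, 2_000)))
            f_hat, _, _ = estimate_fraction_new((n, k, w), PARAMS)
            f_grid = grid_search_mle(n, k, w, PARAMS)
            assert abs(f_hat - f_grid) < 1e-3

    def test_adding_fully_converted_read_never_decreases_estimate(self):
        rng = np.random.default_rng(10)
        n, k, w = simulate_histogram(rng, 0.4, n_reads=150)
        f0, _, _ = estimate_fraction_new((n, k, w), PARAMS)
        n2 = np.append(n, 20); k2 = np.append(k, 20); w2 = np.append(w, 1)
        f1, _, _ = estimate_fraction_new((n2, k2, w2), PARAMS)
        assert f1 >= f0 - 1e-9

    def test_standard_error_coverage(self):
        # ~99.7% nominal central coverage at 3 SEs; demand >= 99% over 300 fits
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(300):
            n, k, w = simulate_histogram(rng, 0.5, n_reads=500)
            f_hat, se, _ = estimate_fraction_new((n, k, w), PARAMS)
            if abs(logit(f_hat) - logit(0.5)) < 3 * se:
                hits += 1
        assert hits >= 297


class TestGeneTableFit:
    def _simulated_table(self, rng, f_by_gene, sample="igg", reads=200):
        rows = []
        for gene, f in f_by_gene.items():
            for rep in (1, 2):
                n_T, vals, counts = simulate_histogram(rng, f, n_reads=reads // 2)
                rows += [
                    [gene, sample, rep, 20, int(v), int(c)] for v, c in zip(vals, counts)
                ]
        return table_from_counts(rows)

    def test_low_read_genes_flagged_without_estimate(self):
        table = table_from_counts([["g1", "igg", 1, 20, 1, 10]])
        out = fit_gene_kinetics(table, "igg", PARAMS, t_hours=4.0)
        assert list(out["flag"]) == ["low_reads"]
        assert np.isnan(out["f_hat"]).all()

    def test_estimates_internally_consistent(self):
        rng = np.random.default_rng(14)
        table = self._simulated_table(rng, {"a": 0.3, "b": 0.7})
        out = fit_gene_kinetics(table, "igg", PARAMS, t_hours=4.0).set_index("gene_id")
        for gene in ("a", "b"):
            row = out.loc[gene]
            assert row["kdeg_per_h"] == pytest.approx(
                -math.log(1 - row["f_hat"]) / 4.0, rel=1e-9
            )
            assert row["t_half_h"] == pytest.approx(
                math.log(2) / row["kdeg_per_h"], rel=1e-9
            )
        assert out.loc["b", "kdeg_per_h"] > out.loc["a", "kdeg_per_h"]

    def test_per_replicate_mode_close_to_pooled(self):
        rng = np.random.default_rng(15)
        table = self._simulated_table(rng, {"a": 0.4}, reads=600)
        pooled = fit_gene_kinetics(table, "igg", PARAMS, 4.0, pool_replicates=True)
        byrep = fit_gene_kinetics(table, "igg", PARAMS, 4.0, pool_replicates=False)
        assert pooled.loc[0, "f_hat"] == pytest.approx(byrep.loc[0, "f_hat"], abs=0.05)

    def test_parameter_recovery_median_error_and_rank(self):
        # 300 genes, 200 reads each, true half-lives log-uniform on [0.5, 12] h
        rng = np.random.default_rng(1)
        t = 4.0
        truth = {}
        rows = []
        for g in range(300):
            t_half = float(np.exp(rng.uniform(np.log(0.5), np.log(12.0))))
            truth[f"g{g:03d}"] = t_half
            f = 1 - math.exp(-math.log(2) / t_half * t)
            n_T, vals, counts = simulate_histogram(rng, f, n_reads=200)
            rows += [
                [f"g{g:03d}", "igg", 1, 20, int(v), int(c)]
                for v, c in zip(vals, counts)
            ]
        out = fit_gene_kinetics(table_from_counts(rows), "igg", PARAMS, t).set_index("gene_id")
        ok = out[out["flag"] != "low_reads"]
        true_vals = np.array([truth[g] for g in ok.index])
        rel_err = np.abs(ok["t_half_h"] - true_vals) / true_vals
        rho = spearmanr(true_vals, ok["t_half_h"]).statistic
        assert np.median(rel_err) < 0.15
        assert rho > 0.9
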