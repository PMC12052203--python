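import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import kstest

from slamkin.diffkin import DiffKinError, benjamini_hochberg, classify
from slamkin.diffkin import test_differential as differential_kinetics
from slamkin.diffkin import test_differential_lrt as differential_kinetics_lrt
from slamkin.kinetics import (
    RateParams,
    fit_gene_kinetics,
    half_life,
    kdeg_from_fraction,
)
from test_kinetics import simulate_histogram, table_from_counts

PARAMS = RateParams(p_e=0.001, p_c=0.05)


def reference_bh(p):
    """Independent step-up implementation working from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def estimates_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "kdeg_per_h", "se_log_kdeg", "flag"]
    )


class TestBenjaminiHochberg:
    def test_single_p_identity(self):
        assert benjamini_hochberg([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        got = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.9])
        assert got == pytest.approx([0.05, 0.05, 0.05, 0.05, 0.9])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_rejects_out_of_range(self):
        with pytest.raises(DiffKinError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            m = int(rng.integers(1, 60))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            assert benjamini_hochberg(p) == pytest.approx(reference_bh(p), abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(22)
        p = rng.random(200)
        _, want, *_ = multipletests(p, method="fdr_bh")
        assert benjamini_hochberg(p) == pytest.approx(want, abs=1e-12)


class TestClassify:
    def test_moderate_ratio_not_transient(self):
        # a 1.35-fold localized/global rate is intermediate at baseline
        assert classify(1.35, 0.001) == "intermediate"

    def test_significant_high_ratio_is_transient(self):
        assert classify(2.6, 0.01) == "transient"

    def test_retained_transcript_is_persistent(self):
        # localized t1/2 12 h vs global 11.4 h -> R = 11.4/12 = 0.95 <= 1
        ratio = kdeg_from_fraction(0.5, 12.0) / kdeg_from_fraction(0.5, 11.4)
        assert ratio == pytest.approx(0.95, abs=0.0001)
        assert classify(ratio, 0.9) == "persistent"

    def test_threshold_boundary_is_inclusive(self):
        assert classify(2.0, 0.049) == "transient"
        assert classify(2.0, 0.051) == "intermediate"
        assert classify(1.0, 0.5) == "persistent"

    def test_strict_persistent_requires_nonsignificance(self):
        assert classify(0.5, 0.01, strict_persistent=True) == "intermediate"
        assert classify(0.5, 0.5, strict_persistent=True) == "persistent"

    def test_log2_scale_variant_moves_threshold_to_fourfold(self):
        assert classify(3.0, 0.01, ratio_threshold=2.0, log2_scale=True) == "intermediate"
        assert classify(4.5, 0.01, ratio_threshold=2.0, log2_scale=True) == "transient"

    def test_domain_errors(self):
        with pytest.raises(DiffKinError):
            classify(0.0, 0.5)
        with pytest.raises(DiffKinError):
            classify(1.0, 1.5)

    @given(
        st.floats(0.01, 100.0, allow_nan=False),
        st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_labels_partition_the_domain(self, ratio, padj):
        assert classify(ratio, padj) in ("transient", "persistent", "intermediate")


class TestTestDifferential:
    def test_identical_estimates_are_null(self):
        loc = estimates_frame([["g", 0.5, 0.1, "ok"]])
        glob = estimates_frame([["g", 0.5, 0.1, "ok"]])
        out = differential_kinetics(loc, glob)
        row = out.iloc[0]
        assert row["kdeg_ratio"] == pytest.approx(1.0)
        assert row["z_stat"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_z_statistic_formula(self):
        # ln rates 0.7 vs 0.0, SEs 0.1 each: z = 0.7 / sqrt(0.02)
        loc = estimates_frame([["g", math.exp(0.7), 0.1, "ok"]])
        glob = estimates_frame([["g", math.exp(0.0), 0.1, "ok"]])
        out = differential_kinetics(loc, glob)
        assert out.loc[0, "z_stat"] == pytest.approx(0.7 / math.sqrt(0.02), rel=1e-9)

    def test_flagged_genes_not_tested_and_outside_bh_family(self):
        loc = estimates_frame(
            [["g1", 0.5, 0.1, "ok"], ["g2", 0.5, 0.1, "low_reads"]]
        )
        glob = estimates_frame(
            [["g1", 0.25, 0.1, "ok"], ["g2", 0.5, 0.1, "ok"], ["g3", 0.5, 0.1, "ok"]]
        )
        out = differential_kinetics(loc, glob).set_index("gene_id")
        assert out.loc["g2", "label"] == "not_tested"
        assert out.loc["g3", "label"] == "not_tested"
        assert np.isnan(out.loc["g2", "padj"])
        # family size is 1, so the single padj equals its p
        assert out.loc["g1", "padj"] == pytest.approx(out.loc["g1", "p_value"])

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(23)
        rows_l = [[f"g{i}", math.exp(rng.normal(0, 0.5)), 0.15, "ok"] for i in range(40)]
        rows_g = [[f"g{i}", math.exp(rng.normal(0, 0.5)), 0.15, "ok"] for i in range(40)]
        out = differential_kinetics(estimates_frame(rows_l), estimates_frame(rows_g))
        assert (out["padj"] >= out["p_value"] - 1e-12).all()

    def test_null_p_values_uniform(self):
        # same underlying rates in both libraries: p-values ~ U(0,1)
        rng = np.random.default_rng(24)
        t = 4.0
        rows_loc, rows_glob = [], []
        for g in range(200):
            f = rng.uniform(0.2, 0.8)
            for dest, sample in ((rows_loc, "loc"), (rows_glob, "glob")):
                n_T, vals, counts = simulate_histogram(rng, f, n_reads=400)
                dest += [
                    [f"g{g}", sample, 1, 20, int(v), int(c)]
                    for v, c in zip(vals, counts)
                ]
        loc = fit_gene_kinetics(table_from_counts(rows_loc), "loc", PARAMS, t)
        glob = fit_gene_kinetics(table_from_counts(rows_glob), "glob", PARAMS, t)
        out = differential_kinetics(loc, glob)
        p = out["p_value"].dropna()
        assert len(p) > 150
        assert kstest(p, "uniform").pvalue > 0.01


class TestCalibrationOnSimulatedKinetics:
    def _one_batch(self, rng, ratio_true, n_genes, t=4.0, reads=200, method="lrt",
                   t_half_range=(0.5, 12.0)):
        rows = []
        for g in range(n_genes):
            t_half = float(np.exp(rng.uniform(*np.log(t_half_range))))
            k_glob = math.log(2) / t_half
            for sample, kdeg in (("loc", k_glob * ratio_true), ("glob", k_glob)):
                f = 1 - math.exp(-kdeg * t)
                n_T, vals, counts = simulate_histogram(rng, f, n_reads=reads)
                rows += [
                    [f"g{g}", sample, 1, 20, int(v), int(c)]
                    for v, c in zip(vals, counts)
                ]
        table = table_from_counts(rows)
        if method == "lrt":
            return differential_kinetics_lrt(table, "loc", "glob", PARAMS, t)
        loc = fit_gene_kinetics(table, "loc", PARAMS, t)
        glob = fit_gene_kinetics(table, "glob", PARAMS, t)
        return differential_kinetics(loc, glob)

    def test_false_positive_rate_and_power(self):
        # false positives over the full half-life range; power in the
        # regime a 4-h pulse can resolve (localized labeling below
        # saturation, i.e. global half-life above ~2.4 h at a 4x ratio)
        rng = np.random.default_rng(25)
        null = pd.concat([self._one_batch(rng, 1.0, 20) for _ in range(10)])
        null = null[null["label"] != "not_tested"]
        fpr = (null["label"] == "transient").mean()
        assert len(null) >= 150
        assert fpr <= 0.05

        alt = pd.concat(
            [self._one_batch(rng, 4.0, 20, t_half_range=(2.4, 12.0)) for _ in range(10)]
        )
        alt = alt[alt["label"] != "not_tested"]
        power = (alt["label"] == "transient").mean()
        assert len(alt) >= 150
        assert power >= 0.80

    def test_lrt_null_p_values_uniform(self):
        rng = np.random.default_rng(26)
        out = self._one_batch(rng, 1.0, 200)
        p = out["p_value"].dropna()
        assert len(p) > 120
        assert kstest(p, "uniform").pvalue > 0.01

    def test_wald_more_conservative_than_lrt_at_saturation(self):
        # both tests agree in the informative regime; at high labeling the
        # Wald z loses power while the LRT retains it
        rng = np.random.default_rng(27)
        lrt = self._one_batch(rng, 4.0, 60, method="lrt")
        rng = np.random.default_rng(27)
        wald = self._one_batch(rng, 4.0, 60, method="wald")
        p_lrt = (lrt[lrt["label"] != "not_tested"]["label"] == "transient").mean()
        p_wald = (wald[wald["label"] != "not_tested"]["label"] == "transient").mean()
        assert p_lrt >= p_wald
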