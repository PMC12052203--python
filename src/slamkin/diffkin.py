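"""Localized-vs-global differential kinetics and dynamics classification.

For each gene with a kinetic estimate in both a compartment-targeted
library and the nucleoplasmic control, the rate ratio
R = k_deg,localized / k_deg,global is tested, p-values are
Benjamini-Hochberg adjusted across tested genes, and genes are labeled:

    transient    R >= 2 and BH-adjusted p < 0.05
    persistent   R <= 1 (no significance requirement by default)
    intermediate otherwise

Two test statistics are provided. ``test_differential`` is a two-sample
Wald z on the log rates with delta-method SEs, computable from kinetic
estimate tables alone. ``test_differential_lrt`` is a per-gene
likelihood-ratio test of a shared rate against free per-library rates on
the underlying conversion histograms; it is the pipeline default because
the Wald statistic's quadratic approximation collapses when labeling
approaches saturation (fraction-new near 1), where the mixture
likelihood is extremely asymmetric.

A strict mode additionally requires padj >= alpha for "persistent"; a
log2-scale mode interprets the ratio threshold as a log2 fold change
(i.e. transient at R >= 2**threshold).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .conversions import ConversionTable
from .kinetics import RateParams, fit_gene_kinetics, mixture_max_loglik

LABELS = ("transient", "persistent", "intermediate", "not_tested")


class DiffKinError(ValueError):
    """Invalid differential-kinetics input."""


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise DiffKinError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def classify(
    ratio: float,
    padj: float,
    ratio_threshold: float = 2.0,
    alpha: float = 0.05,
    strict_persistent: bool = False,
    log2_scale: bool = False,
) -> str:
    """Dynamics label for one gene from its rate ratio and adjusted p."""
    if not ratio > 0:
        raise DiffKinError(f"rate ratio must be > 0, got {ratio}")
    if not 0 <= padj <= 1:
        raise DiffKinError(f"adjusted p must be in [0, 1], got {padj}")
    threshold = 2.0**ratio_threshold if log2_scale else ratio_threshold
    if ratio >= threshold and padj < alpha:
        return "transient"
    if ratio <= 1.0 and (not strict_persistent or padj >= alpha):
        return "persistent"
    return "intermediate"


def test_differential(
    localized: pd.DataFrame,
    global_: pd.DataFrame,
    ratio_threshold: float = 2.0,
    alpha: float = 0.05,
    strict_persistent: bool = False,
    log2_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene differential kinetics between two kinetic-estimate tables.

    Inputs are ``fit_gene_kinetics`` frames (localized = compartment
    library, global_ = control). Genes lacking an ``ok``-flagged estimate
    on either side are reported ``not_tested`` and excluded from the BH
    family.

    Returns columns: gene_id, kdeg_ratio, log2_ratio, z_stat, p_value,
    padj, label.
    """
    cols = ["gene_id", "kdeg_per_h", "se_log_kdeg", "flag"]
    for name, df in (("localized", localized), ("global", global_)):
        missing = set(cols) - set(df.columns)
        if missing:
            raise DiffKinError(f"{name} estimates missing columns: {sorted(missing)}")
    merged = localized[cols].merge(
        global_[cols], on="gene_id", how="outer", suffixes=("_loc", "_glob")
    )
    tested = (merged["flag_loc"] == "ok") & (merged["flag_glob"] == "ok")

    out = pd.DataFrame({"gene_id": merged["gene_id"]})
    ratio = merged["kdeg_per_h_loc"] / merged["kdeg_per_h_glob"]
    se = np.sqrt(merged["se_log_kdeg_loc"] ** 2 + merged["se_log_kdeg_glob"] ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(ratio) / se
    p = 2.0 * norm.sf(np.abs(z))
    out["kdeg_ratio"] = ratio.where(tested)
    out["log2_ratio"] = np.log2(ratio).where(tested)
    out["z_stat"] = pd.Series(z).where(tested)
    out["p_value"] = pd.Series(p).where(tested)
    out["padj"] = np.nan
    out.loc[tested, "padj"] = benjamini_hochberg(out.loc[tested, "p_value"].to_numpy())
    out["label"] = "not_tested"
    out.loc[tested, "label"] = [
        classify(r, q, ratio_threshold, alpha, strict_persistent, log2_scale)
        for r, q in zip(out.loc[tested, "kdeg_ratio"], out.loc[tested, "padj"])
    ]
    return out


def test_differential_lrt(
    table: ConversionTable,
    localized_sample: str,
    global_sample: str,
    params: RateParams,
    t_hours: float,
    min_reads: int = 50,
    ratio_threshold: float = 2.0,
    alpha: float = 0.05,
    strict_persistent: bool = False,
    log2_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene likelihood-ratio differential kinetics on histograms.

    For every gene with an ``ok``-flagged estimate in both libraries, the
    statistic is 2 * (sum of free-fraction maximized log-likelihoods minus
    the shared-fraction maximum on the pooled histogram); with equal pulse
    duration a shared degradation rate is a shared fraction-new, so the
    null has one constrained parameter and the statistic is referred to
    chi-square(1). ``z_stat`` reports the signed root of the statistic.
    Output schema matches ``test_differential``.
    """
    loc_est = fit_gene_kinetics(table, localized_sample, params, t_hours, min_reads)
    glob_est = fit_gene_kinetics(table, global_sample, params, t_hours, min_reads)
    cols = ["gene_id", "kdeg_per_h", "flag"]
    merged = loc_est[cols].merge(
        glob_est[cols], on="gene_id", how="outer", suffixes=("_loc", "_glob")
    )
    tested_mask = (merged["flag_loc"] == "ok") & (merged["flag_glob"] == "ok")

    ratios, zs, ps = [], [], []
    for row in merged.itertuples(index=False):
        if not (row.flag_loc == "ok" and row.flag_glob == "ok"):
            ratios.append(np.nan)
            zs.append(np.nan)
            ps.append(np.nan)
            continue
        h_loc = table.histogram(row.gene_id, localized_sample)
        h_glob = table.histogram(row.gene_id, global_sample)
        ll_loc, _ = mixture_max_loglik(h_loc, params)
        ll_glob, _ = mixture_max_loglik(h_glob, params)
        pooled = (
            np.concatenate([h_loc[0], h_glob[0]]),
            np.concatenate([h_loc[1], h_glob[1]]),
            np.concatenate([h_loc[2], h_glob[2]]),
        )
        ll_null, _ = mixture_max_loglik(pooled, params)
        stat = max(2.0 * (ll_loc + ll_glob - ll_null), 0.0)
        ratio = row.kdeg_per_h_loc / row.kdeg_per_h_glob
        ratios.append(ratio)
        zs.append(math.copysign(math.sqrt(stat), math.log(ratio) if ratio != 1 else 0.0))
        ps.append(float(chi2.sf(stat, df=1)))

    out = pd.DataFrame({"gene_id": merged["gene_id"]})
    out["kdeg_ratio"] = ratios
    out["log2_ratio"] = np.log2(out["kdeg_ratio"])
    out["z_stat"] = zs
    out["p_value"] = ps
    out["padj"] = np.nan
    out.loc[tested_mask, "padj"] = benjamini_hochberg(
        out.loc[tested_mask, "p_value"].to_numpy()
    )
    out["label"] = "not_tested"
    out.loc[tested_mask, "label"] = [
        classify(r, q, ratio_threshold, alpha, strict_persistent, log2_scale)
        for r, q in zip(out.loc[tested_mask, "kdeg_ratio"], out.loc[tested_mask, "padj"])
    ]
    return out
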