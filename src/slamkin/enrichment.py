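"""Compartment-vs-control enrichment on gene-level count matrices.

A deliberately small negative-binomial Wald test: median-of-ratios size
factors, per-gene method-of-moments dispersion shrunk halfway toward a
fitted mean-dispersion trend, and a Wald test on the log fold change with
BH adjustment. A gene is called enriched at fold change > 2 and adjusted
p < 0.05 (the threshold optionally interpreted on the log2 scale).

This is calibrated-by-simulation machinery, not a re-implementation of
any particular published differential-expression stack.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffkin import benjamini_hochberg


class EnrichmentError(ValueError):
    """Invalid count matrix or design."""


@dataclass
class CountMatrix:
    """Genes x samples integer counts with a two-condition design."""

    counts: pd.DataFrame  # index gene_id, columns sample names
    conditions: dict[str, str]  # sample -> "target" | "control"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise EnrichmentError("counts must be non-negative")
        unknown = set(self.conditions) - set(self.counts.columns)
        if unknown:
            raise EnrichmentError(f"conditions for unknown samples: {sorted(unknown)}")
        for cond in ("target", "control"):
            if sum(c == cond for c in self.conditions.values()) < 2:
                raise EnrichmentError(
                    f"condition {cond!r} needs >= 2 replicates for testing"
                )

    def samples(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample column.

    Uses genes with nonzero counts in every sample; the factor for sample
    j is the median over those genes of count_gj / geometric-mean_g.
    """
    mat = counts.to_numpy(float)
    everywhere = (mat > 0).all(axis=1)
    if not everywhere.any():
        raise EnrichmentError(
            "no gene has nonzero counts in all samples; consider a "
            "total-count fallback"
        )
    sub = mat[everywhere]
    geo = np.exp(np.log(sub).mean(axis=1, keepdims=True))
    factors = np.median(sub / geo, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _dispersion_trend(base_mean: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu by least squares on informative genes."""
    use = (disp > 1e-6) & (base_mean > 1)
    if use.sum() < 5:
        return 0.01, 1.0
    X = np.column_stack([np.ones(use.sum()), 1.0 / base_mean[use]])
    coef, *_ = np.linalg.lstsq(X, disp[use], rcond=None)
    a0 = float(max(coef[0], 1e-8))
    a1 = float(max(coef[1], 0.0))
    return a0, a1


def test_enrichment(
    matrix: CountMatrix,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    base_mean_floor: float = 5.0,
    log2_scale: bool = False,
) -> pd.DataFrame:
    """Per-gene target-vs-control NB Wald test.

    Returns columns: gene_id, base_mean, log2_fc, stat, p_value, padj,
    enriched. Genes with base_mean below ``base_mean_floor`` (and all-zero
    genes) are excluded from the BH family; their padj is missing and they
    are never called enriched.
    """
    t_samples = matrix.samples("target")
    c_samples = matrix.samples("control")
    sf = size_factors(matrix.counts)
    norm_counts = matrix.counts / sf

    yt = norm_counts[t_samples].to_numpy(float)
    yc = norm_counts[c_samples].to_numpy(float)
    nt, nc = yt.shape[1], yc.shape[1]
    mu_t = yt.mean(axis=1)
    mu_c = yc.mean(axis=1)
    base_mean = norm_counts.to_numpy(float).mean(axis=1)

    # pooled within-condition variance -> method-of-moments NB dispersion
    ss = yt.var(axis=1, ddof=1) * (nt - 1) + yc.var(axis=1, ddof=1) * (nc - 1)
    pooled_var = ss / (nt + nc - 2)
    grand = (mu_t * nt + mu_c * nc) / (nt + nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = np.where(grand > 0, (pooled_var - grand) / grand**2, 0.0)
    disp_mom = np.clip(disp_mom, 0.0, 10.0)
    a0, a1 = _dispersion_trend(base_mean, disp_mom)
    disp_trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    disp = np.clip(0.5 * disp_mom + 0.5 * disp_trend, 1e-8, 10.0)

    # Wald on ln fold change; Var(ln mean) ~= (1/n) (1/mu + alpha).
    # Group means are used directly (keeps log2_fc exactly invariant to
    # library rescaling); an all-zero group is floored for the log only.
    floor = 1e-8
    log2_fc = np.log2(np.maximum(mu_t, floor) / np.maximum(mu_c, floor))
    var_ln = (1.0 / np.maximum(mu_t, 0.5) + disp) / nt + (
        1.0 / np.maximum(mu_c, 0.5) + disp
    ) / nc
    stat = log2_fc * math.log(2) / np.sqrt(var_ln)
    df = nt + nc - 2
    p = 2.0 * stats.t.sf(np.abs(stat), df)

    out = pd.DataFrame(
        {
            "gene_id": matrix.counts.index,
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "stat": stat,
            "p_value": p,
        }
    ).reset_index(drop=True)
    testable = (base_mean >= base_mean_floor) & (base_mean > 0)
    out["p_value"] = out["p_value"].where(testable)
    out["padj"] = np.nan
    out.loc[testable, "padj"] = benjamini_hochberg(out.loc[testable, "p_value"].to_numpy())
    lfc_threshold = fold_threshold if log2_scale else math.log2(fold_threshold)
    out["enriched"] = (
        testable & (out["log2_fc"] > lfc_threshold) & (out["padj"] < alpha)
    )
    return out


def overlap_summary(n_a: int, n_b: int, shared: int) -> tuple[int, float]:
    """Shared-gene count and its percentage of the union of two sets.

    percent = 100 * shared / (n_a + n_b - shared), reported to one decimal.
    """
    if min(n_a, n_b, shared) < 0:
        raise EnrichmentError("set sizes must be non-negative")
    if shared > min(n_a, n_b):
        raise EnrichmentError(
            f"shared={shared} exceeds the smaller set (min {min(n_a, n_b)})"
        )
    union = n_a + n_b - shared
    percent = 0.0 if union == 0 else round(100.0 * shared / union, 1)
    return shared, percent
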