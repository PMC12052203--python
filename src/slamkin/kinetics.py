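"""Fraction-new, degradation-rate, and half-life estimation.

Each gene's reads are a two-component binomial mixture over conversion
counts: a read made during the s4U pulse converts each of its n_T
thymines with probability p_c, a pre-existing read with the background
probability p_e. The mixture weight f ("fraction new") is estimated per
gene by maximum likelihood; under first-order steady-state turnover
f = 1 - exp(-k_deg * t) for pulse duration t, giving

    k_deg = -ln(1 - f) / t        t_1/2 = ln(2) / k_deg

Standard errors come from the observed Fisher information on logit(f)
and are propagated to ln(k_deg) by the delta method.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit, gammaln, logit

from .conversions import ConversionTable

#: clamp on f keeping k_deg finite and positive
F_EPS = 1e-4


class KineticsError(ValueError):
    """Invalid kinetic-model inputs (rates, fractions, pulse duration)."""


@dataclass(frozen=True)
class RateParams:
    """Background (p_e) and labeled (p_c) per-T conversion probabilities."""

    p_e: float
    p_c: float
    source: str = "fixed"

    def __post_init__(self) -> None:
        if not (0 <= self.p_e < self.p_c <= 1):
            raise KineticsError(
                f"need 0 <= p_e < p_c <= 1, got p_e={self.p_e}, p_c={self.p_c}"
            )


@dataclass
class KineticEstimate:
    """Per-gene kinetic point estimates with uncertainties for one library."""

    gene_id: str
    sample: str
    n_reads: int
    f_hat: float = math.nan
    se_logit_f: float = math.nan
    kdeg: float = math.nan
    se_log_kdeg: float = math.nan
    t_half: float = math.nan
    flag: str = "ok"  # ok | low_reads | boundary


# ---------------------------------------------------------------------------
# closed-form pieces
# ---------------------------------------------------------------------------

def kdeg_from_fraction(f: float, t: float) -> float:
    """Degradation rate (per hour) from fraction-new under steady state."""
    if not 0 < f < 1:
        raise KineticsError(f"fraction new must be in (0, 1), got {f}")
    if t <= 0:
        raise KineticsError(f"pulse duration must be > 0, got {t}")
    return -math.log1p(-f) / t


def half_life(kdeg: float) -> float:
    """Half-life in hours: t_1/2 = ln(2) / k_deg."""
    if kdeg <= 0:
        raise KineticsError(f"k_deg must be > 0, got {kdeg}")
    return math.log(2) / kdeg


def se_log_kdeg_from_logit(f: float, se_logit_f: float) -> float:
    """Delta-method SE of ln(k_deg) from the SE of logit(f).

    d ln k / d f = 1 / [(1-f) * (-ln(1-f))] and d f / d logit f = f (1-f),
    so d ln k / d logit f = f / (-ln(1-f)).
    """
    return se_logit_f * f / (-math.log1p(-f))


# ---------------------------------------------------------------------------
# background and labeled conversion probabilities
# ---------------------------------------------------------------------------

def estimate_background(control_table: ConversionTable) -> float:
    """Pooled background conversion probability from a control library.

    p_e = (sum k + 0.5) / (sum T + 1) over all genes; the pseudocount keeps
    the estimate off zero in clean controls.
    """
    _, sum_T, sum_k = control_table.pooled_totals()
    if sum_T == 0:
        raise KineticsError("control table has no assayable T positions")
    return (sum_k + 0.5) / (sum_T + 1.0)


def _log_binom(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """log Binomial(k; n, p) pmf, safe at p in {0, 1}."""
    coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    if p == 0:
        return np.where(k > 0, -np.inf, coef)
    if p == 1:
        return np.where(k < n, -np.inf, coef)
    return coef + k * math.log(p) + (n - k) * math.log1p(-p)


def estimate_pc_global(
    labeled_tables: ConversionTable | list[ConversionTable],
    p_e: float,
    min_reads: int = 50,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> float:
    """One global labeled-conversion probability by pooled-mixture EM.

    High-coverage genes (>= ``min_reads`` pooled reads) each get a free
    fraction-new; a single p_c is shared. Converged when the pooled
    log-likelihood improves by less than ``tol``. Raises when no gene
    qualifies or when the data carry no labeling signal (p_c estimate not
    above p_e) — callers should then fall back to a configured p_c.
    """
    if isinstance(labeled_tables, ConversionTable):
        labeled_tables = [labeled_tables]
    frames = [t.df for t in labeled_tables if len(t)]
    if not frames:
        raise KineticsError("no labeled data for p_c estimation")
    df = pd.concat(frames, ignore_index=True)
    pooled = df.groupby(["gene_id", "n_T", "k"], sort=True)["n_reads"].sum().reset_index()
    totals = pooled.groupby("gene_id")["n_reads"].sum()
    keep = totals[totals >= min_reads].index
    pooled = pooled[pooled["gene_id"].isin(keep)]
    if pooled.empty:
        raise KineticsError(
            f"no gene reaches {min_reads} reads; use a fixed p_c instead"
        )
    gene_idx, genes = pd.factorize(pooled["gene_id"], sort=True)
    n = pooled["n_T"].to_numpy(float)
    k = pooled["k"].to_numpy(float)
    w = pooled["n_reads"].to_numpy(float)

    f = np.full(len(genes), 0.3)
    p_c = max(10 * p_e, 0.02)
    log_bg = _log_binom(k, n, p_e)
    prev_ll = -np.inf
    for _ in range(max_iter):
        log_new = _log_binom(k, n, p_c)
        fa = np.clip(f[gene_idx], 1e-8, 1 - 1e-8)
        la = np.log(fa) + log_new
        lb = np.log1p(-fa) + log_bg
        ll_row = np.logaddexp(la, lb)
        ll = float(np.sum(w * ll_row))
        resp = np.exp(la - ll_row)  # P(read new | data)
        # M-step
        f = np.bincount(gene_idx, weights=w * resp, minlength=len(genes)) / np.bincount(
            gene_idx, weights=w, minlength=len(genes)
        )
        denom = float(np.sum(w * resp * n))
        if denom <= 0:
            raise KineticsError("p_c unidentifiable: no reads attributed to labeling")
        p_c = float(np.clip(np.sum(w * resp * k) / denom, 1e-6, 1 - 1e-6))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    if p_c <= p_e:
        raise KineticsError(
            f"estimated p_c={p_c:.3g} not above p_e={p_e:.3g}: labeling signal "
            "unidentifiable; use a fixed p_c"
        )
    return p_c


# ---------------------------------------------------------------------------
# per-gene fraction-new MLE
# ---------------------------------------------------------------------------

def _mixture_loglik(
    f: float, n: np.ndarray, k: np.ndarray, w: np.ndarray,
    log_new: np.ndarray, log_bg: np.ndarray,
) -> float:
    la = math.log(f) + log_new
    lb = math.log1p(-f) + log_bg
    return float(np.sum(w * np.logaddexp(la, lb)))


def mixture_max_loglik(
    histogram: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: RateParams,
    eps: float = F_EPS,
) -> tuple[float, float]:
    """(maximized log-likelihood, argmax f) of the mixture for a histogram."""
    n, k, w = (np.asarray(a, float) for a in histogram)
    if n.size == 0 or w.sum() == 0:
        raise KineticsError("empty histogram")
    log_new = _log_binom(k, n, params.p_c)
    log_bg = _log_binom(k, n, params.p_e)
    res = minimize_scalar(
        lambda f: -_mixture_loglik(f, n, k, w, log_new, log_bg),
        bounds=(eps, 1 - eps),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return -float(res.fun), float(res.x)


def estimate_fraction_new(
    histogram: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: RateParams,
    eps: float = F_EPS,
) -> tuple[float, float, str]:
    """MLE of the fraction of new reads for one gene histogram.

    ``histogram`` is (n_T, k, weight) arrays. The likelihood in f is
    unimodal for fixed (p_e, p_c); a bounded scalar optimizer on
    [eps, 1 - eps] finds the maximum, and the SE on logit(f) comes from a
    finite-difference observed Fisher information. Estimates pinned at the
    clamp are flagged "boundary" but retained.
    """
    n, k, w = (np.asarray(a, float) for a in histogram)
    if n.size == 0 or w.sum() == 0:
        raise KineticsError("empty histogram")
    log_new = _log_binom(k, n, params.p_c)
    log_bg = _log_binom(k, n, params.p_e)

    res = minimize_scalar(
        lambda f: -_mixture_loglik(f, n, k, w, log_new, log_bg),
        bounds=(eps, 1 - eps),
        method="bounded",
        options={"xatol": 1e-10},
    )
    f_hat = float(res.x)
    flag = "ok"
    if f_hat <= eps * (1 + 1e-3) or f_hat >= 1 - eps * (1 + 1e-3):
        flag = "boundary"
        f_hat = min(max(f_hat, eps), 1 - eps)

    # observed Fisher information on the logit scale
    theta = logit(f_hat)
    h = 1e-4

    def ll_theta(th: float) -> float:
        return _mixture_loglik(float(expit(th)), n, k, w, log_new, log_bg)

    d2 = (ll_theta(theta + h) - 2 * ll_theta(theta) + ll_theta(theta - h)) / h**2
    se = 1.0 / math.sqrt(max(-d2, 1e-12))
    return f_hat, se, flag


def fit_gene_kinetics(
    table: ConversionTable,
    sample: str,
    params: RateParams,
    t_hours: float,
    min_reads: int = 50,
    pool_replicates: bool = True,
) -> pd.DataFrame:
    """Kinetic estimates for every gene of one library.

    Replicates are pooled into one histogram per gene by default; with
    ``pool_replicates=False`` each replicate is estimated separately and
    combined by an inverse-variance-weighted mean on logit(f). Genes below
    ``min_reads`` are flagged ``low_reads`` and carry no estimate.

    Returns a frame with columns gene_id, sample, n_reads, f_hat,
    se_logit_f, kdeg_per_h, se_log_kdeg, t_half_h, flag.
    """
    if t_hours <= 0:
        raise KineticsError("t_hours must be > 0")
    sub = table.subset(sample)
    rows = []
    for gene_id in sorted(sub.df["gene_id"].unique()):
        if pool_replicates:
            fits = [sub.histogram(gene_id, sample)]
        else:
            reps = sorted(sub.df[sub.df["gene_id"] == gene_id]["replicate"].unique())
            fits = [sub.histogram(gene_id, sample, replicate=r) for r in reps]
        n_reads = int(sum(int(h[2].sum()) for h in fits))
        est = KineticEstimate(gene_id, sample, n_reads)
        if n_reads < min_reads:
            est.flag = "low_reads"
            rows.append(est)
            continue
        thetas, ses, flags = [], [], []
        for h in fits:
            if int(h[2].sum()) == 0:
                continue
            f_hat, se, flag = estimate_fraction_new(h, params)
            thetas.append(logit(f_hat))
            ses.append(se)
            flags.append(flag)
        wts = 1.0 / np.square(ses)
        theta = float(np.sum(wts * np.asarray(thetas)) / np.sum(wts))
        se_logit = float(1.0 / math.sqrt(np.sum(wts)))
        f_hat = float(expit(theta))
        f_hat = min(max(f_hat, F_EPS), 1 - F_EPS)
        est.f_hat = f_hat
        est.se_logit_f = se_logit
        est.kdeg = kdeg_from_fraction(f_hat, t_hours)
        est.se_log_kdeg = se_log_kdeg_from_logit(f_hat, se_logit)
        est.t_half = half_life(est.kdeg)
        est.flag = "boundary" if "boundary" in flags else "ok"
        rows.append(est)
    return pd.DataFrame(
        [
            {
                "gene_id": e.gene_id,
                "sample": e.sample,
                "n_reads": e.n_reads,
                "f_hat": e.f_hat,
                "se_logit_f": e.se_logit_f,
                "kdeg_per_h": e.kdeg,
                "se_log_kdeg": e.se_log_kdeg,
                "t_half_h": e.t_half,
                "flag": e.flag,
            }
            for e in rows
        ]
    )
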