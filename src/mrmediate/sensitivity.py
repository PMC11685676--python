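"""Heterogeneity and pleiotropy diagnostics for an MR analysis.

* Cochran's Q about the IVW estimate (chi-square with m-1 df under
  homogeneity);
* the MR-Egger intercept test (copied from the Egger fit);
* MR-PRESSO: residual-sum-of-squares global pleiotropy test with per-SNP
  outlier detection via parametric simulation, an outlier-corrected IVW
  estimate, and an optional distortion test;
* leave-one-out IVW estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, ivw
from .io import HarmonizedSet


@dataclass
class PressoResult:
    """MR-PRESSO global/outlier/distortion results."""

    global_p: float
    global_rss: float
    outliers: list[str]
    corrected: MREstimate | None
    distortion_p: float | None
    outlier_p: dict = field(default_factory=dict)


@dataclass
class SensitivityReport:
    """All sensitivity diagnostics for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_p: float | None
    presso_global_p: float | None
    presso_outliers: list[str]
    presso_distortion_p: float | None
    loo: pd.DataFrame | None


def cochran_q(h: HarmonizedSet, theta: float) -> tuple[float, int, float]:
    """Cochran's Q = sum_j w_j (Gamma_j - theta*gamma_j)², w_j = 1/sigma_Yj²,
    with a chi-square(m-1) p-value."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 SNPs")
    w = 1.0 / h.se_y**2
    q = float(np.sum(w * (h.beta_y - theta * h.beta_x) ** 2))
    df = h.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_thetas(bx, by, w):
    """Leave-one-out fixed-effects IVW estimates, vectorized.

    Supports 1-D arrays (m,) or 2-D (n_sim, m) batches; returns the same
    shape with entry j = the IVW estimate with SNP j removed.
    """
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def leave_one_out(h: HarmonizedSet, model: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn.

    Returns one row per left-out SNP plus a final row (snp_id = "ALL")
    holding the full-set estimate.
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out requires >= 3 SNPs")
    rows = []
    for j, snp in enumerate(h.snp_ids):
        mask = np.ones(h.n_snp, dtype=bool)
        mask[j] = False
        est = ivw(h.subset(mask), model=model)
        rows.append((snp, est.beta, est.se, est.pvalue))
    full = ivw(h, model=model)
    rows.append(("ALL", full.beta, full.se, full.pvalue))
    return pd.DataFrame(rows, columns=["snp_id", "beta", "se", "pvalue"])


def mr_presso(h: HarmonizedSet, n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed=None,
              distortion: bool = True) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Global test: the observed residual sum of squares
    RSS_obs = sum_j w_j (Gamma_j - gamma_j * theta_(-j))², with theta_(-j)
    the leave-one-out IVW estimate, is compared with its parametric null
    distribution — for each simulation, gamma*_j ~ N(gamma_j, sigma_Xj) and
    Gamma*_j ~ N(gamma_j * theta_(-j), sigma_Yj), and RSS* is recomputed
    with leave-one-out estimates taken on the simulated data.  The global
    p-value uses the add-one correction (1 + #{RSS* >= RSS_obs})/(n_sim+1),
    so it can never reach 0.

    Outlier test: each SNP's observed weighted squared residual is compared
    with its own simulated distribution; per-SNP empirical p-values are
    Bonferroni-corrected by the SNP count and flagged below
    ``outlier_alpha``.  The corrected estimate is IVW on unflagged SNPs.

    Distortion test: the relative change between raw and outlier-corrected
    estimates is compared with the changes produced by removing random
    SNP subsets of the same size.
    """
    m = h.n_snp
    if m < 4:
        raise InsufficientInstrumentsError("MR-PRESSO requires >= 4 SNPs")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    w = 1.0 / sy**2

    theta_loo = _loo_thetas(bx, by, w)
    resid_obs = w * (by - bx * theta_loo) ** 2
    rss_obs = float(np.sum(resid_obs))

    bx_s = rng.normal(bx, sx, size=(n_sim, m))
    by_s = rng.normal(bx * theta_loo, sy, size=(n_sim, m))
    theta_loo_s = _loo_thetas(bx_s, by_s, w)
    resid_s = w * (by_s - bx_s * theta_loo_s) ** 2
    rss_s = resid_s.sum(axis=1)

    global_p = float((1 + np.sum(rss_s >= rss_obs)) / (n_sim + 1))

    p_raw = np.mean(resid_s >= resid_obs[None, :], axis=0)
    p_bonf = np.minimum(1.0, p_raw * m)
    flagged = [s for s, p in zip(h.snp_ids, p_bonf) if p < outlier_alpha]

    corrected = None
    distortion_p = None
    if flagged and m - len(flagged) >= 2:
        keep = ~np.isin(h.snp_ids, flagged)
        corrected = ivw(h.subset(keep))
        if distortion:
            raw = ivw(h)
            d_obs = (corrected.beta - raw.beta) / abs(raw.beta)
            k = len(flagged)
            d_sim = np.empty(n_sim)
            for b in range(n_sim):
                drop = rng.choice(m, size=k, replace=False)
                mask = np.ones(m, dtype=bool)
                mask[drop] = False
                th = (np.sum(w[mask] * bx[mask] * by[mask])
                      / np.sum(w[mask] * bx[mask] ** 2))
                d_sim[b] = (th - raw.beta) / abs(raw.beta)
            distortion_p = float((1 + np.sum(np.abs(d_sim) >= abs(d_obs)))
                                 / (n_sim + 1))
    return PressoResult(global_p, rss_obs, flagged, corrected, distortion_p,
                        outlier_p=dict(zip(h.snp_ids, p_bonf)))


def full_sensitivity(h: HarmonizedSet, estimates, seed=None,
                     n_sim: int = 1000) -> SensitivityReport:
    """Assemble Q, Egger-intercept, MR-PRESSO and leave-one-out diagnostics.

    ``estimates`` must contain the IVW fit (Q is evaluated at its point
    estimate); the Egger intercept is copied from the Egger fit's extras
    when present.  MR-PRESSO and leave-one-out are skipped (fields None)
    when the instrument count is below their minima.
    """
    by_method = {e.method: e for e in estimates}
    if "ivw" not in by_method:
        raise ValueError("full_sensitivity needs an IVW estimate")
    q, df, q_p = cochran_q(h, by_method["ivw"].beta)
    eg = by_method.get("egger")
    presso = mr_presso(h, n_sim=n_sim, seed=seed) if h.n_snp >= 4 else None
    loo = leave_one_out(h) if h.n_snp >= 3 else None
    return SensitivityReport(
        exposure_id=h.exposure_id, outcome_id=h.outcome_id,
        q_stat=q, q_df=df, q_pvalue=q_p,
        egger_intercept=eg.extras.get("intercept") if eg else None,
        egger_intercept_se=eg.extras.get("intercept_se") if eg else None,
        egger_intercept_p=eg.extras.get("intercept_p") if eg else None,
        presso_global_p=presso.global_p if presso else None,
        presso_outliers=presso.outliers if presso else [],
        presso_distortion_p=presso.distortion_p if presso else None,
        loo=loo,
    )
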