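"""Two-sample MR causal-effect estimators.

All estimators consume a :class:`~mrmediate.io.HarmonizedSet` of per-SNP
exposure effects gamma_j (SE sigma_Xj) and outcome effects Gamma_j
(SE sigma_Yj) and return an :class:`MREstimate`.

Methods
-------
wald_ratio
    Single-SNP ratio Gamma/gamma with first-order SE.
ivw
    Inverse-variance-weighted meta-analysis of ratios == weighted regression
    of Gamma on gamma through the origin (weights 1/sigma_Y²).  Default is
    the multiplicative random-effects model: SEs scaled by
    max(1, sqrt(Q/(m-1))), never deflated below fixed-effects.
egger
    Weighted regression with a free intercept after orienting all SNPs to
    the exposure-increasing allele; the intercept is the directional-
    pleiotropy test.  Inference uses t(m-2).
weighted_median
    Interpolated weighted quantile of the per-SNP ratios at q=0.5,
    consistent when valid instruments carry >= 50% of the weight.  SE by
    seeded parametric bootstrap.
mode_estimate
    Kernel-density argmax of the ratios (weighted or simple/"sample" mode),
    consistent when the largest cluster of SNPs is valid.

p-values are two-sided normal except MR-Egger (t with m-2 df).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InsufficientInstrumentsError, UndefinedRatioError
from .io import HarmonizedSet

Z95 = stats.norm.ppf(0.975)

#: number of grid points for the mode estimator's density scan
MODE_GRID_POINTS = 512


@dataclass
class MREstimate:
    """One method's causal-effect estimate on the log-odds (beta) scale.

    ``or_`` and its CI are ``exp`` of the beta-scale values; ``extras``
    carries method-specific quantities (Egger intercept and its SE/p,
    bootstrap replicate count, kernel bandwidth).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    exposure_id: str = ""
    outcome_id: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))


def _finish(method, beta, se, n_snp, h=None, pvalue=None, df_t=None, extras=None):
    beta = float(beta)
    se = float(se)
    if df_t is not None:
        q = stats.t.ppf(0.975, df_t)
        p = 2 * stats.t.sf(abs(beta / se), df_t) if se > 0 else np.nan
    else:
        q = Z95
        p = 2 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
    if pvalue is not None:
        p = pvalue
    return MREstimate(
        method=method, beta=beta, se=se,
        ci_low=beta - q * se, ci_high=beta + q * se,
        pvalue=float(p), n_snp=n_snp,
        exposure_id=getattr(h, "exposure_id", ""),
        outcome_id=getattr(h, "outcome_id", ""),
        extras=extras or {},
    )


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               h: HarmonizedSet | None = None) -> MREstimate:
    """Single-SNP Wald ratio theta = beta_y/beta_x with first-order SE
    |se_y/beta_x|."""
    if beta_x == 0:
        raise UndefinedRatioError("Wald ratio undefined for beta_x = 0")
    theta = beta_y / beta_x
    se = abs(se_y / beta_x)
    return _finish("wald_ratio", theta, se, 1, h)


def _ivw_point(bx, by, w):
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx * bx)
    return s_xy / s_xx, s_xx


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (the primary MR method)."""
    if h.n_snp < 2:
        raise InsufficientInstrumentsError(
            "IVW requires >= 2 SNPs; use wald_ratio for a single instrument")
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    bx, by, sy = h.beta_x, h.beta_y, h.se_y
    w = 1.0 / sy**2
    theta, s_xx = _ivw_point(bx, by, w)
    se = np.sqrt(1.0 / s_xx)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    scale = max(1.0, np.sqrt(q / (h.n_snp - 1)))
    if model == "multiplicative_random":
        se *= scale
    return _finish("ivw", theta, se, h.n_snp, h,
                   extras={"model": model, "q_stat": q, "re_scale": scale})


def egger(h: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: weighted fit of Gamma on gamma with intercept.

    SNPs are first oriented to the exposure-increasing allele (gamma >= 0),
    the convention under which the intercept estimates average directional
    pleiotropy.  Slope and intercept SEs use the multiplicative
    random-effects scale max(1, sqrt(Q_egger/(m-2))); inference is t(m-2).
    """
    m = h.n_snp
    if m < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 SNPs")
    sign = np.where(h.beta_x < 0, -1.0, 1.0)
    x = h.beta_x * sign
    y = h.beta_y * sign
    w = 1.0 / h.se_y**2
    sw = np.sum(w)
    mx = np.sum(w * x) / sw
    my = np.sum(w * y) / sw
    sxx = np.sum(w * (x - mx) ** 2)
    slope = np.sum(w * (x - mx) * (y - my)) / sxx
    intercept = my - slope * mx
    resid = y - intercept - slope * x
    q = float(np.sum(w * resid**2))
    scale2 = max(1.0, q / (m - 2))
    slope_se = np.sqrt(scale2 / sxx)
    int_se = np.sqrt(scale2 * (1.0 / sw + mx**2 / sxx))
    int_p = 2 * stats.t.sf(abs(intercept / int_se), m - 2)
    return _finish("egger", slope, slope_se, m, h, df_t=m - 2,
                   extras={"intercept": float(intercept),
                           "intercept_se": float(int_se),
                           "intercept_p": float(int_p),
                           "q_stat": q})


def _ratio_weights(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP ratios and normalized inverse-variance weights.

    The ratio variance uses the first-order term sigma_Y²/gamma² only.
    """
    theta = h.beta_y / h.beta_x
    w = h.beta_x**2 / h.se_y**2
    return theta, w / np.sum(w)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ww = w[order] / np.sum(w[order])
    p = np.cumsum(ww) - ww / 2.0
    return float(np.interp(0.5, p, th))


def _parametric_bootstrap(h, point_fn, n_boot, seed):
    """SE of a ratio-based estimator by resampling gamma_j, Gamma_j from
    normals centred at the observed effects."""
    if n_boot < 2:
        return np.nan
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = h.beta_x, h.se_x, h.beta_y, h.se_y
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs[bxs == 0] = 1e-300  # guard: ratio undefined at exactly zero
        ests[b] = point_fn(bys / bxs, bxs**2 / sy**2)
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed=None) -> MREstimate:
    """Weighted-median estimator (interpolated weighted quantile at 0.5)."""
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 SNPs")
    theta, w = _ratio_weights(h)
    est = _weighted_median_point(theta, w)
    se = _parametric_bootstrap(
        h, lambda th, wt: _weighted_median_point(th, wt / np.sum(wt)),
        n_boot, seed)
    return _finish("weighted_median", est, se, h.n_snp, h,
                   extras={"n_boot": n_boot})


def _mode_bandwidth(theta: np.ndarray, phi: float) -> float:
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    s = min(sd, iqr / 1.34)
    if s == 0:
        s = max(sd, iqr / 1.34)  # degenerate spread: fall back to the other
    return phi * 0.9 * s * len(theta) ** (-0.2)


def _mode_point(theta: np.ndarray, w: np.ndarray, phi: float) -> float:
    bw = _mode_bandwidth(theta, phi)
    if bw == 0:
        return float(theta[0])  # all ratios identical
    grid = np.linspace(theta.min() - 3 * bw, theta.max() + 3 * bw,
                       MODE_GRID_POINTS)
    dens = np.sum(w[:, None]
                  * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / bw) ** 2),
                  axis=0)
    top = np.flatnonzero(dens == dens.max())
    return float(grid[top].mean())  # argmax ties -> midpoint of tied points


def mode_estimate(h: HarmonizedSet, weighted: bool = True, phi: float = 1.0,
                  n_boot: int = 1000, seed=None) -> MREstimate:
    """Mode-based estimate: Gaussian-kernel density argmax over the ratios.

    ``weighted=True`` uses inverse-variance weights (weighted mode);
    ``weighted=False`` is the simple/"sample" mode with equal weights.
    Bandwidth: phi * 0.9 * min(sd, iqr/1.34) * m^(-1/5).
    """
    if h.n_snp < 3:
        raise InsufficientInstrumentsError("mode estimator requires >= 3 SNPs")
    theta, w = _ratio_weights(h)
    if not weighted:
        w = np.full_like(theta, 1.0 / len(theta))
    est = _mode_point(theta, w, phi)

    def point(th, wt):
        wt = wt / np.sum(wt) if weighted else np.full_like(th, 1.0 / len(th))
        return _mode_point(th, wt, phi)

    se = _parametric_bootstrap(h, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return _finish(method, est, se, h.n_snp, h,
                   extras={"n_boot": n_boot, "phi": phi,
                           "bandwidth": _mode_bandwidth(theta, phi)})


def run_all_methods(h: HarmonizedSet, seed=None, n_boot: int = 1000,
                    ivw_model: str = "multiplicative_random") -> list[MREstimate]:
    """All five estimators with seed-derived substreams; deterministic.

    Degrades gracefully: 2 SNPs -> IVW only; 1 SNP -> Wald ratio only
    (the degradation is recorded in the single estimate's extras).
    """
    m = h.n_snp
    if m == 1:
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0], h)
        est.extras["degraded"] = "single_snp"
        return [est]
    if m == 2:
        est = ivw(h, model=ivw_model)
        est.extras["degraded"] = "two_snps"
        return [est]
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    children = ss.spawn(3)
    return [
        ivw(h, model=ivw_model),
        egger(h),
        weighted_median(h, n_boot=n_boot, seed=children[0]),
        mode_estimate(h, weighted=True, n_boot=n_boot, seed=children[1]),
        mode_estimate(h, weighted=False, n_boot=n_boot, seed=children[2]),
    ]


def direction_consistent(estimates) -> bool:
    """True iff every estimate's beta strictly shares one sign (a beta of
    exactly 0 counts as inconsistent)."""
    betas = np.array([e.beta for e in estimates])
    if len(betas) == 0:
        raise ValueError("need at least one estimate")
    return bool(np.all(betas > 0) or np.all(betas < 0))
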