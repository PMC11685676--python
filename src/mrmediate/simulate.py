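"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a summary-level MR
analysis assumes, in place of real biobank downloads: per-SNP true
instrument effects, optional horizontal pleiotropy (balanced or
directional), block LD, and independent estimation noise in the exposure
and outcome samples.

Model (per SNP j, standardized-trait approximation):

* maf_j ~ Uniform(maf_range); true effect gamma_j ~ N(0, gamma_sd²), then
  the effect allele is oriented to the exposure-increasing allele so
  gamma_j >= 0 — the convention under which "directional" pleiotropy and
  the MR-Egger intercept are meaningful;
* pleiotropy alpha_j = 0 for valid SNPs; for the invalid fraction,
  alpha_j ~ N(pleiotropy_mean, pleiotropy_sd²) (balanced mode forces
  mean 0);
* true outcome effect Gamma_j = theta_xy * gamma_j + alpha_j;
* sampling SE sigma = 1/sqrt(2 n maf (1-maf)); observed effects are truth
  plus N(0, sigma²) noise, independent between the two samples; p-values
  are two-sided Wald tests.

One global seed expands into named substreams (maf, gamma, pleiotropy,
noise per sample) so changing one component leaves the others fixed.
Defaults (m=50 instruments, n=100,000, gamma_sd=0.03, maf in [0.05, 0.5])
give strong instruments (mean F well above 10) whose p-values
predominantly pass the 1e-5 exposure threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .instruments import LDMatrix
from .io import COLUMNS, SummaryStatTable

_STREAMS = ("maf", "gamma", "pleiotropy", "noise_x", "noise_y",
            "noise_m", "delta")


@dataclass
class SimConfig:
    """Parameters of the generative model (see module docstring)."""

    m_snps: int = 50
    n_exposure: int = 100_000
    n_mediator: int = 100_000
    n_outcome: int = 100_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.03
    theta_xy: float = 0.0
    theta_xm: float = 0.0
    theta_my: float = 0.0
    direct_xy: float = 0.0
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_mean: float = 0.01
    pleiotropy_sd: float = 0.005
    invalid_fraction: float = 0.0
    ld_block_size: int = 1
    ld_within_r2: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if min(self.m_snps, self.n_exposure, self.n_mediator,
               self.n_outcome) <= 0:
            raise ValueError("counts and sample sizes must be positive")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(c)
                for name, c in zip(_STREAMS, children)}


def _sigma(n: int, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    return 2 * stats.norm.sf(np.abs(beta / se))


def _table(trait_id, trait_class, snp_ids, chrom, pos, maf, beta, se, n):
    df = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "eaf": maf, "beta": beta, "se": se,
        "pvalue": np.clip(_wald_p(beta, se), 1e-300, 1.0), "n": float(n),
    })[COLUMNS]
    return SummaryStatTable(trait_id, df, trait_class)


def _draw_instruments(cfg: SimConfig, rngs, m: int):
    maf = rngs["maf"].uniform(*cfg.maf_range, size=m)
    gamma = np.abs(rngs["gamma"].normal(0.0, cfg.gamma_sd, size=m))
    k = int(round(cfg.invalid_fraction * m))
    invalid = np.zeros(m, dtype=bool)
    alpha = np.zeros(m)
    if cfg.pleiotropy_mode != "none" and k > 0:
        idx = rngs["pleiotropy"].choice(m, size=k, replace=False)
        invalid[idx] = True
        mean = 0.0 if cfg.pleiotropy_mode == "balanced" else cfg.pleiotropy_mean
        alpha[idx] = rngs["pleiotropy"].normal(mean, cfg.pleiotropy_sd, size=k)
    return maf, gamma, alpha, invalid


def simulate_pair(cfg: SimConfig):
    """Exposure/outcome summary statistics for one two-sample MR analysis.

    Returns ``(exposure, outcome, truth)`` where truth is a dict carrying
    every latent quantity (gamma, alpha, invalid mask, sigmas, theta).
    """
    rngs = cfg.rngs()
    m = cfg.m_snps
    maf, gamma, alpha, invalid = _draw_instruments(cfg, rngs, m)
    Gamma = cfg.theta_xy * gamma + alpha

    sx = _sigma(cfg.n_exposure, maf)
    sy = _sigma(cfg.n_outcome, maf)
    bx = gamma + rngs["noise_x"].normal(0.0, sx)
    by = Gamma + rngs["noise_y"].normal(0.0, sy)

    ids = [f"rs{j + 1:06d}" for j in range(m)]
    pos = [1_000_000 * (j + 1) for j in range(m)]
    exposure = _table("sim_exposure", "metabolite", ids, "1", pos, maf,
                      bx, sx, cfg.n_exposure)
    outcome = _table("sim_outcome", "outcome", ids, "1", pos, maf,
                     by, sy, cfg.n_outcome)
    truth = {"gamma": gamma, "alpha": alpha, "invalid": invalid, "maf": maf,
             "sigma_x": sx, "sigma_y": sy, "theta_xy": cfg.theta_xy,
             "snp_ids": ids}
    return exposure, outcome, truth


def simulate_mediation_triple(cfg: SimConfig):
    """Exposure/mediator/outcome tables with a planted causal chain.

    Two disjoint instrument blocks of ``m_snps`` SNPs each:

    * X-instruments (chromosome 1) affect the exposure directly (gamma),
      the mediator through theta_xm, and the outcome through the total
      effect theta_xm*theta_my + direct_xy;
    * M-instruments (chromosome 2) affect the mediator only (delta) and
      the outcome through theta_my.

    All three tables contain every SNP (effects near zero where no path
    exists) so harmonization and the mediator-instrument adjustment are
    exercised exactly as on real data.  Truth includes the planted total
    effect and mediated proportion.
    """
    rngs = cfg.rngs()
    m = cfg.m_snps
    maf_x, gamma, alpha, invalid = _draw_instruments(cfg, rngs, m)
    maf_m = rngs["maf"].uniform(*cfg.maf_range, size=m)
    delta = np.abs(rngs["delta"].normal(0.0, cfg.gamma_sd, size=m))

    theta_t = cfg.theta_xm * cfg.theta_my + cfg.direct_xy
    # truth per block: effects on X, M, Y
    tx = np.concatenate([gamma, np.zeros(m)])
    tm = np.concatenate([cfg.theta_xm * gamma, delta])
    ty = np.concatenate([theta_t * gamma + alpha, cfg.theta_my * delta])
    maf = np.concatenate([maf_x, maf_m])

    sx = _sigma(cfg.n_exposure, maf)
    sm = _sigma(cfg.n_mediator, maf)
    sy = _sigma(cfg.n_outcome, maf)
    bx = tx + rngs["noise_x"].normal(0.0, sx)
    bm = tm + rngs["noise_m"].normal(0.0, sm)
    by = ty + rngs["noise_y"].normal(0.0, sy)

    ids = ([f"rsX{j + 1:06d}" for j in range(m)]
           + [f"rsM{j + 1:06d}" for j in range(m)])
    chrom = ["1"] * m + ["2"] * m
    pos = [1_000_000 * (j + 1) for j in range(m)] * 2
    exposure = _table("sim_metabolite", "metabolite", ids, chrom, pos, maf,
                      bx, sx, cfg.n_exposure)
    mediator = _table("sim_immune", "immune", ids, chrom, pos, maf,
                      bm, sm, cfg.n_mediator)
    outcome = _table("sim_crc", "outcome", ids, chrom, pos, maf,
                     by, sy, cfg.n_outcome)
    truth = {
        "gamma": gamma, "delta": delta, "alpha": alpha, "invalid": invalid,
        "theta_xm": cfg.theta_xm, "theta_my": cfg.theta_my,
        "direct_xy": cfg.direct_xy, "theta_total": theta_t,
        "indirect": cfg.theta_xm * cfg.theta_my,
        "proportion_pct": (100.0 * cfg.theta_xm * cfg.theta_my / theta_t
                           if theta_t != 0 else np.nan),
        "x_instruments": ids[:m], "m_instruments": ids[m:],
    }
    return exposure, mediator, outcome, truth


def simulate_ld(cfg: SimConfig, snp_ids) -> LDMatrix:
    """Block-diagonal r² matrix: ``ld_within_r2`` inside consecutive blocks
    of ``ld_block_size`` SNPs (last block may be smaller), 0 elsewhere,
    unit diagonal."""
    ids = list(snp_ids)
    m = len(ids)
    r2 = np.zeros((m, m))
    b = max(1, cfg.ld_block_size)
    for start in range(0, m, b):
        stop = min(start + b, m)
        r2[start:stop, start:stop] = cfg.ld_within_r2
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(ids, r2)


def catalog(cfg: SimConfig, n_traits: int, n_causal: int, theta: float,
            trait_class: str = "metabolite", prefix: str = "T"):
    """A catalog of ``n_traits`` exposures against one shared outcome; the
    first ``n_causal`` exposures carry a true effect ``theta`` on it.

    Used by the screening-stage drivers; returns (exposures, outcome).
    Each trait gets its own instrument block (distinct SNP ids) so the
    shared outcome table concatenates all blocks.
    """
    exposures = []
    out_frames = []
    for t in range(n_traits):
        sub = replace(cfg, seed=np.random.SeedSequence((cfg.seed, t)).generate_state(1)[0] % (2**31),
                      theta_xy=theta if t < n_causal else 0.0)
        exp, out, _ = simulate_pair(sub)
        tag = f"{prefix}{t:03d}"
        for tab in (exp, out):
            tab.df["snp_id"] = tag + tab.df["snp_id"]
            tab.df["chrom"] = str(t + 1)
        exp.trait_id = f"{trait_class}_{t:03d}"
        exp.trait_class = trait_class
        exposures.append(exp)
        out_frames.append(out.df)
    outcome = SummaryStatTable("sim_outcome",
                               pd.concat(out_frames, ignore_index=True),
                               "outcome")
    return exposures, outcome
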