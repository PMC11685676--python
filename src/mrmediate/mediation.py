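"""Two-step mediation MR: screening, product-of-coefficients, reverse MR.

The decision logic mirrors a strict exposure screen followed by a two-step
mediation analysis over exposure -> mediator -> outcome pathways:

* ``screen`` applies the four strict gates — IVW p < 0.05, direction of
  effect consistent across all five methods, MR-PRESSO global p > 0.05,
  Egger-intercept (pleiotropy) p > 0.05;
* ``run_mediation`` estimates the total effect beta_T (exposure->outcome),
  beta_A (exposure->mediator) and beta_B (mediator->outcome, with the
  mediator's instruments adjusted by removing the SNPs used in the
  exposure->mediator analysis and their LD partners), then combines them
  with the product-of-coefficients (Sobel) method and computes the
  mediated proportion beta_A*beta_B / beta_T;
* ``reverse_mr_check`` runs MR with outcome and exposure swapped; a
  significant reverse effect disqualifies the pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import MRError, NoInstrumentsError, UndefinedProportionError
from .estimators import Z95, MREstimate, direction_consistent, ivw, run_all_methods, wald_ratio
from .instruments import InstrumentSet, LDMatrix, SelectionParams, select_instruments
from .io import HarmonizedSet, SummaryStatTable, harmonize
from .sensitivity import SensitivityReport, full_sensitivity

logger = logging.getLogger(__name__)


@dataclass
class ScreenDecision:
    """Outcome of the four strict screening gates for one pair."""

    exposure_id: str
    outcome_id: str
    ivw_p: float
    direction_ok: bool
    presso_ok: bool
    pleiotropy_ok: bool
    passed: bool = field(init=False)
    alpha: float = 0.05

    def __post_init__(self):
        self.passed = (self.ivw_p < self.alpha and self.direction_ok
                       and self.presso_ok and self.pleiotropy_ok)


@dataclass
class MediationResult:
    """One exposure -> mediator -> outcome pathway.

    ``proportion`` is the mediated proportion as a signed percentage
    (indirect / beta_t * 100); it may be negative or exceed 100
    (inconsistent mediation, flagged by ``inconsistent``).
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    beta_t: float
    se_t: float
    indirect: float
    indirect_se: float
    z: float
    pvalue: float
    ci_low: float
    ci_high: float
    proportion: float
    inconsistent: bool
    reverse_flagged: bool
    mc_ci_low: float | None = None
    mc_ci_high: float | None = None
    n_snp_a: int = 0
    n_snp_b: int = 0
    n_snp_t: int = 0


def screen(estimates, sens: SensitivityReport, alpha: float = 0.05) -> ScreenDecision:
    """Evaluate the four strict gates independently and conjoin them.

    A missing MR-PRESSO global p (too few instruments) fails its gate: the
    screen demands positive evidence of no outlier interference.
    """
    by_method = {e.method: e for e in estimates}
    if "ivw" not in by_method:
        raise ValueError("screen requires an IVW estimate")
    ivw_p = by_method["ivw"].pvalue
    presso_p = sens.presso_global_p
    pleio_p = sens.egger_intercept_p
    return ScreenDecision(
        exposure_id=sens.exposure_id, outcome_id=sens.outcome_id,
        ivw_p=ivw_p,
        direction_ok=direction_consistent(estimates),
        presso_ok=presso_p is not None and presso_p > alpha,
        pleiotropy_ok=pleio_p is not None and pleio_p > alpha,
        alpha=alpha,
    )


def adjusted_mediator_instruments(mediator_ivs: InstrumentSet,
                                  exposure_mediator_ivs: InstrumentSet,
                                  ld: LDMatrix, r2_max: float = 0.001,
                                  remove_ld_partners: bool = True) -> InstrumentSet:
    """Remove from the mediator's instruments every SNP used in the
    exposure->mediator analysis (and, by default, any SNP in LD r² >=
    ``r2_max`` with one), adjusting the mediator->outcome step for the
    exposure."""
    used = set(exposure_mediator_ivs.snp_ids)

    def excluded(snp: str) -> bool:
        if snp in used:
            return True
        if remove_ld_partners:
            return any(ld.r2_between(snp, u) >= r2_max for u in used)
        return False

    keep = [not excluded(s) for s in mediator_ivs.snp_ids]
    df = mediator_ivs.df.loc[keep].reset_index(drop=True)
    if df.empty:
        raise NoInstrumentsError(
            f"adjusting {mediator_ivs.exposure_id!r} removed every instrument",
            stage="mediator_adjustment")
    att = dict(mediator_ivs.attrition)
    att["mediator_adjustment"] = mediator_ivs.n_snp - len(df)
    return InstrumentSet(mediator_ivs.exposure_id, df, att)


def sobel(beta_a: float, se_a: float, beta_b: float, se_b: float):
    """Product-of-coefficients indirect effect with first-order (delta
    method) SE: sqrt(beta_a²·se_b² + beta_b²·se_a²).

    Returns (indirect, indirect_se, z, pvalue, ci_low, ci_high).
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    indirect = beta_a * beta_b
    se = np.sqrt(beta_a**2 * se_b**2 + beta_b**2 * se_a**2)
    if se == 0:
        z, p = 0.0, 1.0
    else:
        z = indirect / se
        p = 2 * stats.norm.sf(abs(z))
    return (float(indirect), float(se), float(z), float(p),
            float(indirect - Z95 * se), float(indirect + Z95 * se))


def mediated_proportion(indirect: float, beta_t: float,
                        floor: float = 1e-8) -> tuple[float, bool]:
    """Mediated proportion indirect/beta_t as a signed percentage.

    May be negative or exceed 100% (inconsistent mediation, when the
    indirect and total effects point in opposite directions — flagged).
    """
    if abs(beta_t) < floor:
        raise UndefinedProportionError(
            f"total effect {beta_t} below floor {floor}; proportion undefined")
    prop = indirect / beta_t * 100.0
    inconsistent = indirect != 0 and np.sign(indirect) != np.sign(beta_t)
    return float(prop), bool(inconsistent)


def _mr_leg(exposure: SummaryStatTable, outcome: SummaryStatTable,
            ld: LDMatrix, params: SelectionParams) -> tuple[MREstimate, HarmonizedSet, InstrumentSet]:
    """Instrument selection -> harmonization -> IVW for one causal leg."""
    ivs = select_instruments(exposure, outcome, ld, params)
    iv_table = SummaryStatTable(exposure.trait_id, ivs.df[list(exposure.df.columns)],
                                exposure.trait_class)
    h = harmonize(iv_table, outcome)
    if h.n_snp >= 2:
        est = ivw(h)
    else:
        est = wald_ratio(h.beta_x[0], h.se_x[0], h.beta_y[0], h.se_y[0], h)
    return est, h, ivs


def reverse_mr_check(outcome_table: SummaryStatTable,
                     exposure_table: SummaryStatTable, ld: LDMatrix,
                     params: SelectionParams | None = None,
                     alpha: float = 0.05):
    """Test for reverse causation by running MR with the outcome as the
    exposure (instruments at genome-wide significance).

    Returns ``(flag, estimate)``: flag True when the reverse IVW p < alpha
    (pathway must be excluded).  When no reverse instruments can be
    selected the flag is False with a warning (reverse effect unassessable).
    """
    params = params or SelectionParams(p_threshold=5e-8)
    try:
        est, _, _ = _mr_leg(outcome_table, exposure_table, ld, params)
    except MRError as exc:
        logger.warning("reverse MR %s -> %s not assessable: %s",
                       outcome_table.trait_id, exposure_table.trait_id, exc)
        return False, None
    return bool(est.pvalue < alpha), est


@dataclass
class MediationParams:
    """Knobs of the two-step mediation analysis."""

    selection: SelectionParams = field(default_factory=SelectionParams)
    reverse_selection: SelectionParams = field(
        default_factory=lambda: SelectionParams(p_threshold=5e-8))
    alpha: float = 0.05
    proportion_floor: float = 1e-8
    adjust_r2_max: float = 0.001
    #: require each leg to pass the strict screen (off: estimate regardless)
    strict_legs: bool = False
    #: Monte-Carlo CI replicates for the indirect effect (0 disables)
    n_mc: int = 5000
    run_reverse: bool = True


def run_mediation(exposure: SummaryStatTable, mediator: SummaryStatTable,
                  outcome: SummaryStatTable, ld: LDMatrix,
                  params: MediationParams | None = None,
                  seed=None) -> MediationResult:
    """Full two-step mediation for one exposure -> mediator -> outcome triple.

    Step 0: total effect beta_T (exposure -> outcome IVW).
    Step 1: beta_A (exposure -> mediator IVW).
    Step 2: beta_B (mediator -> outcome IVW on instruments adjusted for the
    exposure).  Then the Sobel product-of-coefficients test, the mediated
    proportion, and (optionally) a reverse-MR check of outcome -> exposure.

    With ``params.strict_legs`` each leg must pass the four-gate screen.
    Deterministic given identical inputs and seed.
    """
    params = params or MediationParams()
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(4)

    legs = {}
    for name, (exp_t, out_t) in {
        "total": (exposure, outcome),
        "exposure_mediator": (exposure, mediator),
    }.items():
        try:
            legs[name] = _mr_leg(exp_t, out_t, ld, params.selection)
        except MRError as exc:
            raise MRError(f"mediation leg {name!r} failed: {exc}") from exc

    est_t, h_t, _ = legs["total"]
    est_a, h_a, ivs_a = legs["exposure_mediator"]

    try:
        ivs_m = select_instruments(mediator, outcome, ld, params.selection)
        ivs_b = adjusted_mediator_instruments(ivs_m, ivs_a, ld,
                                              params.adjust_r2_max)
        iv_table = SummaryStatTable(mediator.trait_id,
                                    ivs_b.df[list(mediator.df.columns)],
                                    mediator.trait_class)
        h_b = harmonize(iv_table, outcome)
        est_b = (ivw(h_b) if h_b.n_snp >= 2 else
                 wald_ratio(h_b.beta_x[0], h_b.se_x[0], h_b.beta_y[0],
                            h_b.se_y[0], h_b))
    except MRError as exc:
        raise MRError(f"mediation leg 'mediator_outcome' failed: {exc}") from exc

    if params.strict_legs:
        for name, (est, h) in {"total": (est_t, h_t),
                               "exposure_mediator": (est_a, h_a),
                               "mediator_outcome": (est_b, h_b)}.items():
            if h.n_snp < 3:
                raise MRError(f"leg {name!r} has too few SNPs for the strict screen")
            ests = run_all_methods(h, seed=sub[0], n_boot=200)
            sens = full_sensitivity(h, ests, seed=sub[1], n_sim=500)
            dec = screen(ests, sens, alpha=params.alpha)
            if not dec.passed:
                raise MRError(f"leg {name!r} failed the strict screen")

    indirect, ind_se, z, p, lo, hi = sobel(est_a.beta, est_a.se,
                                           est_b.beta, est_b.se)
    prop, inconsistent = mediated_proportion(indirect, est_t.beta,
                                             params.proportion_floor)

    mc_lo = mc_hi = None
    if params.n_mc:
        rng = np.random.default_rng(sub[2])
        draws = (rng.normal(est_a.beta, est_a.se, params.n_mc)
                 * rng.normal(est_b.beta, est_b.se, params.n_mc))
        mc_lo, mc_hi = (float(v) for v in np.percentile(draws, [2.5, 97.5]))

    reverse_flagged = False
    if params.run_reverse:
        reverse_flagged, _ = reverse_mr_check(outcome, exposure, ld,
                                              params.reverse_selection,
                                              params.alpha)

    return MediationResult(
        exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
        beta_a=est_a.beta, se_a=est_a.se,
        beta_b=est_b.beta, se_b=est_b.se,
        beta_t=est_t.beta, se_t=est_t.se,
        indirect=indirect, indirect_se=ind_se, z=z, pvalue=p,
        ci_low=lo, ci_high=hi, proportion=prop, inconsistent=inconsistent,
        reverse_flagged=reverse_flagged,
        mc_ci_low=mc_lo, mc_ci_high=mc_hi,
        n_snp_a=h_a.n_snp, n_snp_b=h_b.n_snp, n_snp_t=h_t.n_snp,
    )
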