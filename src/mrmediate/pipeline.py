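"""Catalog-scale orchestration: screen many exposures, then mediate.

Mirrors the study design of a metabolome/immunome-wide MR screen: every
exposure in a catalog is run through instrument selection, harmonization,
the five estimators, the sensitivity suite and the four-gate strict screen
against one outcome; exposures and mediators that pass are crossed in the
two-step mediation stage, and reverse-MR-flagged pathways are removed.

Per-exposure failures (no instruments, empty harmonization) are logged and
skipped, never fatal — a 1,400-trait catalog run must survive individual
failures.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError, MRError
from .estimators import run_all_methods
from .instruments import LDMatrix, SelectionParams, select_instruments
from .io import SummaryStatTable, harmonize, write_manifest, write_results
from .mediation import MediationParams, run_mediation, screen
from .sensitivity import full_sensitivity

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    exposure_p: float = 1e-5
    outcome_p: float = 5e-8
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    maf_min: float = 0.01
    alpha: float = 0.05
    ivw_model: str = "multiplicative_random"
    n_boot: int = 1000
    presso_n_sim: int = 1000
    n_mc: int = 5000
    fdr: bool = False
    seed: int = 0

    def selection_params(self) -> SelectionParams:
        return SelectionParams(p_threshold=self.exposure_p,
                               r2_max=self.r2_max, window_kb=self.window_kb,
                               outcome_p=self.outcome_p,
                               f_min=self.f_min, maf_min=self.maf_min)

    def mediation_params(self) -> MediationParams:
        return MediationParams(selection=self.selection_params(),
                               alpha=self.alpha, n_mc=self.n_mc,
                               adjust_r2_max=self.r2_max)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _estimate_row(e):
    return {
        "exposure": e.exposure_id, "outcome": e.outcome_id,
        "method": e.method, "nsnp": e.n_snp, "beta": e.beta, "se": e.se,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "pvalue": e.pvalue,
        "or": e.or_, "or_ci_low": e.or_low, "or_ci_high": e.or_high,
    }


def run_screen_stage(catalog, outcome: SummaryStatTable, ld: LDMatrix,
                     cfg: RunConfig):
    """Screen every exposure in ``catalog`` against ``outcome``.

    Returns ``(decisions, estimates, sensitivity)`` DataFrames.  Exposures
    whose instrument selection or harmonization fails are recorded in the
    decision table with ``passed=False`` and an error note.
    """
    if not catalog:
        raise ConfigurationError("exposure catalog is empty")
    sel = cfg.selection_params()
    ss = np.random.SeedSequence(cfg.seed)
    decisions, est_rows, sens_rows = [], [], []
    for exp, child in zip(catalog, ss.spawn(len(catalog))):
        sub = child.spawn(2)
        try:
            ivs = select_instruments(exp, outcome, ld, sel)
            iv_table = SummaryStatTable(exp.trait_id,
                                        ivs.df[list(exp.df.columns)],
                                        exp.trait_class)
            h = harmonize(iv_table, outcome)
            ests = run_all_methods(h, seed=sub[0], n_boot=cfg.n_boot,
                                   ivw_model=cfg.ivw_model)
            sens = full_sensitivity(h, ests, seed=sub[1],
                                    n_sim=cfg.presso_n_sim)
            dec = screen(ests, sens, alpha=cfg.alpha)
        except MRError as exc:
            logger.warning("exposure %s skipped: %s", exp.trait_id, exc)
            decisions.append({"exposure": exp.trait_id,
                              "outcome": outcome.trait_id,
                              "ivw_p": np.nan, "direction_ok": False,
                              "presso_ok": False, "pleiotropy_ok": False,
                              "passed": False, "error": str(exc)})
            continue
        decisions.append({"exposure": dec.exposure_id,
                          "outcome": dec.outcome_id, "ivw_p": dec.ivw_p,
                          "direction_ok": dec.direction_ok,
                          "presso_ok": dec.presso_ok,
                          "pleiotropy_ok": dec.pleiotropy_ok,
                          "passed": dec.passed, "error": ""})
        est_rows += [_estimate_row(e) for e in ests]
        sens_rows.append({"exposure": sens.exposure_id,
                          "outcome": sens.outcome_id,
                          "q_stat": sens.q_stat, "q_df": sens.q_df,
                          "q_pvalue": sens.q_pvalue,
                          "egger_intercept": sens.egger_intercept,
                          "egger_intercept_p": sens.egger_intercept_p,
                          "presso_global_p": sens.presso_global_p,
                          "presso_outliers": ",".join(sens.presso_outliers)})
    decisions = pd.DataFrame(decisions)
    n_passed = int(decisions["passed"].sum())
    logger.info("screen stage: %d/%d exposures passed", n_passed, len(catalog))
    return decisions, pd.DataFrame(est_rows), pd.DataFrame(sens_rows)


_MEDIATION_COLS = ["exposure", "mediator", "outcome", "beta_a", "se_a",
                   "beta_b", "se_b", "beta_t", "se_t", "indirect",
                   "indirect_se", "z", "pvalue", "ci_low", "ci_high",
                   "mc_ci_low", "mc_ci_high", "proportion_pct",
                   "inconsistent", "reverse_flagged"]


def run_mediation_stage(passed_exposures, passed_mediators,
                        outcome: SummaryStatTable, ld: LDMatrix,
                        cfg: RunConfig) -> pd.DataFrame:
    """Two-step mediation over all exposure x mediator pairs.

    A pair proceeds only when the exposure -> mediator leg is significant
    (that leg is fitted inside :func:`run_mediation`; pairs whose legs fail
    are logged and skipped).  Reverse-MR-flagged pathways are removed from
    the final table, which is sorted by Sobel p-value.  An optional
    Benjamini-Hochberg column is appended with ``cfg.fdr`` (informational
    only; pass/fail still uses raw p).
    """
    mpar = cfg.mediation_params()
    ss = np.random.SeedSequence((cfg.seed, 1))
    rows = []
    pairs = [(e, m) for e in passed_exposures for m in passed_mediators]
    for (exp, med), child in zip(pairs, ss.spawn(max(1, len(pairs)))):
        try:
            res = run_mediation(exp, med, outcome, ld, mpar,
                                seed=child.generate_state(1)[0] % (2**31))
        except MRError as exc:
            logger.warning("pathway %s -> %s skipped: %s",
                           exp.trait_id, med.trait_id, exc)
            continue
        # step-1 significance gate: exposure -> mediator leg
        a_p = (2 * stats.norm.sf(abs(res.beta_a / res.se_a))
               if res.se_a > 0 else 1.0)
        if a_p >= cfg.alpha:
            continue
        if res.reverse_flagged:
            logger.info("pathway %s -> %s removed by reverse MR",
                        exp.trait_id, med.trait_id)
            continue
        rows.append({"exposure": res.exposure_id, "mediator": res.mediator_id,
                     "outcome": res.outcome_id, "beta_a": res.beta_a,
                     "se_a": res.se_a, "beta_b": res.beta_b, "se_b": res.se_b,
                     "beta_t": res.beta_t, "se_t": res.se_t,
                     "indirect": res.indirect, "indirect_se": res.indirect_se,
                     "z": res.z, "pvalue": res.pvalue, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "mc_ci_low": res.mc_ci_low,
                     "mc_ci_high": res.mc_ci_high,
                     "proportion_pct": res.proportion,
                     "inconsistent": res.inconsistent,
                     "reverse_flagged": res.reverse_flagged})
    table = pd.DataFrame(rows, columns=_MEDIATION_COLS)
    if table.empty:
        logger.warning("mediation stage: no passing pathways")
        return table
    table = table.sort_values("pvalue", kind="mergesort").reset_index(drop=True)
    if cfg.fdr:
        p = table["pvalue"].to_numpy()
        order = np.argsort(p)
        q = np.empty_like(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        table["fdr_bh"] = np.minimum(q, 1.0)
    return table


def run_all(catalog_exposures, catalog_mediators, outcome, ld,
            cfg: RunConfig, out_dir=None):
    """Screen both catalogs, mediate the passers, optionally write TSVs +
    a JSON run-manifest.  Returns a dict of result DataFrames."""
    dec_e, est_e, sens_e = run_screen_stage(catalog_exposures, outcome, ld, cfg)
    dec_m, est_m, sens_m = run_screen_stage(catalog_mediators, outcome, ld, cfg)
    passed_e = [t for t in catalog_exposures
                if t.trait_id in set(dec_e.loc[dec_e["passed"], "exposure"])]
    passed_m = [t for t in catalog_mediators
                if t.trait_id in set(dec_m.loc[dec_m["passed"], "exposure"])]
    mediation = run_mediation_stage(passed_e, passed_m, outcome, ld, cfg)
    results = {
        "screen_exposures": dec_e, "screen_mediators": dec_m,
        "estimates": pd.concat([est_e, est_m], ignore_index=True),
        "sensitivity": pd.concat([sens_e, sens_m], ignore_index=True),
        "mediation": mediation,
    }
    if out_dir is not None:
        write_results(results, out_dir)
        write_manifest(out_dir, dataclasses.asdict(cfg), cfg.seed,
                       inputs={"n_exposures": len(catalog_exposures),
                               "n_mediators": len(catalog_mediators),
                               "outcome": outcome.trait_id})
    return results
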