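"""Genetic-instrument selection for two-sample MR.

Implements the standard instrument-selection cascade for summary-level MR:

1. genome-wide/suggestive significance filter on the exposure GWAS
   (p < 5e-8 for well-powered outcomes, p < 1e-5 for molecular traits);
2. greedy LD clumping (r² < 0.001 within a 10,000 kb window by default)
   against a local precomputed r² matrix;
3. exclusion of SNPs directly associated with the outcome (p < 5e-8);
4. instrument-strength filtering: per-SNP F > 10 and MAF > 0.01.

Proxy substitution (r² > 0.8) is available for SNPs missing from an outcome
GWAS but is off by default in the pipeline.

LD comes from a local symmetric r² matrix (square TSV with SNP-id header, or
long-format ``snp_a  snp_b  r2``); SNP pairs absent from the matrix are
treated as unlinked (r² = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import NoInstrumentsError
from .io import SummaryStatTable

logger = logging.getLogger(__name__)


@dataclass
class LDMatrix:
    """Symmetric matrix of squared allelic correlations keyed by snp_id."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.snp_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix shape does not match snp_ids")
        if not np.allclose(self.r2, self.r2.T):
            raise ValueError("r2 matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0):
            raise ValueError("r2 diagonal must be 1")
        if self.r2.min() < 0 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r2 entries must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self._warned_missing = False

    @classmethod
    def identity(cls, snp_ids) -> "LDMatrix":
        ids = list(snp_ids)
        return cls(ids, np.eye(len(ids)))

    @classmethod
    def read(cls, path) -> "LDMatrix":
        """Read either a square matrix TSV (header = snp ids) or a
        long-format TSV with columns snp_a, snp_b, r2."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if {"snp_a", "snp_b", "r2"}.issubset(df.columns):
            ids = sorted(set(df["snp_a"]).union(df["snp_b"]))
            idx = {s: i for i, s in enumerate(ids)}
            r2 = np.eye(len(ids))
            for a, b, v in zip(df["snp_a"], df["snp_b"], df["r2"]):
                r2[idx[a], idx[b]] = v
                r2[idx[b], idx[a]] = v
            return cls(ids, r2)
        ids = list(df.columns)
        return cls(ids, df.to_numpy(float))

    def r2_between(self, a: str, b: str) -> float:
        """r² between two SNPs; pairs not covered are treated as unlinked."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            if not self._warned_missing:
                logger.info("LD matrix does not cover some SNPs; "
                            "uncovered pairs treated as r2=0")
                self._warned_missing = True
            return 1.0 if a == b else 0.0
        return float(self.r2[ia, ib])


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure.

    ``df`` carries the surviving summary-stat records plus per-SNP
    ``f_stat``, ``r2_explained`` and ``f_method`` (which strength formula
    was used); ``attrition`` maps stage name -> SNPs removed at that stage.
    """

    exposure_id: str
    df: pd.DataFrame
    attrition: dict = field(default_factory=dict)

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()


@dataclass
class SelectionParams:
    """Thresholds of the instrument-selection cascade."""

    p_threshold: float = 1e-5
    r2_max: float = 0.001
    window_kb: float = 10_000.0
    outcome_p: float = 5e-8
    f_min: float = 10.0
    maf_min: float = 0.01
    #: run the outcome-association exclusion before (rather than after) clumping
    exclude_before_clump: bool = False


def filter_pvalue(table: SummaryStatTable, threshold: float) -> SummaryStatTable:
    """Keep SNPs with exposure p-value strictly below ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    keep = table.df["pvalue"] < threshold
    return SummaryStatTable(table.trait_id, table.df.loc[keep].reset_index(drop=True),
                            table.trait_class)


def clump(table: SummaryStatTable, ld: LDMatrix,
          r2_max: float = 0.001, window_kb: float = 10_000.0) -> SummaryStatTable:
    """Greedy LD clumping: repeatedly accept the smallest-p remaining SNP
    and discard remaining SNPs on the same chromosome within ``window_kb``
    that have r² >= ``r2_max`` with it.  Ties at equal p break
    lexicographically by snp_id.  Output is in genomic order.
    """
    df = table.df
    if df.empty:
        return SummaryStatTable(table.trait_id, df.copy(), table.trait_class)
    order = df.sort_values(["pvalue", "snp_id"], kind="mergesort")
    window_bp = window_kb * 1000.0
    alive = dict.fromkeys(order.index, True)
    accepted = []
    for idx in order.index:
        if not alive[idx]:
            continue
        accepted.append(idx)
        alive[idx] = False
        lead = df.loc[idx]
        for jdx in order.index:
            if not alive[jdx]:
                continue
            cand = df.loc[jdx]
            if (cand["chrom"] == lead["chrom"]
                    and abs(cand["pos"] - lead["pos"]) <= window_bp
                    and ld.r2_between(lead["snp_id"], cand["snp_id"]) >= r2_max):
                alive[jdx] = False
    kept = df.loc[accepted].sort_values(["chrom", "pos"], kind="mergesort")
    return SummaryStatTable(table.trait_id, kept.reset_index(drop=True),
                            table.trait_class)


def exclude_outcome_associated(table: SummaryStatTable,
                               outcome: SummaryStatTable,
                               threshold: float = 5e-8) -> SummaryStatTable:
    """Drop SNPs whose *outcome* p-value is below ``threshold`` (exclusion
    criterion of the MR assumptions).  SNPs absent from the outcome table
    are retained — they simply fall out later at harmonization."""
    out_p = outcome.df.set_index("snp_id")["pvalue"]
    p = table.df["snp_id"].map(out_p)
    keep = p.isna() | (p >= threshold)
    return SummaryStatTable(table.trait_id, table.df.loc[keep].reset_index(drop=True),
                            table.trait_class)


def instrument_strength(beta: float, se: float, eaf: float | None,
                        n: float | None) -> tuple[float, float, str]:
    """Per-SNP variance explained and F-statistic.

    With an effect-allele frequency and sample size available, uses the
    standardized-trait approximation R² = 2·maf·(1−maf)·beta² and
    F = R²·(n−2)/(1−R²).  Otherwise falls back to the Wald-chi-square
    approximation F = (beta/se)² (with R² reported as nan).

    Returns ``(r2_explained, f_stat, method)`` where method is
    ``"r2"`` or ``"wald"``.
    """
    have_eaf = eaf is not None and not np.isnan(eaf)
    have_n = n is not None and not np.isnan(n)
    if have_eaf and have_n:
        if n <= 2:
            raise ValueError("sample size must exceed 2")
        maf = min(eaf, 1 - eaf)
        r2 = 2.0 * maf * (1.0 - maf) * beta * beta
        f = r2 * (n - 2) / (1.0 - r2) if r2 < 1 else np.inf
        return r2, f, "r2"
    return np.nan, (beta / se) ** 2, "wald"


def _strength_frame(df: pd.DataFrame) -> pd.DataFrame:
    vals = [instrument_strength(b, s, e, n) for b, s, e, n in
            zip(df["beta"], df["se"], df["eaf"], df["n"])]
    out = df.copy()
    out["r2_explained"] = [v[0] for v in vals]
    out["f_stat"] = [v[1] for v in vals]
    out["f_method"] = [v[2] for v in vals]
    return out


def select_instruments(table: SummaryStatTable, outcome: SummaryStatTable,
                       ld: LDMatrix,
                       params: SelectionParams | None = None) -> InstrumentSet:
    """Full selection cascade; emits per-stage attrition counts.

    Stage order: p-value filter -> LD clumping -> outcome-association
    exclusion -> strength filter (F > f_min and MAF > maf_min; SNPs with
    missing eaf skip the MAF gate).  ``params.exclude_before_clump`` swaps
    stages 2 and 3.

    Raises
    ------
    NoInstrumentsError
        Naming the stage whose filter emptied the candidate set.
    """
    params = params or SelectionParams()
    attrition: dict[str, int] = {"input": table.n_snp}

    def check(tab: SummaryStatTable, stage: str):
        if tab.n_snp == 0:
            raise NoInstrumentsError(
                f"no instruments left for {table.trait_id!r} after stage "
                f"{stage!r}", stage=stage)

    t1 = filter_pvalue(table, params.p_threshold)
    attrition["pvalue_filter"] = table.n_snp - t1.n_snp
    check(t1, "pvalue_filter")

    stages = [("clump", lambda t: clump(t, ld, params.r2_max, params.window_kb)),
              ("outcome_exclusion",
               lambda t: exclude_outcome_associated(t, outcome, params.outcome_p))]
    if params.exclude_before_clump:
        stages.reverse()
    t2 = t1
    for name, fn in stages:
        t3 = fn(t2)
        attrition[name] = t2.n_snp - t3.n_snp
        check(t3, name)
        t2 = t3

    df = _strength_frame(t2.df)
    maf = np.minimum(df["eaf"], 1 - df["eaf"])
    maf_ok = df["eaf"].isna() | (maf > params.maf_min)
    keep = (df["f_stat"] > params.f_min) & maf_ok
    attrition["strength_filter"] = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    iset = InstrumentSet(table.trait_id, df, attrition)
    if iset.n_snp == 0:
        raise NoInstrumentsError(
            f"no instruments left for {table.trait_id!r} after stage "
            "'strength_filter'", stage="strength_filter")
    attrition["output"] = iset.n_snp
    return iset


def find_proxy(snp_id: str, ld: LDMatrix, candidates: SummaryStatTable,
               r2_min: float = 0.8):
    """Best proxy SNP with r² strictly above ``r2_min``.

    Ties break by higher r², then lower p-value, then snp_id.  Returns the
    candidate row as a Series, or None when no candidate qualifies.
    """
    best = None
    best_key = None
    for rec in candidates.df.itertuples(index=False):
        if rec.snp_id == snp_id:
            continue
        r2 = ld.r2_between(snp_id, rec.snp_id)
        if r2 <= r2_min:
            continue
        key = (-r2, rec.pvalue, rec.snp_id)
        if best_key is None or key < best_key:
            best_key = key
            best = rec
    if best is None:
        return None
    return pd.Series(best._asdict())
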