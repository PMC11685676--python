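"""Reading, validating and harmonizing GWAS summary statistics.

A GWAS is held as a :class:`SummaryStatTable`: a pandas DataFrame of per-SNP
association records (snp_id, chrom, pos, alleles, eaf, beta, se, pvalue, n)
plus a trait identifier.  Exposure/outcome pairs are aligned to a common
effect allele by :func:`harmonize`, producing the (beta_x, se_x, beta_y,
se_y) quadruples every MR estimator consumes.

Column names in input files are configurable; the defaults follow
GWAS-SSF-style naming (chromosome, base_pair_location, effect_allele, ...).
Positions are 1-based and are used only for clumping windows — SNP matching
is always by snp_id.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    HarmonizationError,
    MissingColumnError,
)

logger = logging.getLogger(__name__)

#: canonical column order of a SummaryStatTable DataFrame
COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n",
]

#: default mapping canonical-field -> file header (GWAS-SSF-like dialect)
DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pvalue": "p_value",
    "n": "n",
}

_REQUIRED = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pvalue"]
_OPTIONAL = ["eaf", "n"]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SummaryStatTable:
    """One GWAS's per-SNP association records.

    Parameters
    ----------
    trait_id
        Identifier of the measured trait (e.g. a GWAS accession).
    df
        DataFrame with the columns in :data:`COLUMNS`; ``snp_id`` unique.
    trait_class
        One of ``{"metabolite", "immune", "outcome", "other"}``.
    n_dropped
        Rows removed during validation when read from a file.
    """

    trait_id: str
    df: pd.DataFrame
    trait_class: str = "other"
    n_dropped: int = 0

    def __post_init__(self):
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"]
            raise ValueError(
                f"duplicate snp_id in table {self.trait_id!r}: {list(dups[:5])}"
            )

    @property
    def n_snp(self) -> int:
        return len(self.df)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to a shared effect allele.

    ``df`` columns: snp_id, beta_x, se_x, beta_y, se_y, eaf_x, eaf_y, n_x.
    Array accessors return the per-SNP exposure effects gamma_j (``beta_x``),
    their SEs sigma_Xj, the outcome effects Gamma_j (``beta_y``) and sigma_Yj.
    """

    exposure_id: str
    outcome_id: str
    df: pd.DataFrame

    @property
    def n_snp(self) -> int:
        return len(self.df)

    @property
    def beta_x(self) -> np.ndarray:
        return self.df["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.df["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.df["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.df["se_y"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.df["snp_id"].tolist()

    def subset(self, keep) -> "HarmonizedSet":
        """Return a new set restricted to ``keep`` (boolean mask or snp_id list)."""
        if isinstance(keep, (list, set, frozenset, tuple, pd.Index)):
            mask = self.df["snp_id"].isin(list(keep)).to_numpy()
        else:
            mask = np.asarray(keep, dtype=bool)
        return HarmonizedSet(self.exposure_id, self.outcome_id,
                             self.df.loc[mask].reset_index(drop=True))


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_summary_stats(path, column_map: dict | None = None,
                       trait_id: str | None = None,
                       trait_class: str = "other") -> SummaryStatTable:
    """Read a delimited summary-statistics file into a validated table.

    Rows violating the record invariants (se <= 0, p outside (0, 1],
    eaf outside [0, 1], non-ACGT or identical alleles, missing required
    values) are dropped and counted in ``table.n_dropped``.  Alleles are
    upper-cased.

    Raises
    ------
    MissingColumnError
        A required column of ``column_map`` is absent from the header.
    EmptyInputError
        The file has no data rows.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=_detect_sep(path))
    if raw.empty:
        raise EmptyInputError(f"no data rows in {path}")
    for fld in _REQUIRED:
        if cmap[fld] not in raw.columns:
            raise MissingColumnError(
                f"required column {cmap[fld]!r} (field {fld!r}) missing from {path}"
            )
    df = pd.DataFrame({fld: raw[cmap[fld]] for fld in _REQUIRED})
    for fld in _OPTIONAL:
        col = cmap.get(fld)
        df[fld] = raw[col] if col in raw.columns else np.nan

    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for col in ("pos", "eaf", "beta", "se", "pvalue", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")

    ok = (
        df["snp_id"].notna()
        & df["pos"].notna()
        & df["beta"].notna()
        & df["se"].notna() & (df["se"] > 0)
        & df["pvalue"].notna() & (df["pvalue"] > 0) & (df["pvalue"] <= 1)
        & df["effect_allele"].isin(_VALID_ALLELES)
        & df["other_allele"].isin(_VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | ((df["eaf"] >= 0) & (df["eaf"] <= 1)))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read %s: dropped %d invalid rows", path, n_dropped)
    df = df.loc[ok, COLUMNS].reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return SummaryStatTable(
        trait_id=trait_id or path.stem, df=df,
        trait_class=trait_class, n_dropped=n_dropped,
    )


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G allele pairs (strand-ambiguous SNPs)."""
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: SummaryStatTable, outcome: SummaryStatTable,
              drop_palindromic: bool = True,
              infer_palindromic: bool = False,
              palindromic_maf_max: float = 0.42) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    SNPs are intersected on ``snp_id`` (exposure order preserved).  For each
    shared SNP the outcome alleles are compared with the exposure alleles:

    * identical -> kept as-is;
    * swapped -> outcome beta negated, outcome eaf complemented;
    * identical/swapped after complementary-strand relabeling (A<->T, C<->G)
      -> relabeled (and sign-flipped if swapped), counted in the log;
    * otherwise -> dropped as allele-incompatible.

    Palindromic (A/T, C/G) SNPs cannot be strand-resolved from alleles alone
    and are removed when ``drop_palindromic`` is true (the default policy).
    ``infer_palindromic`` optionally retains them when both effect-allele
    frequencies are informative (MAF < ``palindromic_maf_max`` on both
    sides), aligning by frequency.

    Raises
    ------
    HarmonizationError
        If no SNP survives — callers must not silently run estimators on
        an empty set.
    """
    if exposure.n_snp == 0 or outcome.n_snp == 0:
        raise EmptyInputError("harmonize requires two non-empty tables")

    out = outcome.df.set_index("snp_id")
    rows = []
    n_relabel = 0
    for rec in exposure.df.itertuples(index=False):
        if rec.snp_id not in out.index:
            continue
        o = out.loc[rec.snp_id]
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        beta_y, eaf_y = float(o["beta"]), float(o["eaf"])

        if is_palindromic(ea_x, oa_x) or is_palindromic(ea_y, oa_y):
            if drop_palindromic:
                if not infer_palindromic:
                    continue
                # frequency inference: needs informative, concordant MAF
                if np.isnan(rec.eaf) or np.isnan(eaf_y):
                    continue
                maf_x = min(rec.eaf, 1 - rec.eaf)
                maf_y = min(eaf_y, 1 - eaf_y)
                if maf_x >= palindromic_maf_max or maf_y >= palindromic_maf_max:
                    continue
                same_side = (rec.eaf < 0.5) == (eaf_y < 0.5)
                if not same_side:
                    beta_y = -beta_y
                    eaf_y = 1.0 - eaf_y
                rows.append((rec.snp_id, rec.beta, rec.se, beta_y,
                             float(o["se"]), rec.eaf, eaf_y, rec.n))
                continue
            # fall through: keep palindromic SNPs, treating alleles literally
        if (ea_y, oa_y) == (ea_x, oa_x):
            flip = False
        elif (ea_y, oa_y) == (oa_x, ea_x):
            flip = True
        else:
            cea, coa = _COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y)
            if (cea, coa) == (ea_x, oa_x):
                flip = False
                n_relabel += 1
            elif (cea, coa) == (oa_x, ea_x):
                flip = True
                n_relabel += 1
            else:
                continue  # allele-incompatible
        if flip:
            beta_y = -beta_y
            eaf_y = 1.0 - eaf_y
        rows.append((rec.snp_id, rec.beta, rec.se, beta_y,
                     float(o["se"]), rec.eaf, eaf_y, rec.n))

    if n_relabel:
        logger.info("harmonize %s~%s: %d SNPs strand-relabeled",
                    exposure.trait_id, outcome.trait_id, n_relabel)
    if not rows:
        raise HarmonizationError(
            f"no SNPs shared by {exposure.trait_id!r} and {outcome.trait_id!r} "
            "survive harmonization"
        )
    df = pd.DataFrame(rows, columns=["snp_id", "beta_x", "se_x", "beta_y",
                                     "se_y", "eaf_x", "eaf_y", "n_x"])
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, df)


# ---------------------------------------------------------------------------
# result output

_FLOAT_FMT = "%.17g"  # full round-trip precision


def write_summary_stats(table: SummaryStatTable, path) -> Path:
    """Write a table in the default GWAS-SSF-style dialect that
    :func:`read_summary_stats` reads back unchanged."""
    path = Path(path)
    out = table.df.rename(columns=DEFAULT_COLUMN_MAP)
    out.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def _to_frame(items) -> pd.DataFrame:
    if isinstance(items, pd.DataFrame):
        return items
    rows = []
    for it in items:
        if dataclasses.is_dataclass(it):
            d = dataclasses.asdict(it)
            extras = d.pop("extras", None)
            if isinstance(extras, dict):
                d.update(extras)
            rows.append(d)
        else:
            rows.append(dict(it))
    return pd.DataFrame(rows)


def write_results(tables: dict, out_dir) -> dict[str, Path]:
    """Write each result collection as ``<name>.tsv`` under ``out_dir``.

    ``tables`` maps a result-type name (e.g. ``"estimates"``,
    ``"sensitivity"``, ``"mediation"``) to a DataFrame or a sequence of
    dataclasses/dicts.  Column order is the natural field order and stable;
    floats are written at full round-trip precision.  Empty collections
    yield a header-only file when a DataFrame (with columns) is given.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, items in tables.items():
        df = _to_frame(items)
        path = out_dir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[name] = path
    return written


def write_manifest(out_dir, params: dict, seed, inputs: dict | None = None,
                   version: str = "0.1.0") -> Path:
    """Write the JSON run-manifest recording inputs, parameters and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "mrmediate",
        "version": version,
        "python": platform.python_version(),
        "seed": seed,
        "params": params,
        "inputs": inputs or {},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
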