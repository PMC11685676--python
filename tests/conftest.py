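import numpy as np
import pandas as pd
import pytest

from mrmediate.io import COLUMNS, HarmonizedSet, SummaryStatTable


def make_table(snp_ids, betas, ses, pvalues=None, *, chrom="1", pos=None,
               ea="A", oa="G", eaf=0.3, n=100_000.0, trait_id="trait"):
    """Build a SummaryStatTable from parallel per-SNP value lists."""
    m = len(snp_ids)

    def col(v):
        return list(v) if isinstance(v, (list, tuple, np.ndarray)) else [v] * m

    if pvalues is None:
        from scipy import stats
        pvalues = [2 * stats.norm.sf(abs(b / s)) for b, s in zip(col(betas), col(ses))]
    df = pd.DataFrame({
        "snp_id": list(snp_ids), "chrom": col(chrom),
        "pos": col(pos) if pos is not None else [1_000_000 * (j + 1) for j in range(m)],
        "effect_allele": col(ea), "other_allele": col(oa),
        "eaf": col(eaf), "beta": col(betas), "se": col(ses),
        "pvalue": col(pvalues), "n": col(n),
    })[COLUMNS]
    return SummaryStatTable(trait_id, df)


def make_h(beta_x, se_x, beta_y, se_y, snp_ids=None,
           exposure_id="exp", outcome_id="out"):
    """Build a HarmonizedSet directly from effect/SE arrays."""
    m = len(beta_x)
    df = pd.DataFrame({
        "snp_id": snp_ids or [f"rs{j + 1}" for j in range(m)],
        "beta_x": beta_x, "se_x": se_x, "beta_y": beta_y, "se_y": se_y,
        "eaf_x": 0.3, "eaf_y": 0.3, "n_x": 100_000.0,
    })
    return HarmonizedSet(exposure_id, outcome_id, df)


@pytest.fixture
def three_snp_h():
    """The shared 3-SNP fixture used by the IVW/Egger closed-form checks."""
    return make_h([0.1, 0.2, 0.15], [0.01, 0.01, 0.02],
                  [0.06, 0.08, 0.09], [0.01, 0.01, 0.02])
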