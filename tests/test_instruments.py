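"""Instrument-selection cascade: p filter, clumping, exclusion, strength."""

import numpy as np
import pandas as pd
import pytest

from mrmediate.errors import NoInstrumentsError
from mrmediate.instruments import (
    LDMatrix,
    SelectionParams,
    clump,
    exclude_outcome_associated,
    filter_pvalue,
    find_proxy,
    instrument_strength,
    select_instruments,
)

from conftest import make_table


def ld_from_pairs(snp_ids, pairs):
    """LD matrix with the given r2 on listed (a, b) pairs, 0 elsewhere."""
    idx = {s: i for i, s in enumerate(snp_ids)}
    r2 = np.eye(len(snp_ids))
    for a, b, v in pairs:
        r2[idx[a], idx[b]] = r2[idx[b], idx[a]] = v
    return LDMatrix(list(snp_ids), r2)


class TestFilterPvalue:
    def test_strict_threshold(self):
        tab = make_table(["rs1", "rs2", "rs3"], [0.1] * 3, [0.01] * 3,
                         pvalues=[1e-9, 1e-6, 1e-4])
        assert filter_pvalue(tab, 1e-5).df["snp_id"].tolist() == ["rs1", "rs2"]
        assert filter_pvalue(tab, 5e-8).df["snp_id"].tolist() == ["rs1"]

    def test_boundary_excluded(self):
        tab = make_table(["rs1"], [0.1], [0.01], pvalues=[1e-5])
        assert filter_pvalue(tab, 1e-5).n_snp == 0


class TestClump:
    def test_greedy_rule_on_forced_instance(self):
        # s1 best p; s2 linked+near -> dropped; s3 unlinked -> kept
        tab = make_table(["s1", "s2", "s3"], [0.1] * 3, [0.01] * 3,
                         pvalues=[1e-10, 1e-9, 1e-8],
                         pos=[1_000_000, 1_050_000, 1_100_000])
        ld = ld_from_pairs(["s1", "s2", "s3"],
                           [("s1", "s2", 0.5), ("s1", "s3", 0.0005),
                            ("s2", "s3", 0.0005)])
        out = clump(tab, ld)
        assert out.df["snp_id"].tolist() == ["s1", "s3"]

    def test_outside_window_retained(self):
        tab = make_table(["s1", "s2"], [0.1] * 2, [0.01] * 2,
                         pvalues=[1e-10, 1e-9],
                         pos=[1_000_000, 1_000_000 + 20_000_000 * 1000])
        ld = ld_from_pairs(["s1", "s2"], [("s1", "s2", 0.5)])
        assert clump(tab, ld).n_snp == 2

    def test_different_chromosomes_never_pruned(self):
        tab = make_table(["s1", "s2"], [0.1] * 2, [0.01] * 2,
                         pvalues=[1e-10, 1e-9], chrom=["1", "2"],
                         pos=[1_000_000, 1_000_000])
        ld = ld_from_pairs(["s1", "s2"], [("s1", "s2", 0.9)])
        assert clump(tab, ld).n_snp == 2

    @pytest.mark.parametrize("instance_seed", range(5))
    def test_matches_brute_force_oracle(self, instance_seed):
        """Random 6-SNP instances agree with an independent re-trace of the
        sort-and-sweep rule."""
        rng = np.random.default_rng(instance_seed)
        ids = [f"s{j}" for j in range(6)]
        pos = sorted(rng.integers(1, 20_000_000, size=6).tolist())
        pvals = rng.uniform(1e-12, 1e-4, size=6).tolist()
        r2 = rng.uniform(0, 1, size=(6, 6))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        tab = make_table(ids, [0.1] * 6, [0.01] * 6, pvalues=pvals, pos=pos)
        r2_max, window_kb = 0.3, 5_000.0

        # oracle: explicit greedy hand-trace, set-based
        remaining = sorted(range(6), key=lambda j: (pvals[j], ids[j]))
        kept = []
        removed = set()
        for j in remaining:
            if j in removed:
                continue
            kept.append(j)
            for k in remaining:
                if k not in removed and k != j:
                    if (abs(pos[k] - pos[j]) <= window_kb * 1000
                            and r2[j, k] >= r2_max):
                        removed.add(k)
        expected = [ids[j] for j in sorted(kept, key=lambda j: pos[j])]

        out = clump(tab, ld, r2_max=r2_max, window_kb=window_kb)
        assert out.df["snp_id"].tolist() == expected

    def test_no_retained_pair_both_near_and_linked(self):
        rng = np.random.default_rng(42)
        ids = [f"s{j}" for j in range(10)]
        pos = sorted(rng.integers(1, 30_000_000, size=10).tolist())
        r2 = rng.uniform(0, 1, size=(10, 10))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(ids, r2)
        tab = make_table(ids, [0.1] * 10, [0.01] * 10,
                         pvalues=rng.uniform(1e-10, 1e-5, 10).tolist(), pos=pos)
        out = clump(tab, ld, r2_max=0.2, window_kb=8_000)
        kept = out.df.set_index("snp_id")
        for a in kept.index:
            for b in kept.index:
                if a < b:
                    near = abs(kept.loc[a, "pos"] - kept.loc[b, "pos"]) <= 8_000_000
                    linked = ld.r2_between(a, b) >= 0.2
                    assert not (near and linked)

    def test_identity_ld_keeps_everything(self):
        tab = make_table([f"s{j}" for j in range(5)], [0.1] * 5, [0.01] * 5,
                         pvalues=np.linspace(1e-9, 1e-6, 5).tolist())
        out = clump(tab, LDMatrix.identity(tab.df["snp_id"]))
        assert out.n_snp == 5

    def test_zero_window_and_unit_r2max_keep_input(self):
        rng = np.random.default_rng(3)
        ids = [f"s{j}" for j in range(6)]
        r2 = rng.uniform(0, 0.99, size=(6, 6))
        r2 = (r2 + r2.T) / 2
        np.fill_diagonal(r2, 1.0)
        tab = make_table(ids, [0.1] * 6, [0.01] * 6,
                         pvalues=rng.uniform(1e-9, 1e-5, 6).tolist(),
                         pos=list(range(1_000_000, 7_000_000, 1_000_000)))
        ld = LDMatrix(ids, r2)
        assert clump(tab, ld, window_kb=0).n_snp == 6
        assert clump(tab, ld, r2_max=1.0).n_snp == 6


class TestExcludeOutcomeAssociated:
    def test_rules(self):
        exp = make_table(["rs1", "rs2", "rs3"], [0.1] * 3, [0.01] * 3)
        out = make_table(["rs1", "rs2"], [0.3, 0.05], [0.01, 0.01],
                         pvalues=[1e-9, 1e-7])
        kept = exclude_outcome_associated(exp, out)
        # 1e-9 removed; 1e-7 retained; missing rs3 retained
        assert kept.df["snp_id"].tolist() == ["rs2", "rs3"]


class TestInstrumentStrength:
    def test_wald_fallback_when_eaf_missing(self):
        r2, f, method = instrument_strength(0.1, 0.01, np.nan, 10_000)
        assert method == "wald"
        assert f == pytest.approx(100.0)

    def test_null_effect(self):
        r2, f, _ = instrument_strength(0.0, 0.01, 0.5, 10_000)
        assert r2 == 0.0 and f == 0.0

    def test_r2_formula_hand_evaluated(self):
        # R2 = 2*0.2*0.8*0.05^2 = 8e-4; F = R2*(n-2)/(1-R2)
        r2, f, method = instrument_strength(0.05, 0.01, 0.2, 10_000)
        assert method == "r2"
        assert r2 == pytest.approx(8.0e-4, rel=1e-12)
        assert f == pytest.approx(8.0e-4 * 9998 / (1 - 8.0e-4), rel=1e-12)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            instrument_strength(0.1, 0.01, 0.2, 2)


class TestSelectInstruments:
    def _fixture(self):
        """8 SNPs built so each stage removes exactly one known SNP set:
        8 -> 7 (p filter) -> 6 (clump) -> 5 (outcome) -> 4 (strength)."""
        ids = [f"s{j}" for j in range(1, 9)]
        pvals = [1e-10, 1e-9, 1e-8, 1e-8, 1e-7, 1e-6, 1e-6, 1e-3]  # s8 fails p
        betas = [0.10, 0.10, 0.10, 0.10, 0.10, 0.10, 0.004, 0.10]  # s7 weak F
        eafs = [0.3] * 8
        pos = [1_000_000 * j for j in range(1, 9)]
        tab = make_table(ids, betas, [0.01] * 8, pvalues=pvals, pos=pos,
                         eaf=eafs, n=100_000.0)
        # s2 clumps away with s1 (r2=0.9, 1 Mb apart)
        ld = ld_from_pairs(ids, [("s1", "s2", 0.9)])
        # s3 strongly associated with outcome
        out = make_table(ids, [0.1] * 8, [0.01] * 8,
                         pvalues=[0.5, 0.5, 1e-9, 0.5, 0.5, 0.5, 0.5, 0.5])
        return tab, out, ld

    def test_staged_attrition(self):
        tab, out, ld = self._fixture()
        iset = select_instruments(tab, out, ld, SelectionParams())
        assert iset.n_snp == 4
        assert set(iset.snp_ids) == {"s1", "s4", "s5", "s6"}
        att = iset.attrition
        assert att["pvalue_filter"] == 1
        assert att["clump"] == 1
        assert att["outcome_exclusion"] == 1
        assert att["strength_filter"] == 1
        removed = sum(v for k, v in att.items()
                      if k not in ("input", "output"))
        assert att["input"] - removed == att["output"] == iset.n_snp

    def test_all_filtered_names_first_stage(self):
        tab = make_table(["s1", "s2"], [0.1] * 2, [0.01] * 2,
                         pvalues=[1e-3, 1e-2])
        out = make_table(["s1", "s2"], [0.0] * 2, [0.01] * 2, pvalues=[1.0, 1.0])
        with pytest.raises(NoInstrumentsError) as exc:
            select_instruments(tab, out, LDMatrix.identity(["s1", "s2"]))
        assert exc.value.stage == "pvalue_filter"

    def test_vacuous_strength_filter(self):
        tab, out, ld = self._fixture()
        params = SelectionParams(f_min=0.0, maf_min=0.0)
        iset = select_instruments(tab, out, ld, params)
        assert iset.attrition["strength_filter"] == 0
        assert iset.n_snp == 5

    def test_every_retained_snp_strong(self):
        tab, out, ld = self._fixture()
        iset = select_instruments(tab, out, ld)
        assert (iset.df["f_stat"] > 10).all()
        maf = np.minimum(iset.df["eaf"], 1 - iset.df["eaf"])
        assert (maf > 0.01).all()


class TestFindProxy:
    def _setup(self):
        cands = make_table(["p1", "p2", "p3"], [0.1] * 3, [0.01] * 3,
                           pvalues=[1e-8, 1e-6, 1e-7])
        return cands

    def test_highest_r2_wins(self):
        cands = self._setup()
        ld = ld_from_pairs(["x", "p1", "p2", "p3"],
                           [("x", "p1", 0.85), ("x", "p2", 0.9)])
        assert find_proxy("x", ld, cands)["snp_id"] == "p2"

    def test_strict_threshold_returns_none(self):
        cands = self._setup()
        ld = ld_from_pairs(["x", "p1", "p2", "p3"], [("x", "p1", 0.79)])
        assert find_proxy("x", ld, cands) is None

    def test_r2_tie_broken_by_lower_p(self):
        cands = self._setup()
        ld = ld_from_pairs(["x", "p1", "p2", "p3"],
                           [("x", "p1", 0.9), ("x", "p2", 0.9)])
        assert find_proxy("x", ld, cands)["snp_id"] == "p1"


class TestLDMatrix:
    def test_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.9]]))

    def test_uncovered_pairs_unlinked(self):
        ld = LDMatrix.identity(["a", "b"])
        assert ld.r2_between("a", "zzz") == 0.0
        assert ld.r2_between("zzz", "zzz") == 1.0

    def test_round_trip_square_and_long(self, tmp_path):
        ld = ld_from_pairs(["a", "b", "c"], [("a", "b", 0.4)])
        sq = tmp_path / "sq.tsv"
        pd.DataFrame(ld.r2, columns=ld.snp_ids).to_csv(sq, sep="\t", index=False)
        ld2 = LDMatrix.read(sq)
        np.testing.assert_allclose(ld2.r2, ld.r2)
        long = tmp_path / "long.tsv"
        pd.DataFrame({"snp_a": ["a"], "snp_b": ["b"], "r2": [0.4]}).to_csv(
            long, sep="\t", index=False)
        ld3 = LDMatrix.read(long)
        assert ld3.r2_between("a", "b") == pytest.approx(0.4)
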