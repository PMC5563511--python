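import numpy as np
import pandas as pd
import pytest

from asdetect.junction_si import (
    FLAG_LOW_READS,
    FLAG_UNEVALUABLE,
    SiParams,
    gene_rpkm,
    junction_rpkm,
    si_pipeline,
    splicing_index,
    top2_junction_table,
)
from asdetect.synthetic_data import toy_junction_study

pytestmark = pytest.mark.filterwarnings("ignore::RuntimeWarning")


class TestRpkm:
    def test_worked_example(self):
        # 100 reads, 10M mapped, 80-nt junction segment: 100 / (10 * 0.08)
        assert junction_rpkm(100, 1e7, 80) == pytest.approx(125.0)

    def test_zero_count(self):
        assert junction_rpkm(0, 1e7, 80) == 0.0

    def test_linearity(self):
        assert junction_rpkm(200, 1e7, 80) == pytest.approx(2 * junction_rpkm(100, 1e7, 80))

    def test_zero_mapped_reads_is_an_error(self):
        with pytest.raises(ValueError, match="mapped_reads"):
            junction_rpkm(10, 0, 80)

    def test_gene_rpkm_sum(self):
        assert gene_rpkm([2.0, 2.0, 4.0]) == 8.0
        assert gene_rpkm([]) == 0.0
        assert gene_rpkm([4.0, 2.0, 2.0]) == gene_rpkm([2.0, 2.0, 4.0])


class TestSplicingIndex:
    def test_ln_ratio(self):
        assert splicing_index(0.5, 0.25) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_no_change(self):
        assert splicing_index(0.37, 0.37) == 0.0

    def test_antisymmetry(self):
        assert splicing_index(0.25, 0.5) == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_zero_ni_is_unevaluable(self):
        assert np.isnan(splicing_index(0.0, 0.5))
        assert np.isnan(splicing_index(0.5, 0.0))


class TestSiPipeline:
    @pytest.fixture()
    def toy(self):
        return toy_junction_study()

    def test_toy_table_yields_exactly_three_survivors(self, toy):
        """The hand-evaluated filter cascade keeps jA1, jA2 (reciprocal shift
        in gene A) and jB1; jB3 fails the SI cutoff, jB2 the read floor,
        gene C the expression filter and jD1 is untestable."""
        counts, gene_of, groups = toy
        table = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        assert sorted(table.index[table["survivor"]]) == ["jA1", "jA2", "jB1"]
        assert table.loc["jB2", "flags"] & FLAG_LOW_READS
        assert table.loc["jD1", "flags"] & FLAG_UNEVALUABLE

    def test_ni_sums_to_one_per_gene_and_sample(self, toy):
        counts, gene_of, groups = toy
        table = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        ni_cols = [c for c in table.columns if c.startswith("NI_")]
        sums = table.groupby("gene_id")[ni_cols].sum()
        assert np.allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_si_antisymmetric_under_group_swap(self, toy):
        counts, gene_of, groups = toy
        fwd = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        rev = si_pipeline(counts, gene_of, groups, ("wt", "mut"))
        si_f = fwd["SI"].sort_index()
        si_r = rev["SI"].sort_index()
        both = si_f.notna() & si_r.notna()
        assert np.allclose(si_f[both], -si_r[both], atol=1e-12)

    def test_sample_scaling_leaves_ni_unchanged(self, toy):
        counts, gene_of, groups = toy
        scaled = counts.copy()
        scaled["mut1"] = scaled["mut1"] * 7
        a = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        b = si_pipeline(scaled, gene_of, groups, ("mut", "wt"))
        assert np.allclose(a["NI_mut1"].sort_index().to_numpy(float),
                           b["NI_mut1"].sort_index().to_numpy(float),
                           atol=1e-12, equal_nan=True)

    def test_survivors_monotone_in_si_cutoff(self, toy):
        counts, gene_of, groups = toy
        prev = None
        for cutoff in (0.25, 0.5, 1.0, 1.5, 3.0):
            tab = si_pipeline(counts, gene_of, groups, ("mut", "wt"),
                              SiParams(si_cutoff=cutoff))
            surv = set(tab.index[tab["survivor"]])
            if prev is not None:
                assert surv <= prev
            prev = surv

    def test_all_equal_counts_have_no_survivors(self):
        samples = [f"wt{i}" for i in range(4)] + [f"mut{i}" for i in range(4)]
        counts = pd.DataFrame(
            {"j1": [10] * 8, "j2": [10] * 8}, index=samples
        ).T
        gene_of = {"j1": "g", "j2": "g"}
        groups = {s: s[:-1] for s in samples}
        tab = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        assert not tab["survivor"].any()

    def test_read_floor_applies_regardless_of_ni(self):
        samples = [f"wt{i}" for i in range(4)] + [f"mut{i}" for i in range(4)]
        counts = pd.DataFrame(
            {"j1": [3] * 8, "j2": [30, 31, 29, 30, 3, 4, 3, 2]}, index=samples
        ).T
        gene_of = {"j1": "g", "j2": "g"}
        groups = {s: s[:-1] for s in samples}
        tab = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        assert tab.loc["j1", "flags"] & FLAG_LOW_READS
        assert not tab.loc["j1", "survivor"]

    def test_too_few_replicates_rejected(self, toy):
        counts, gene_of, groups = toy
        small = counts[["wt1", "mut1", "mut2"]]
        with pytest.raises(ValueError, match="two replicates"):
            si_pipeline(small, gene_of, {k: groups[k] for k in small.columns},
                        ("mut", "wt"))

    def test_sidak_adjustment_exceeds_raw_p(self, toy):
        counts, gene_of, groups = toy
        tab = si_pipeline(counts, gene_of, groups, ("mut", "wt"))
        tested = tab["adj_p"].notna()
        assert (tab.loc[tested, "adj_p"] >= tab.loc[tested, "t_p"] - 1e-15).all()


class TestTop2Table:
    def make_results(self, rows):
        df = pd.DataFrame(rows).set_index("junction_id")
        for col in ("mean_NI_mut", "mean_NI_wt"):
            df[col] = df.get(col, 0.5)
        df["SI"] = df.get("SI", 1.5)
        return df

    def test_three_survivors_keep_best_two(self):
        df = self.make_results([
            {"junction_id": "j1", "gene_id": "g", "survivor": True, "t_p": 0.001},
            {"junction_id": "j2", "gene_id": "g", "survivor": True, "t_p": 0.01},
            {"junction_id": "j3", "gene_id": "g", "survivor": True, "t_p": 0.04},
        ])
        out = top2_junction_table(df, ("mut", "wt"))
        assert list(out["J1_id"]) == ["j1"] and list(out["J2_id"]) == ["j2"]

    def test_single_survivor_gene_excluded(self):
        df = self.make_results([
            {"junction_id": "j1", "gene_id": "g", "survivor": True, "t_p": 0.001},
            {"junction_id": "j2", "gene_id": "g", "survivor": False, "t_p": 0.01},
        ])
        assert top2_junction_table(df, ("mut", "wt")).empty

    def test_p_tie_broken_by_lower_coordinate(self):
        df = self.make_results([
            {"junction_id": "g:junc:500-900", "gene_id": "g", "survivor": True, "t_p": 0.01},
            {"junction_id": "g:junc:100-200", "gene_id": "g", "survivor": True, "t_p": 0.01},
            {"junction_id": "g:junc:300-400", "gene_id": "g", "survivor": True, "t_p": 0.01},
        ])
        out = top2_junction_table(df, ("mut", "wt"))
        assert out.loc[0, "J1_id"] == "g:junc:100-200"
        assert out.loc[0, "J2_id"] == "g:junc:300-400"
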