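"""TPM normalisation, enzyme-family summation, top-95% filter, two-way ANOVA
and Tukey letter groups."""

import numpy as np
import pandas as pd
import pytest

from rumennet import (
    ExpressionTable,
    SampleDesign,
    anova_time,
    classify_tag,
    compute_tpm,
    run_enzymes,
    sum_by_enzyme_family,
    taxon_contributions,
    top95_filter,
    tukey_letters,
    tukey_pairwise,
)


def _design(n_animals=3, tps=(1.0, 2.0, 4.0, 6.0, 8.0)):
    rows = [
        {"sample_id": f"cow{a}_T{t:g}", "animal_id": f"cow{a}", "timepoint_h": t}
        for a in range(1, n_animals + 1)
        for t in tps
    ]
    return SampleDesign(table=pd.DataFrame(rows).set_index("sample_id"))


def _table(counts: pd.DataFrame, lengths, tags, families=None) -> ExpressionTable:
    meta = pd.DataFrame(
        {
            "family": families if families is not None else ["famA"] * len(counts),
            "genus": "g",
            "functional_cluster": "FC1",
            "enzyme_tag": tags,
            "length_bp": lengths,
        },
        index=counts.index,
    )
    return ExpressionTable(counts=counts, gene_meta=meta)


class TestTpm:
    def test_two_gene_hand_example(self):
        counts = pd.DataFrame({"s1": [10, 10]},
                              index=pd.Index(["g1", "g2"], name="gene_id"))
        table = _table(counts, [500, 1000], ["", ""])
        tpm = compute_tpm(table)
        np.testing.assert_allclose(tpm["s1"], [666666.666667, 333333.333333], rtol=1e-9)

    def test_equal_genes_symmetric(self):
        n = 8
        counts = pd.DataFrame({"s1": [7] * n},
                              index=pd.Index([f"g{i}" for i in range(n)], name="gene_id"))
        tpm = compute_tpm(_table(counts, [600] * n, [""] * n))
        np.testing.assert_allclose(tpm["s1"], 1e6 / n)

    def test_columns_sum_to_million(self, default_bundle):
        tpm = compute_tpm(default_bundle.table)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_invariant_to_uniform_count_scaling(self):
        counts = pd.DataFrame({"s1": [10, 30, 5]},
                              index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        t1 = compute_tpm(_table(counts, [500, 900, 1500], ["", "", ""]))
        t2 = compute_tpm(_table(counts * 7, [500, 900, 1500], ["", "", ""]))
        pd.testing.assert_frame_equal(t1, t2)

    def test_zero_sample_named(self):
        counts = pd.DataFrame({"dead": [0, 0], "ok": [5, 5]},
                              index=pd.Index(["g1", "g2"], name="gene_id"))
        with pytest.raises(ValueError, match="dead"):
            compute_tpm(_table(counts, [500, 500], ["", ""]))


class TestClassifyAndSum:
    def test_classify(self):
        assert classify_tag("GH5") == "GH"
        assert classify_tag("gh13") == "GH"
        assert classify_tag("M24") == "peptidase"
        assert classify_tag("M24b") == "peptidase"
        assert classify_tag("C11") == "peptidase"
        assert classify_tag("LuxS") == "LuxS"
        assert classify_tag("") is None
        assert classify_tag(None) is None

    def test_gh_sum_hand_example(self):
        counts = pd.DataFrame({"s1": [1, 1, 1]},
                              index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        tpm = pd.DataFrame({"s1": [100.0, 50.0, 77.0]}, index=counts.index)
        meta = _table(counts, [500] * 3, ["GH5", "GH5", ""]).gene_meta
        sums = sum_by_enzyme_family(tpm, meta)
        assert sums.loc[("GH", "GH5"), "s1"] == pytest.approx(150.0)
        assert ("GH", "") not in sums.index  # untagged genes contribute nowhere

    def test_luxs_summed_per_taxon(self):
        counts = pd.DataFrame({"s1": [1, 1, 1]},
                              index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        tpm = pd.DataFrame({"s1": [10.0, 20.0, 40.0]}, index=counts.index)
        meta = _table(counts, [500] * 3, ["LuxS", "LuxS", "LuxS"],
                      families=["famA", "famA", "famB"]).gene_meta
        sums = sum_by_enzyme_family(tpm, meta)
        assert sums.loc[("LuxS", "famA"), "s1"] == pytest.approx(30.0)
        assert sums.loc[("LuxS", "famB"), "s1"] == pytest.approx(40.0)

    def test_matches_groupby_oracle(self, default_bundle):
        table = default_bundle.table
        tpm = compute_tpm(table)
        sums = sum_by_enzyme_family(tpm, table.gene_meta)
        tagged = table.gene_meta["enzyme_tag"].map(classify_tag).notna()
        gh5 = (table.gene_meta["enzyme_tag"] == "GH5") & tagged
        if gh5.any():
            oracle = tpm[gh5.to_numpy()].sum(axis=0)
            np.testing.assert_allclose(sums.loc[("GH", "GH5")].to_numpy(),
                                       oracle.to_numpy())


class TestTop95:
    def _sums(self, totals, etype="GH"):
        idx = pd.MultiIndex.from_tuples(
            [(etype, f"{etype}{i}") for i in range(len(totals))],
            names=["enzyme_type", "unit"])
        return pd.DataFrame({"s1": totals}, index=idx)

    def test_hand_cumulative_walk(self):
        sums = self._sums([70.0, 20.0, 6.0, 4.0])
        kept = top95_filter(sums, fraction=0.95)
        assert len(kept) == 3
        assert (kept.index.get_level_values("unit") == ["GH0", "GH1", "GH2"]).all()

    def test_single_family_always_kept(self):
        assert len(top95_filter(self._sums([5.0]))) == 1

    def test_fraction_one_keeps_all(self):
        assert len(top95_filter(self._sums([70.0, 20.0, 6.0, 4.0]), fraction=1.0)) == 4

    def test_types_filtered_separately(self):
        gh = self._sums([70.0, 20.0, 6.0, 4.0], "GH")
        pep = self._sums([99.0, 1.0], "M")
        pep.index = pd.MultiIndex.from_tuples(
            [("peptidase", "M1"), ("peptidase", "M2")], names=["enzyme_type", "unit"])
        kept = top95_filter(pd.concat([gh, pep]), fraction=0.95)
        assert len(kept.loc["GH"]) == 3
        assert len(kept.loc["peptidase"]) == 1  # 99% alone reaches the cut


class TestAnova:
    def test_all_equal_null_identity(self):
        design = _design()
        sums = pd.DataFrame([np.full(15, 3.0)], columns=design.sample_ids,
                            index=pd.MultiIndex.from_tuples(
                                [("GH", "GH5")], names=["enzyme_type", "unit"]))
        res = anova_time(sums, design)
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_balanced_ss_decomposition(self):
        design = _design()
        rng = np.random.default_rng(2)
        y = rng.lognormal(3, 0.5, size=15)
        sub = design.table
        tps = sorted(sub["timepoint_h"].unique())
        animals = sorted(sub["animal_id"].unique())
        grand = y.mean()
        t_idx = np.array([tps.index(t) for t in sub["timepoint_h"]])
        a_idx = np.array([animals.index(a) for a in sub["animal_id"]])
        ss_time = 3 * sum((y[t_idx == k].mean() - grand) ** 2 for k in range(5))
        ss_animal = 5 * sum((y[a_idx == k].mean() - grand) ** 2 for k in range(3))
        ss_total = ((y - grand) ** 2).sum()
        ss_resid = ss_total - ss_time - ss_animal
        # the implementation's F must equal the one built from these pieces
        sums = pd.DataFrame([y], columns=design.sample_ids,
                            index=pd.MultiIndex.from_tuples(
                                [("GH", "GH5")], names=["enzyme_type", "unit"]))
        res = anova_time(sums, design)
        f_expected = (ss_time / 4) / (ss_resid / 8)
        assert res["F"].iloc[0] == pytest.approx(f_expected, rel=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        design = _design()
        rng = np.random.default_rng(4)
        sums = pd.DataFrame(rng.lognormal(3, 0.6, size=(3, 15)),
                            columns=design.sample_ids,
                            index=pd.MultiIndex.from_tuples(
                                [("GH", f"GH{i}") for i in range(3)],
                                names=["enzyme_type", "unit"]))
        res = anova_time(sums, design)
        for i in range(3):
            df = pd.DataFrame({
                "y": sums.iloc[i].to_numpy(),
                "animal": design.table["animal_id"].to_numpy(),
                "time": design.table["timepoint_h"].astype(str).to_numpy(),
            })
            tab = anova_lm(smf.ols("y ~ C(animal) + C(time)", df).fit(), typ=2)
            assert res["p"].iloc[i] == pytest.approx(tab.loc["C(time)", "PR(>F)"],
                                                     abs=1e-10)

    def test_planted_step_significant(self, default_bundle):
        res = run_enzymes(default_bundle.table, default_bundle.design)
        assert len(res.anova) > 0
        assert res.anova["significant"].any()

    def test_unbalanced_design_rejected(self):
        design = _design()
        sums = pd.DataFrame([np.arange(14.0)],
                            columns=design.sample_ids[:-1],
                            index=pd.MultiIndex.from_tuples(
                                [("GH", "GH5")], names=["enzyme_type", "unit"]))
        with pytest.raises(ValueError, match="balanced"):
            anova_time(sums, design)


class TestTukey:
    def test_equal_means_single_letter(self):
        design = _design()
        vals = design.table["animal_id"].map(
            {"cow1": 1.0, "cow2": 2.0, "cow3": 3.0})  # pure animal effect
        vals.index = design.table.index
        letters = tukey_letters(vals, design)
        assert set(letters.values()) == {"a"}

    def test_k2_equals_blocked_t_test(self):
        """With two timepoints the Tukey p equals the t-test built on the same
        MSE and residual df (q = sqrt(2) |t|), to 1e-6."""
        from scipy import stats

        design = _design(tps=(1.0, 8.0))
        rng = np.random.default_rng(6)
        vals = pd.Series(rng.lognormal(2, 0.5, size=6), index=design.table.index)
        p_tukey = list(tukey_pairwise(vals, design).values())[0]

        sub = design.table
        tps = sorted(sub["timepoint_h"].unique())
        animals = sorted(sub["animal_id"].unique())
        y = vals.to_numpy()
        grand = y.mean()
        t_idx = np.array([tps.index(t) for t in sub["timepoint_h"]])
        a_idx = np.array([animals.index(a) for a in sub["animal_id"]])
        t_means = np.array([y[t_idx == k].mean() for k in range(2)])
        ss_time = 3 * ((t_means - grand) ** 2).sum()
        ss_animal = 2 * sum((y[a_idx == k].mean() - grand) ** 2 for k in range(3))
        ss_resid = ((y - grand) ** 2).sum() - ss_time - ss_animal
        mse = ss_resid / 2  # (2-1)(3-1) residual df
        t_stat = abs(t_means[0] - t_means[1]) / np.sqrt(mse * (2 / 3))
        p_t = 2 * stats.t.sf(t_stat, 2)
        assert p_tukey == pytest.approx(p_t, abs=1e-6)

    def test_tukey_conservative_vs_unadjusted_t(self):
        from scipy import stats

        design = _design()
        rng = np.random.default_rng(9)
        vals = pd.Series(rng.lognormal(2, 0.5, size=15), index=design.table.index)
        pair_p = tukey_pairwise(vals, design)

        sub = design.table
        tps = sorted(sub["timepoint_h"].unique())
        animals = sorted(sub["animal_id"].unique())
        y = vals.to_numpy()
        t_idx = np.array([tps.index(t) for t in sub["timepoint_h"]])
        a_idx = np.array([animals.index(a) for a in sub["animal_id"]])
        grand = y.mean()
        t_means = np.array([y[t_idx == k].mean() for k in range(5)])
        ss_time = 3 * ((t_means - grand) ** 2).sum()
        ss_animal = 5 * sum((y[a_idx == k].mean() - grand) ** 2 for k in range(3))
        ss_resid = ((y - grand) ** 2).sum() - ss_time - ss_animal
        mse = ss_resid / 8
        for (ta, tb), p in pair_p.items():
            i, j = tps.index(ta), tps.index(tb)
            t_stat = abs(t_means[i] - t_means[j]) / np.sqrt(mse * (2 / 3))
            p_t = 2 * stats.t.sf(t_stat, 8)
            assert p >= p_t - 1e-12


class TestContributions:
    def _setup(self):
        design = _design(tps=(1.0, 2.0))
        genes = pd.Index(["g1", "g2", "g3"], name="gene_id")
        counts = pd.DataFrame(1, index=genes, columns=design.sample_ids)
        meta = pd.DataFrame(
            {"family": ["famA", "famB", "famC"], "genus": "g",
             "functional_cluster": "FC1", "enzyme_tag": ["GH5", "GH5", "M24"],
             "length_bp": 600},
            index=genes)
        return design, meta

    def test_single_taxon_share_one(self):
        design, meta = self._setup()
        tpm = pd.DataFrame(
            [[30.0] * 6, [0.0] * 6, [5.0] * 6],
            index=meta.index, columns=design.sample_ids)
        contrib = taxon_contributions(tpm, meta, design)
        m24 = contrib[contrib["enzyme_family"] == "M24"]
        np.testing.assert_allclose(m24["proportion"], 1.0)

    def test_hand_ratio(self):
        design, meta = self._setup()
        tpm = pd.DataFrame(
            [[30.0] * 6, [10.0] * 6, [1.0] * 6],
            index=meta.index, columns=design.sample_ids)
        contrib = taxon_contributions(tpm, meta, design)
        gh5 = contrib[contrib["enzyme_family"] == "GH5"].set_index("family")
        a = gh5[gh5["timepoint_h"] == 1.0]
        assert a.loc["famA", "proportion"] == pytest.approx(0.75)
        assert a.loc["famB", "proportion"] == pytest.approx(0.25)

    def test_shares_sum_to_one_where_defined(self, default_bundle):
        tpm = compute_tpm(default_bundle.table)
        nb = default_bundle.design.non_baseline_samples()
        contrib = taxon_contributions(tpm[nb], default_bundle.table.gene_meta,
                                      default_bundle.design)
        defined = contrib.dropna(subset=["proportion"])
        sums = defined.groupby(["enzyme_type", "enzyme_family", "timepoint_h"])[
            "proportion"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, rtol=1e-9)
        assert defined["proportion"].between(0, 1 + 1e-12).all()

    def test_silent_timepoint_emitted_missing(self):
        design, meta = self._setup()
        tpm = pd.DataFrame(0.0, index=meta.index, columns=design.sample_ids)
        t1 = [s for s in design.sample_ids if design.table.loc[s, "timepoint_h"] == 1.0]
        tpm.loc["g3", t1] = 5.0  # M24 expressed only at 1 h
        contrib = taxon_contributions(tpm, meta, design)
        m24 = contrib[contrib["enzyme_family"] == "M24"].set_index("timepoint_h")
        assert m24.loc[1.0, "proportion"] == pytest.approx(1.0)
        assert np.isnan(m24.loc[2.0, "proportion"])


def test_run_enzymes_structure(default_bundle):
    """The LuxS path mirrors the GH/peptidase analysis: per-taxon sums are
    tested and lettered when significant."""
    res = run_enzymes(default_bundle.table, default_bundle.design)
    assert {"GH", "peptidase", "LuxS"} <= set(
        res.tpm_sums.index.get_level_values("enzyme_type"))
    assert set(res.anova.index) == set(res.retained.index)
    if len(res.letters):
        assert set(res.letters.columns) >= {"enzyme_type", "unit", "T1", "T8"}
        sig = res.anova[res.anova["significant"]]
        assert len(res.letters) == len(sig)
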