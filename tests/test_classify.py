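import numpy as np
import pandas as pd
import pytest

from cpghm.classify import (
    ClassifierConfig,
    CpGHypermutatorModel,
    TukeyFence,
    global_cpg_threshold,
    group_cohorts,
    ici_classify,
    select_representative,
    tukey_upper_fence,
)


class TestTukeyFence:
    def test_printed_cohort_quartiles_give_060_threshold(self):
        # the CpG-proportion distribution's Q3/IQR yield the 0.60 cut-off
        fence = TukeyFence.from_quartiles(q3=0.305, iqr=0.193)
        assert fence.upper == pytest.approx(0.5945)
        assert round(fence.upper, 1) == 0.6

    def test_linear_interpolation_quantiles(self):
        fence = tukey_upper_fence(np.arange(1, 13))
        assert fence.q3 == pytest.approx(9.25)
        assert fence.iqr == pytest.approx(5.5)
        assert fence.upper == pytest.approx(17.5)

    def test_constant_values_degenerate_fence(self):
        fence = tukey_upper_fence([4.0, 4.0, 4.0])
        assert fence.iqr == 0
        assert fence.upper == 4.0

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            tukey_upper_fence([1.0])


class TestRepresentativeSelection:
    def _meta(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "patient_id", "study_id", "histology",
                           "method", "timing"],
        )

    def test_primary_preferred_over_metastasis(self):
        meta = self._meta([("S1", "P1", "ST", "H", "WES", "primary"),
                           ("S2", "P1", "ST", "H", "WES", "metastasis")])
        out = select_representative(meta, seed=0)
        assert out.set_index("sample_id")["is_representative"].to_dict() == {
            "S1": True, "S2": False}
        assert not out["excluded_from_thresholds"].any()

    def test_metastasis_only_patient_excluded_from_thresholds(self):
        meta = self._meta([("S1", "P1", "ST", "H", "WES", "metastasis"),
                           ("S2", "P1", "ST", "H", "WES", "relapse")])
        out = select_representative(meta, seed=0)
        assert not out["is_representative"].any()
        assert out["excluded_from_thresholds"].all()

    def test_multiple_primaries_seeded_and_order_invariant(self):
        meta = self._meta([("S1", "P1", "ST", "H", "WES", "primary"),
                           ("S2", "P1", "ST", "H", "WES", "primary")])
        first = select_representative(meta, seed=7)
        again = select_representative(meta.iloc[::-1].reset_index(drop=True), seed=7)
        chosen1 = first.loc[first["is_representative"], "sample_id"].iloc[0]
        chosen2 = again.loc[again["is_representative"], "sample_id"].iloc[0]
        assert chosen1 == chosen2


class TestCohortGrouping:
    def _meta(self, n, study="ST", hist="H"):
        return pd.DataFrame({
            "sample_id": [f"S{study}{hist}{i}" for i in range(n)],
            "patient_id": [f"P{study}{hist}{i}" for i in range(n)],
            "study_id": study, "histology": hist, "method": "WES",
            "timing": "primary", "is_representative": True,
            "excluded_from_thresholds": False,
        })

    def test_cohort_of_19_dropped_20_retained(self):
        meta = pd.concat([self._meta(19, hist="A"), self._meta(20, hist="B")],
                         ignore_index=True)
        out = group_cohorts(meta, min_cohort_size=20)
        assert set(out["histology"]) == {"B"}

    def test_same_histology_different_studies_are_distinct_cohorts(self):
        meta = pd.concat([self._meta(25, study="ST1"), self._meta(25, study="ST2")],
                         ignore_index=True)
        out = group_cohorts(meta, min_cohort_size=20)
        assert out["cohort"].nunique() == 2


class TestGlobalThreshold:
    def test_fence_over_eligible_samples_only(self):
        props = pd.Series([0.1, 0.2, 0.3, 0.9])
        nmut = pd.Series([50, 50, 50, 5])  # last sample below the 10-mutation bar
        fence = global_cpg_threshold(props, nmut, min_mutations=10)
        assert fence.upper == tukey_upper_fence([0.1, 0.2, 0.3]).upper

    def test_too_few_eligible_raises(self):
        with pytest.raises(ValueError):
            global_cpg_threshold(pd.Series([0.5]), pd.Series([100]))


class TestIciClassify:
    @pytest.mark.parametrize(
        "tmb,prop,expected",
        [(12, 0.65, "TMB-Hi_CpG-Hi"), (12, 0.30, "TMB-Hi_CpG-Lo"),
         (5, 0.90, "TMB-Lo"), (10, 0.61, "TMB-Hi_CpG-Hi")],
    )
    def test_rules(self, tmb, prop, expected):
        assert ici_classify(tmb, prop) == expected


class TestClassifierEndToEnd:
    def test_strata_are_disjoint_and_nested(self, default_calls):
        calls = default_calls.calls
        assert set(calls["label"]) <= {"non-HM", "HM_CpG-Lo", "HM_CpG-Hi"}
        hm = calls["label"] != "non-HM"
        hi = calls["label"] == "HM_CpG-Hi"
        assert (hi & ~hm).sum() == 0  # every CpG-Hi is a hypermutator

    def test_order_invariance(self, small_cohort):
        cfg = ClassifierConfig(rng_seed=3)
        res1 = CpGHypermutatorModel(small_cohort.catalog, small_cohort.meta,
                                    regions=small_cohort.reference.regions,
                                    config=cfg).fit()
        shuffled_cat = small_cohort.catalog.sample(frac=1, random_state=9).reset_index(drop=True)
        shuffled_meta = small_cohort.meta.sample(frac=1, random_state=9).reset_index(drop=True)
        res2 = CpGHypermutatorModel(shuffled_cat, shuffled_meta,
                                    regions=small_cohort.reference.regions,
                                    config=cfg).fit()
        pd.testing.assert_series_equal(res1.labels.sort_index(),
                                       res2.labels.sort_index())

    def test_lower_fence_multiplier_never_decreases_hm_calls(self, small_cohort):
        def n_hm(mult):
            cfg = ClassifierConfig(rng_seed=0, fence_multiplier=mult)
            res = CpGHypermutatorModel(small_cohort.catalog, small_cohort.meta,
                                       regions=small_cohort.reference.regions,
                                       config=cfg).fit()
            return (res.calls["label"] != "non-HM").sum()

        assert n_hm(1.0) >= n_hm(1.5) >= n_hm(2.5)

    def test_agrees_with_brute_force_rule_enumeration(self, small_cohort):
        """Independent re-implementation: enumerate the three criteria
        directly from per-sample counts and cohort quantiles."""
        from cpghm.spectrum import cpg_ct_proportion
        from cpghm.catalog import restrict_to_regions

        cfg = ClassifierConfig(rng_seed=0)
        res = CpGHypermutatorModel(small_cohort.catalog, small_cohort.meta,
                                   regions=small_cohort.reference.regions,
                                   config=cfg).fit()
        cat = restrict_to_regions(small_cohort.catalog, small_cohort.reference.regions)
        total_mb = small_cohort.reference.regions.total_mb
        calls = res.calls.set_index("sample_id")
        counts = cat.groupby("sample_id").size()
        props = {sid: cpg_ct_proportion(g) for sid, g in cat.groupby("sample_id")}
        # thresholds recomputed independently with numpy quantiles
        rep = calls[calls["is_representative"]]
        tmb_floor = np.median(rep["n_mutations"] / total_mb)
        eligible = rep[rep["n_mutations"] > 10]["cpg_proportion"].dropna()
        q1, q3 = np.percentile(eligible, [25, 75])
        cpg_thr = q3 + 1.5 * (q3 - q1)
        for cohort_key, grp in calls.groupby("cohort"):
            gq1, gq3 = np.percentile(
                grp.loc[grp["is_representative"], "n_mutations"], [25, 75])
            fence = gq3 + 1.5 * (gq3 - gq1)
            for sid, row in grp.iterrows():
                n = counts.get(sid, 0)
                is_hm = (n > fence) and (n / total_mb > tmb_floor)
                p = props.get(sid, np.nan)
                expected = ("HM_CpG-Hi" if is_hm and p > cpg_thr
                            else "HM_CpG-Lo" if is_hm else "non-HM")
                assert row["label"] == expected, sid

    def test_frozen_cpg_threshold_mode(self, small_cohort):
        cfg = ClassifierConfig(rng_seed=0, cpg_threshold=0.60)
        res = CpGHypermutatorModel(small_cohort.catalog, small_cohort.meta,
                                   regions=small_cohort.reference.regions,
                                   config=cfg).fit()
        assert res.cpg_threshold == 0.60

    def test_summary_and_manifest_report_thresholds(self, default_calls):
        text = default_calls.summary()
        assert "global CpG>TpG threshold" in text
        m = default_calls.manifest()
        assert m["config"]["rng_seed"] == 0
        assert m["global_cpg_threshold"] == pytest.approx(default_calls.cpg_threshold)
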