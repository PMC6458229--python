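import numpy as np
import pandas as pd
import pytest

from cityframe import correct as cx
from cityframe.harmonize import ILL_DEFINED_DISEASE, ILL_DEFINED_INJURY, MISSING
from conftest import make_agg_table


def records_frame(n, **overrides):
    base = {
        "country": "XX", "year": 2010, "l2_code": "m1", "age5": "65-69",
        "sex": "male", "education": "primary completed",
        "icd_code": "I21", "icd_revision": 10,
        "cause_group": "cardiovascular", "ill_flag": "well_defined",
        "age_imputed": False, "sex_imputed": False, "cause_imputed": False,
        "sampled_replicate": False,
    }
    base.update(overrides)
    return pd.DataFrame([dict(base) for _ in range(n)])


class TestDropMissingLocation:
    def test_planted_missing_dropped_and_audited(self):
        df = pd.concat(
            [records_frame(93), records_frame(7, l2_code=None)], ignore_index=True
        )
        kept, audit = cx.drop_missing_location(df)
        assert len(kept) == 93
        assert audit["n_dropped"].sum() == 7

    def test_none_missing_identity(self):
        df = records_frame(10)
        kept, audit = cx.drop_missing_location(df)
        assert len(kept) == 10 and audit.empty

    def test_all_missing_empty_output(self):
        df = records_frame(4, l2_code=None)
        kept, audit = cx.drop_missing_location(df)
        assert kept.empty and audit["n_dropped"].sum() == 4


class TestImputeMissing:
    def test_degenerate_stratum(self):
        df = pd.concat(
            [records_frame(20, age5="70-74"), records_frame(3, age5=MISSING)],
            ignore_index=True,
        )
        out, audit = cx.impute_missing(df, seed=5)
        assert (out["age5"] == "70-74").all()
        assert audit["age_imputed"] == 3
        assert out["age_imputed"].sum() == 3

    def test_missing_cause_goes_to_ill_defined_only(self):
        df = pd.concat(
            [
                records_frame(30),
                records_frame(10, cause_group=ILL_DEFINED_DISEASE, icd_code="R99",
                              ill_flag="ill_defined_disease"),
                records_frame(5, cause_group=ILL_DEFINED_INJURY, icd_code="Y10",
                              ill_flag="ill_defined_injury"),
                records_frame(8, cause_group=MISSING, icd_code=None, ill_flag=MISSING),
            ],
            ignore_index=True,
        )
        out, _ = cx.impute_missing(df, seed=5)
        imputed = out[out["cause_imputed"]]
        assert len(imputed) == 8
        assert imputed["cause_group"].isin([ILL_DEFINED_DISEASE, ILL_DEFINED_INJURY]).all()
        assert imputed["ill_flag"].isin(["ill_defined_disease", "ill_defined_injury"]).all()

    def test_nonmissing_fields_untouched_and_count_preserved(self, harmonized):
        table, _ = harmonized
        out, _ = cx.impute_missing(table, seed=5)
        assert len(out) == len(table)
        present = table["age5"] != MISSING
        assert (out.loc[present, "age5"] == table.loc[present, "age5"]).all()
        present_sex = table["sex"] != MISSING
        assert (out.loc[present_sex, "sex"] == table.loc[present_sex, "sex"]).all()

    def test_reproducible_given_seed(self, harmonized):
        table, _ = harmonized
        a, _ = cx.impute_missing(table, seed=9)
        b, _ = cx.impute_missing(table, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_backoff_uses_country_marginal(self):
        # missing-age record whose (sex, cause) stratum has no donors at all
        donors = records_frame(50, age5="30-34")
        orphan = records_frame(1, age5=MISSING, sex="female", cause_group="cancer")
        out, _ = cx.impute_missing(pd.concat([donors, orphan], ignore_index=True), seed=1)
        assert out.iloc[-1]["age5"] == "30-34"

    def test_no_donors_anywhere_errors(self):
        df = records_frame(3, age5=MISSING)
        with pytest.raises(cx.CorrectionError, match="donor"):
            cx.impute_missing(df, seed=1)

    def test_imputed_frequencies_track_donor_distribution(self):
        """Imputed age-band shares reproduce the donor conditional distribution."""
        rng = np.random.default_rng(0)
        bands = ["60-64", "65-69", "70-74"]
        probs = [0.5, 0.3, 0.2]
        donors = records_frame(5000)
        donors["age5"] = rng.choice(bands, size=5000, p=probs)
        missing = records_frame(10_000, age5=MISSING)
        out, _ = cx.impute_missing(pd.concat([donors, missing], ignore_index=True), seed=3)
        freqs = out.iloc[5000:]["age5"].value_counts(normalize=True)
        donor_freqs = donors["age5"].value_counts(normalize=True)
        for band in bands:
            assert abs(freqs[band] - donor_freqs[band]) < 0.01


class TestRedistribute:
    def row(self, cause, observed, l2="m1", age5="65-69", sex="male"):
        return ("XX", 2010, l2, age5, sex, "primary completed", cause, observed, observed)

    def test_proportional_allocation(self):
        table = make_agg_table(
            [self.row("cardio", 30), self.row("injury", 10), self.row(ILL_DEFINED_DISEASE, 8)]
        )
        out = cx.redistribute_ill_defined(table, value_cols=("observed_count",))
        got = out.set_index("cause_group")["observed_count_redistributed"]
        assert got["cardio"] == pytest.approx(36.0)
        assert got["injury"] == pytest.approx(12.0)
        assert got[ILL_DEFINED_DISEASE] == 0.0

    def test_no_ill_defined_identity(self):
        table = make_agg_table([self.row("cardio", 30)])
        out = cx.redistribute_ill_defined(table)
        assert (out["observed_count_redistributed"] == out["observed_count"]).all()

    def test_stratum_totals_conserved_random(self, rng):
        rows = []
        causes = ["cardio", "cancer", ILL_DEFINED_DISEASE, ILL_DEFINED_INJURY]
        for l2 in ("m1", "m2"):
            for age5 in ("30-34", "65-69"):
                for sex in ("male", "female"):
                    for cause in causes:
                        rows.append(self.row(cause, int(rng.integers(0, 50)), l2, age5, sex))
        table = make_agg_table(rows)
        out = cx.redistribute_ill_defined(table)
        for (age5, sex), grp in out.groupby(["age5", "sex"]):
            pre = table[(table.age5 == age5) & (table.sex == sex)]["observed_count"].sum()
            assert grp["observed_count_redistributed"].sum() == pytest.approx(float(pre), abs=1e-9)
        assert (
            out.loc[out.cause_group.isin(cx.ILL_CLASSES), "observed_count_redistributed"] == 0
        ).all()

    def test_empty_stratum_backs_off_then_buckets(self):
        # stratum with only ill-defined deaths: falls back to the coarser
        # stratum's cause mix; with no well-defined deaths anywhere the mass
        # lands in the explicit unredistributable bucket
        lone = make_agg_table([self.row(ILL_DEFINED_DISEASE, 5)])
        out = cx.redistribute_ill_defined(lone)
        bucket = out[out.cause_group == cx.UNREDISTRIBUTABLE]
        assert bucket["observed_count_redistributed"].sum() == pytest.approx(5.0)

        with_other_stratum = make_agg_table(
            [self.row(ILL_DEFINED_DISEASE, 5), self.row("cardio", 7, age5="30-34", sex="female")]
        )
        out2 = cx.redistribute_ill_defined(with_other_stratum)
        got = out2.groupby("cause_group")["observed_count_redistributed"].sum()
        # borrowed cause mix, but the deaths stay in their own age-sex cell
        assert got["cardio"] == pytest.approx(12.0)
        moved = out2[(out2.cause_group == "cardio") & (out2.age5 == "65-69")]
        assert moved["observed_count_redistributed"].sum() == pytest.approx(5.0)


class TestUndercount:
    def factor(self, c, **kw):
        return cx.CompletenessFactor(country="XX", value=c, **kw)

    def test_complete_registration_identity(self):
        df = records_frame(50)
        out = cx.correct_undercount(df, [self.factor(1.0)], seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_expected_replicates(self):
        df = records_frame(80)
        added = [
            len(cx.correct_undercount(df, [self.factor(0.8)], seed=s)) - 80
            for s in range(200)
        ]
        assert np.mean(added) == pytest.approx(20.0, abs=1.0)

    def test_single_donor_hot_deck_clones_content(self):
        df = records_frame(6)
        out = cx.correct_undercount(df, [self.factor(0.5)], seed=2)
        reps = out[out["sampled_replicate"]]
        assert len(reps) in (5, 6, 7)
        assert (reps["icd_code"] == "I21").all() and (reps["age5"] == "65-69").all()

    def test_most_specific_factor_wins(self):
        df = pd.concat([records_frame(40), records_frame(40, sex="female")],
                       ignore_index=True)
        factors = [self.factor(1.0), self.factor(0.5, sex="female")]
        out = cx.correct_undercount(df, factors, seed=3)
        reps = out[out["sampled_replicate"]]
        assert (reps["sex"] == "female").all()
        assert len(reps) > 0

    def test_invalid_completeness_rejected(self):
        with pytest.raises(cx.CorrectionError):
            self.factor(0.0)
        with pytest.raises(cx.CorrectionError):
            self.factor(1.2)

    def test_corrected_ratio_converges_to_inverse_completeness(self):
        """corrected/observed per cell approaches 1/c for a large cell."""
        df = records_frame(20_000)
        out = cx.correct_undercount(df, [self.factor(0.8)], seed=4)
        assert len(out) / 20_000 == pytest.approx(1 / 0.8, rel=0.02)


class TestRecordLevelRedistribution:
    def test_ill_defined_records_reassigned_to_observed_causes(self):
        df = pd.concat(
            [
                records_frame(30),
                records_frame(10, cause_group="cancer", icd_code="C50"),
                records_frame(8, cause_group=ILL_DEFINED_DISEASE, icd_code="R99",
                              ill_flag="ill_defined_disease"),
            ],
            ignore_index=True,
        )
        out = cx.redistribute_records(df, seed=6)
        assert len(out) == len(df)
        assert not out["cause_group"].isin(cx.ILL_CLASSES).any()
        assert out.iloc[40:]["cause_group"].isin(["cardiovascular", "cancer"]).all()

    def test_alternative_pipeline_order_runs(self, harmonized, country_factor):
        table, _ = harmonized
        _, agg, audit = cx.run_pipeline(
            table.head(2000), country_factor, seed=3, redistribute_before_undercount=True
        )
        assert audit["n_input"] == 2000
        assert not agg["cause_group"].isin(cx.ILL_CLASSES).any()


class TestAggregate:
    def test_observed_excludes_replicates(self):
        df = pd.concat(
            [records_frame(5), records_frame(2, sampled_replicate=True)], ignore_index=True
        )
        table = cx.aggregate_deaths(df, redistribute=False)
        assert table["observed_count"].sum() == 5
        assert table["corrected_count"].sum() == 7

    def test_empty_input_empty_table(self):
        table = cx.aggregate_deaths(records_frame(0))
        assert table.empty

    def test_total_reconciles_with_records(self, harmonized, country_factor):
        table, _ = harmonized
        kept, _ = cx.drop_missing_location(table)
        imputed, _ = cx.impute_missing(kept, seed=7)
        corrected = cx.correct_undercount(imputed, country_factor, seed=7)
        agg = cx.aggregate_deaths(corrected)
        assert agg["observed_count"].sum() == (~corrected["sampled_replicate"]).sum()
        assert agg["corrected_count"].sum() == len(corrected)
        assert agg["corrected_count_redistributed"].sum() == pytest.approx(
            float(len(corrected)), abs=1e-6
        )
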