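import datetime as dt

import numpy as np
import pytest

from ocstrat import clinical as clin


def make_record(
    sample_id="S1",
    recist="NA",
    followup_days=400,
    vital="alive",
    treatments=(),
    recurrences=(),
    histology="HGSC",
):
    return clin.ClinicalRecord(
        sample_id=sample_id,
        patient_id=f"P-{sample_id}",
        disease_status="recurrent",
        histology=histology,
        grade="poor",
        figo="III",
        biopsy_site="peritoneum",
        biopsy_date=dt.date(2019, 6, 1),
        treatments=list(treatments),
        recist=recist,
        recurrence_dates=list(recurrences),
        followup_days=followup_days,
        vital_status=vital,
    )


def platinum(start, stop, pre=True):
    return clin.Treatment("carboplatin", "chemo", start, stop, pre)


class TestResponseGrouping:
    @pytest.mark.parametrize(
        "recist,expected",
        [("CR", "favorable"), ("PR", "favorable"), ("SD", "poor"),
         ("PD", "poor"), ("NA", "missing")],
    )
    def test_grouping(self, recist, expected):
        assert clin.group_response(recist) == expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            clin.group_response("MR")


class TestSerousGradeMapping:
    def test_moderate_and_poor_are_hgsc(self):
        assert clin.classify_serous_histology("poor") == "HGSC"
        assert clin.classify_serous_histology("moderate") == "HGSC"
        assert clin.classify_serous_histology("well") == "LGSC"
        assert clin.classify_serous_histology("unknown") == "serous-NOS"


class TestPfi:
    def test_days_and_bin(self):
        rec = make_record(
            treatments=[platinum(dt.date(2018, 10, 1), dt.date(2019, 1, 1))],
            recurrences=[dt.date(2019, 5, 1)],
        )
        days, bin_ = clin.compute_pfi(rec)
        assert days == 120 and bin_ == "<=6 months"

    def test_above_183_days_is_over_six_months(self):
        rec = make_record(
            treatments=[platinum(dt.date(2018, 10, 1), dt.date(2019, 1, 1))],
            recurrences=[dt.date(2019, 7, 20)],  # 200 days later
        )
        days, bin_ = clin.compute_pfi(rec)
        assert days == 200 and bin_ == ">6 months"

    def test_no_recurrence_is_na(self):
        rec = make_record(
            treatments=[platinum(dt.date(2018, 10, 1), dt.date(2019, 1, 1))]
        )
        assert clin.compute_pfi(rec) == (None, "NA")

    def test_no_platinum_is_na(self):
        rec = make_record(recurrences=[dt.date(2019, 5, 1)])
        assert clin.compute_pfi(rec) == (None, "NA")

    def test_recurrence_before_platinum_stop_raises(self):
        rec = make_record(
            treatments=[platinum(dt.date(2019, 1, 1), dt.date(2019, 6, 1))],
            recurrences=[dt.date(2019, 3, 1)],
        )
        with pytest.raises(ValueError, match="recurrence precedes"):
            clin.compute_pfi(rec)


class TestOneYearSurvival:
    def _group(self, n_survivors, n_dead_early, n_censored_early=0):
        records = [
            make_record(f"a{i}", followup_days=500) for i in range(n_survivors)
        ]
        records += [
            make_record(f"b{i}", followup_days=200, vital="dead")
            for i in range(n_dead_early)
        ]
        records += [
            make_record(f"c{i}", followup_days=100, vital="alive")
            for i in range(n_censored_early)
        ]
        return records

    @pytest.mark.parametrize(
        "survivors,dead,expected",
        [(15, 2, 88), (18, 7, 72), (47, 43, 52)],
    )
    def test_printed_pairs(self, survivors, dead, expected):
        s, at_risk, pct = clin.one_year_survival(self._group(survivors, dead))
        assert (s, at_risk, pct) == (survivors, survivors + dead, expected)

    def test_early_censored_excluded_from_both_sides(self):
        s, at_risk, pct = clin.one_year_survival(self._group(3, 1, n_censored_early=4))
        assert (s, at_risk) == (3, 4)

    def test_death_after_one_year_counts_as_survivor(self):
        records = [make_record("x", followup_days=400, vital="dead")]
        assert clin.one_year_survival(records)[:2] == (1, 1)

    def test_empty_group(self):
        assert clin.one_year_survival([]) == (0, 0, None)


class TestKm:
    def test_no_deaths_flat_curve(self):
        records = [make_record(f"s{i}", followup_days=300) for i in range(5)]
        kmf = clin.km_curve(records)
        assert kmf.survival_function_.iloc[-1, 0] == 1.0

    def test_all_die_at_100(self):
        records = [
            make_record(f"s{i}", followup_days=100, vital="dead") for i in range(5)
        ]
        kmf = clin.km_curve(records)
        assert kmf.predict(99.0) == 1.0
        assert kmf.predict(100.0) == 0.0

    def test_negative_times_rejected(self):
        rec = make_record()
        rec.followup_days = -1  # bypasses construction-time validation
        with pytest.raises(ValueError):
            clin.km_curve([rec])

    def test_matches_exponential_survival_within_ci(self, rng):
        """Product-limit estimate brackets the true e^{-lambda t} curve."""
        lam = 0.002
        n = 500
        death = rng.exponential(1 / lam, size=n)
        censor = rng.uniform(0, 1500, size=n)
        records = [
            make_record(
                f"s{i}",
                followup_days=int(min(d, c)),
                vital="dead" if d <= c else "alive",
            )
            for i, (d, c) in enumerate(zip(death, censor))
        ]
        kmf = clin.km_curve(records)
        ci = kmf.confidence_interval_survival_function_
        for t in (100.0, 300.0, 500.0):
            truth = np.exp(-lam * t)
            idx = ci.index[ci.index <= t][-1]
            lo, hi = ci.loc[idx].tolist()
            assert lo <= truth <= hi


class TestRankSum:
    def test_matches_permutation_oracle(self, rng):
        """Rank-sum p-value agrees with a permutation test at small n."""
        x = rng.normal(0, 1, 8)
        y = rng.normal(1, 1, 9)
        p = clin.wilcoxon_rank_sum(x, y)

        def stat(a, b):
            combined = np.concatenate([a, b])
            ranks = np.argsort(np.argsort(combined)) + 1
            return ranks[: len(a)].sum()

        obs = stat(x, y)
        pooled = np.concatenate([x, y])
        n_perm = 20_000
        count = 0
        mean_stat = len(x) * (len(x) + len(y) + 1) / 2
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(stat(perm[: len(x)], perm[len(x):]) - mean_stat) >= abs(obs - mean_stat) - 1e-9:
                count += 1
        p_perm = count / n_perm
        assert abs(p - p_perm) < 0.02

    def test_bonferroni(self):
        assert clin.bonferroni(0.003, 7) == pytest.approx(0.021)
        assert clin.bonferroni(0.5, 7) == 1.0


class TestClusterSummaries:
    def test_response_percentages(self):
        labels = {f"s{i}": 1 for i in range(42)}
        records = {}
        for i in range(42):
            recist = "PR" if i < 17 else ("SD" if i < 35 else "NA")
            records[f"s{i}"] = make_record(f"s{i}", recist=recist)
        (summary,) = clin.summarize_cluster(labels, records)
        assert summary.favorable_n == 17
        assert summary.favorable_n + summary.poor_n == 35
        assert clin.percent(summary.favorable_n, 35) == 49

    def test_label_without_record_raises(self):
        with pytest.raises(ValueError, match="s1"):
            clin.summarize_cluster({"s1": 1}, {})

    def test_partition_invariant(self):
        labels = {"a": 1, "b": 1, "c": 2}
        records = {k: make_record(k, recist=r) for k, r in
                   zip("abc", ["CR", "NA", "PD"])}
        summaries = clin.summarize_cluster(labels, records)
        for s in summaries:
            assert s.favorable_n + s.poor_n + s.missing_response_n == s.n


class TestRoundTrip:
    def test_clinical_tsv_roundtrip(self, tmp_path):
        rec = make_record(
            treatments=[platinum(dt.date(2018, 10, 1), dt.date(2019, 1, 1))],
            recurrences=[dt.date(2019, 5, 1)],
            recist="PR",
        )
        path = tmp_path / "clin.tsv"
        clin.write_clinical([rec], path)
        (back,) = clin.read_clinical(path)
        assert back == rec

    def test_drug_class_map_covers_platinum(self):
        df = clin.drug_class_map()
        platinum_drugs = set(df[df.platinum].drug)
        assert {"carboplatin", "cisplatin"} <= platinum_drugs
        assert set(df.drug_class) <= set(clin.DRUG_CLASSES)
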