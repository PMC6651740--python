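"""Cohort I/O and the pre/post study statistics against the printed study."""

import json

import pytest

from cardiofuzz import (
    ParticipantRecord,
    category_ratios,
    group_summary,
    overall_improvements,
    per_subject_metrics,
    read_cohort,
    report,
    write_cohort,
)
from cardiofuzz.physiology import round1, round_half_away

from conftest import brute_population_std

# Per-subject indicator percentages as printed in the study's category tables.
PRINTED_DRHR = {
    "E13": 18, "E1": 13, "E7": 16, "E10": 15, "E21": 16, "E23": 14,
    "E2": 11, "E3": 11, "E4": 11, "E6": 15, "E16": 4, "E17": 12, "E20": 7,
    "E24": 13, "E25": 13, "E5": 7, "E8": 5, "E9": 9, "E14": 8, "E15": 5,
    "E19": 11, "E22": 13, "E11": 7, "E12": 5, "E18": 15,
}
PRINTED_GHRR = {
    "E13": 27, "E1": 90, "E7": 114, "E10": 106, "E21": 100, "E23": 105,
    "E2": 41, "E3": 40, "E4": 38, "E6": 19, "E16": 5, "E17": 13, "E20": 14,
    "E24": 34, "E25": 35, "E5": 77, "E8": 52, "E9": 65, "E14": 89, "E15": 64,
    "E19": 64, "E22": 100, "E11": 11, "E12": 0, "E18": 17,
}
PRINTED_CATEGORY = {"E13": "over-80", "E18": "below-70", "E19": "70s", "E7": "over-80"}

# Group summary rows as printed: (pre_mean, pre_std, post_mean, post_std,
# mean_diff, improvement_pct)
PRINTED_SUMMARY = {
    ("reference", "RHR"): (72.1, 6.6, 64.3, 4.5, -7.8, 11),
    ("reference", "HRR"): (37.3, 6.7, 45.2, 3.9, 7.9, 23),
    ("control", "RHR"): (78.0, 3.7, 69.2, 3.5, -8.8, 11),
    ("control", "HRR"): (23.2, 7.5, 40.2, 5.6, 17.0, 80),
}


class TestCohortIO:
    def test_packaged_cohort_shape(self, cohort):
        assert len(cohort) == 25
        groups = [r.group for r in cohort]
        assert groups.count("reference") == 12
        assert groups.count("control") == 13
        e2 = next(r for r in cohort if r.code == "E2")
        assert (e2.pre_rhr, e2.pre_hrr, e2.post_rhr, e2.post_hrr) == (76, 32, 68, 45)

    def test_round_trip(self, tmp_path, cohort):
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        assert read_cohort(path) == cohort

    def test_empty_file_is_empty_cohort(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        assert read_cohort(path) == []
        path.write_text("code,group,pre_rhr,pre_hrr,post_rhr,post_hrr\n")
        assert read_cohort(path) == []

    def test_duplicate_code_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "code,group,pre_rhr,pre_hrr,post_rhr,post_hrr\n"
            "E1,control,80,20,70,30\nE1,control,81,21,71,31\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(path)

    def test_missing_column_and_bad_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("code,group,pre_rhr\nE1,control,80\n")
        with pytest.raises(ValueError, match="missing column"):
            read_cohort(path)
        path.write_text(
            "code,group,pre_rhr,pre_hrr,post_rhr,post_hrr\n"
            "E1,control,eighty,20,70,30\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_cohort(path)

    def test_invalid_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            ParticipantRecord("X1", "placebo", 70, 30, 65, 35)


class TestPerSubjectMetrics:
    def test_every_printed_indicator_reproduced(self, cohort):
        metrics = {m.code: m for m in per_subject_metrics(cohort, include_cel=False)}
        assert set(metrics) == set(PRINTED_DRHR)
        for code, expected in PRINTED_DRHR.items():
            assert metrics[code].drhr_pct == expected, code
        for code, expected in PRINTED_GHRR.items():
            assert metrics[code].ghrr_pct == expected, code

    def test_categories_match_printed_table_placement(self, cohort):
        metrics = {m.code: m for m in per_subject_metrics(cohort, include_cel=False)}
        for code, category in PRINTED_CATEGORY.items():
            assert metrics[code].rhr_category == category

    def test_cel_computed_from_post_readings(self, cohort):
        metrics = {m.code: m for m in per_subject_metrics(cohort, include_cel=True)}
        for m in metrics.values():
            assert m.cel is not None and 0 <= m.cel.score <= 100
        # E12 ends fit: post RHR 55 (Sportsman), post HRR 52 (Quite) -> Excellent band
        assert metrics["E12"].cel.label in ("E", "SE")


class TestGroupSummary:
    def test_matches_printed_table(self, cohort):
        summaries = group_summary(cohort)
        for (group, indicator), row in PRINTED_SUMMARY.items():
            s = summaries[group][indicator]
            assert (s.pre_mean, s.pre_std, s.post_mean, s.post_std,
                    s.mean_diff, s.improvement_pct) == row, (group, indicator)

    def test_brute_force_oracle(self, cohort):
        """Every summary number recomputed by direct loops over the records."""
        summaries = group_summary(cohort)
        for group in ("reference", "control"):
            members = [r for r in cohort if r.group == group]
            for indicator, pre_attr, post_attr in (
                ("RHR", "pre_rhr", "post_rhr"), ("HRR", "pre_hrr", "post_hrr")):
                pre = [getattr(r, pre_attr) for r in members]
                post = [getattr(r, post_attr) for r in members]
                s = summaries[group][indicator]
                assert s.n == len(members)
                assert s.pre_mean == round1(sum(pre) / len(pre))
                assert s.post_mean == round1(sum(post) / len(post))
                assert s.pre_std == round1(brute_population_std(pre))
                assert s.post_std == round1(brute_population_std(post))
                assert s.mean_diff == round1(s.post_mean - s.pre_mean)
                diffs = [b - a for a, b in zip(pre, post)]
                assert s.paired_diff_std == round1(brute_population_std(diffs))
                if indicator == "RHR":
                    pcts = [round_half_away((a - b) / a * 100) for a, b in zip(pre, post)]
                else:
                    pcts = [round_half_away((b - a) / a * 100) for a, b in zip(pre, post)]
                assert s.improvement_pct == round_half_away(sum(pcts) / len(pcts))

    def test_all_eight_printed_stds_need_population_convention(self, cohort):
        """Population (divide-by-n) STD reproduces all eight printed values."""
        printed = [PRINTED_SUMMARY[k][i] for k in PRINTED_SUMMARY for i in (1, 3)]
        summaries = group_summary(cohort)
        computed = [getattr(summaries[g][ind], a)
                    for (g, ind) in PRINTED_SUMMARY for a in ("pre_std", "post_std")]
        assert computed == printed

    def test_single_subject_group(self):
        cohort = [ParticipantRecord("A", "reference", 70, 30, 65, 36),
                  ParticipantRecord("B", "control", 80, 20, 72, 28)]
        s = group_summary(cohort)["reference"]["RHR"]
        assert (s.pre_mean, s.pre_std, s.mean_diff) == (70.0, 0.0, -5.0)

    def test_empty_group_rejected(self):
        only_ref = [ParticipantRecord("A", "reference", 70, 30, 65, 36)]
        with pytest.raises(ValueError, match="empty"):
            group_summary(only_ref)


class TestCohortAggregates:
    def test_overall_improvements(self, cohort):
        rhr, hrr = overall_improvements(group_summary(cohort))
        assert rhr == pytest.approx(11.0)
        assert hrr == pytest.approx(51.5)

    def test_category_ratios(self, cohort):
        ratios = category_ratios(cohort)
        assert ratios.counts == {"over-80": 6, "70s": 16, "below-70": 3}
        assert ratios.fractions["over-80"] == pytest.approx(0.24)
        assert ratios.fractions["70s"] == pytest.approx(0.64)
        assert ratios.fractions["below-70"] == pytest.approx(0.12)
        assert sum(ratios.fractions.values()) == pytest.approx(1.0)

    def test_uniform_cohort_single_category(self):
        cohort = [ParticipantRecord(f"S{i}", "reference" if i < 3 else "control",
                                    75, 30, 70, 35) for i in range(6)]
        assert category_ratios(cohort).fractions == {"over-80": 0.0, "70s": 1.0,
                                                     "below-70": 0.0}


class TestReport:
    def test_report_contents_and_determinism(self, tmp_path, cohort):
        p1, p2 = tmp_path / "r1.json", tmp_path / "r2.json"
        doc = report(cohort, path=p1)
        report(cohort, path=p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert doc["n_subjects"] == 25
        assert len(doc["subjects"]) == 25
        assert doc["overall_improvement_pct"] == {"RHR": 11.0, "HRR": 51.5}
        parsed = json.loads(p1.read_text())
        assert parsed["groups"]["control"]["HRR"]["improvement_pct"] == 80

    def test_cel_column_optional(self, cohort):
        doc = report(cohort, include_cel=False)
        assert all("cel" not in s for s in doc["subjects"])
        doc_with = report(cohort, include_cel=True)
        assert all("cel" in s for s in doc_with["subjects"])

    def test_unwritable_path_raises(self, tmp_path, cohort):
        with pytest.raises(OSError):
            report(cohort, path=tmp_path / "missing_dir" / "r.json")
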