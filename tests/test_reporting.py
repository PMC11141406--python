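"""Outcome tables, checklist, study-flow accounting and file round trips."""

import numpy as np
import pandas as pd
import pytest

from rsakit.quality import QCThresholds, qc_gate
from rsakit.reporting import (
    checklist_report,
    flow_report,
    outcome_table,
    render_markdown_table,
)

from conftest import make_result


def small_study(n=25, mean=0.5, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    results = [
        make_result(
            patient_id=f"p{i}", followup_exam_id=f"p{i}-t730",
            tx=rng.normal(mean, sd), days=730,
        )
        for i in range(n)
    ]
    manifest = {
        "patients": [
            {"patient_id": f"p{i}", "group": "g1", "baseline_day": 5} for i in range(n)
        ],
        "timepoints_days": [730],
        "modality": "RSA",
    }
    return results, manifest


class TestOutcomeTable:
    def test_single_result_center_is_value_with_caveat(self):
        res = [make_result(tx=0.42, days=365)]
        out = outcome_table(res, timepoints_days=[365])
        row = out.table[(out.table["outcome"] == "tx")].iloc[0]
        assert row["center"] == pytest.approx(0.42)
        assert np.isnan(row["low"])
        assert any("CI not estimable" in c for c in out.caveats)

    def test_group_mean_within_ci_of_truth(self):
        results, _ = small_study(n=25, mean=0.5, sd=0.1)
        out = outcome_table(results, timepoints_days=[730])
        row = out.table[out.table["outcome"] == "tx"].iloc[0]
        assert row["n"] == 25
        assert row["low"] < 0.5 < row["high"]

    def test_left_results_converted_before_aggregation(self):
        res = [
            make_result(patient_id="pL", followup_exam_id="l1", tx=1.0, side="left"),
            make_result(patient_id="pR", followup_exam_id="r1", tx=1.0, side="right"),
        ]
        out = outcome_table(res, timepoints_days=[365])
        row = out.table[out.table["outcome"] == "tx"].iloc[0]
        assert row["center"] == pytest.approx(0.0)  # (−1 + 1) / 2

    def test_mean_sd_style(self):
        results, _ = small_study(n=10)
        out = outcome_table(results, style="mean_sd", timepoints_days=[730])
        row = out.table[out.table["outcome"] == "tx"].iloc[0]
        vals = np.array([r.tx for r in results])
        assert row["center"] == pytest.approx(vals.mean())
        assert row["low"] == pytest.approx(vals.std(ddof=1))  # SD slot

    def test_empty_cell_reported_not_dropped(self):
        res = [
            make_result(patient_id="a", followup_exam_id="a-1", days=365),
            make_result(patient_id="b", followup_exam_id="b-1", days=730),
        ]
        out = outcome_table(res, group_of={"a": "g1", "b": "g2"}, timepoints_days=[365, 730])
        cell = out.table[
            (out.table["group"] == "g1")
            & (out.table["timepoint_days"] == 730)
            & (out.table["outcome"] == "tx")
        ]
        assert len(cell) == 1 and cell.iloc[0]["n"] == 0

    def test_two_group_difference_with_ci(self):
        rng = np.random.default_rng(3)
        res = [
            make_result(patient_id=f"a{i}", followup_exam_id=f"a{i}-1",
                        tx=rng.normal(0.8, 0.1), days=365)
            for i in range(15)
        ] + [
            make_result(patient_id=f"b{i}", followup_exam_id=f"b{i}-1",
                        tx=rng.normal(0.3, 0.1), days=365)
            for i in range(15)
        ]
        group_of = {r.patient_id: r.patient_id[0] for r in res}
        out = outcome_table(res, group_of, timepoints_days=[365])
        d = out.group_difference
        row = d[d["outcome"] == "tx"].iloc[0]
        assert row["low"] < 0.5 < row["high"]


class TestChecklist:
    def test_derivable_items_provided_for_complete_study(self):
        results, manifest = small_study()
        config = {
            "title_identification": "... an RSA study",
            "thresholds": QCThresholds(),
            "dpi": 150,
        }
        report = checklist_report(manifest, results, config)
        by_id = {i["item_id"]: i for i in report.items}
        for item in (
            "baseline_timing_mean_sd", "primary_endpoint_timing_mean_sd",
            "cn_me_cutoffs", "marker_method", "units_mm_deg",
            "marker_quality_summary", "raw_migration_table",
        ):
            assert by_id[item]["status"] == "provided", item
        assert by_id["surgeons"]["status"] == "missing"

    def test_ct_scanner_item_flagged_when_absent(self):
        results, manifest = small_study()
        manifest["modality"] = "CT_RSA"
        report = checklist_report(manifest, results, {})
        by_id = {i["item_id"]: i for i in report.items}
        assert by_id["ct_scanner"]["status"] == "missing"
        # marker-based items are not applicable to CT-RSA
        assert "calibration_cage" not in by_id

    def test_timing_stats_match_direct_recomputation(self):
        results, manifest = small_study()
        report = checklist_report(manifest, results, {})
        by_id = {i["item_id"]: i for i in report.items}
        days = [p["baseline_day"] for p in manifest["patients"]]
        assert f"mean {np.mean(days):.1f}" in by_id["baseline_timing_mean_sd"]["value"]

    def test_markdown_and_json_render(self):
        results, manifest = small_study(n=3)
        report = checklist_report(manifest, results, {})
        md = report.to_markdown()
        assert md.startswith("| Section | Item |")
        assert "checklist" in report.to_json()


class TestFlowReport:
    def test_no_exclusions_no_missing(self):
        results, manifest = small_study(n=5)
        flow = flow_report(manifest, results, qc_gate(results))
        assert (flow.rows["missing"] == 0).all()
        assert flow.check_conservation()

    def test_quality_exclusions_counted(self):
        results, manifest = small_study(n=6)
        for r in results[:3]:
            object.__setattr__(r.quality_migrating, "me", 0.9)  # frozen dataclass
        gate = qc_gate(results)
        flow = flow_report(manifest, results, gate)
        row = flow.rows.iloc[0]
        assert row["reason_quality_exclusion"] == 3
        assert row["analyzed"] == 3
        assert flow.check_conservation()

    def test_generator_dropout_counts_match(self):
        from rsakit.migration import compute_migration
        from rsakit.phantom import StudyGroup, StudyScenario, gen_study

        scen = StudyScenario(
            groups=[StudyGroup("g1", 10)], dropout_hazard=0.25, seed=3
        )
        study = gen_study(scen)
        exams = {e.exam_id: e for e in study.examinations}
        results = []
        for p in study.manifest["patients"]:
            pid = p["patient_id"]
            base = exams[f"{pid}-base"]
            for tp in study.manifest["timepoints_days"]:
                eid = f"{pid}-t{tp}"
                if eid in exams:
                    results.append(compute_migration(base, exams[eid]))
        flow = flow_report(study.manifest, results, qc_gate(results))
        n_dropout_truth = sum(
            len(gaps) for gaps in study.manifest["missing"].values()
        )
        assert flow.rows["reason_dropout"].sum() == n_dropout_truth
        assert flow.check_conservation()


class TestRenderer:
    def test_rendered_numbers_match_underlying_values(self):
        df = pd.DataFrame({"a": [0.123456], "b": ["x"]})
        md = render_markdown_table(df)
        assert "| 0.12 | x |" in md


class TestIORoundTrips:
    def test_cage_json(self, tmp_path):
        from rsakit.io import read_cage_json, write_cage_json
        from rsakit.phantom import make_setup

        cage = make_setup("uniplanar").cage
        path = tmp_path / "cage.json"
        write_cage_json(cage, path)
        back = read_cage_json(path)
        assert back.cage_type == cage.cage_type
        for k in cage.fiducials:
            np.testing.assert_allclose(back.fiducials[k], cage.fiducials[k])

    def test_detections_csv(self, tmp_path, rng):
        from rsakit.io import read_detections_csv, write_detections_csv
        from rsakit.phantom import make_setup, project_markers

        setup = make_setup("uniplanar")
        det = project_markers({"m0": setup.marker_center}, setup, "A", rng=rng)
        path = tmp_path / "det.csv"
        write_detections_csv([det], path)
        back = read_detections_csv(path)["A"]
        np.testing.assert_allclose(back.points["m0"], det.points["m0"])
        assert back.dpi == det.dpi

    def test_marker_table_and_examinations(self, tmp_path):
        from rsakit.io import examinations_from_tables, read_marker_table, write_marker_table
        from rsakit.phantom import StudyGroup, StudyScenario, gen_study

        study = gen_study(StudyScenario(groups=[StudyGroup("g1", 2)], seed=5))
        path = tmp_path / "exams.csv"
        write_marker_table(study.examinations, path)
        table = read_marker_table(path)
        meta = {
            e.exam_id: {"patient_id": e.patient_id, "side": e.side,
                        "days_since_surgery": e.days_since_surgery, "kind": e.kind}
            for e in study.examinations
        }
        back = examinations_from_tables(table, meta)
        assert len(back) == len(study.examinations)
        orig = {e.exam_id: e for e in study.examinations}
        for e in back:
            o = orig[e.exam_id]
            assert e.days_since_surgery == o.days_since_surgery
            np.testing.assert_allclose(
                e.bodies["bone"].positions(sorted(e.bodies["bone"].marker_ids)),
                o.bodies["bone"].positions(sorted(o.bodies["bone"].marker_ids)),
                atol=1e-9,
            )

    def test_results_csv(self, tmp_path):
        from rsakit.io import read_results_csv, write_results_csv

        results = [make_result(tx=0.5, followup_exam_id="fu1")]
        path = tmp_path / "results.csv"
        write_results_csv(results, path)
        df = read_results_csv(path)
        assert df.iloc[0]["tx_mm"] == pytest.approx(0.5)
        assert df.iloc[0]["marker_method"] == "all"

    def test_thresholds_yaml(self, tmp_path):
        from rsakit.io import read_thresholds_yaml

        path = tmp_path / "thr.yaml"
        path.write_text("me_max: 0.2\n")
        thr = read_thresholds_yaml(path)
        assert thr.me_max == 0.2 and thr.cn_max == 120.0
        path.write_text("bogus_field: 1\n")
        with pytest.raises(ValueError, match="unknown threshold"):
            read_thresholds_yaml(path)
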