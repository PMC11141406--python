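"""Guideline-compliant study reporting: outcome tables, checklist, study flow.

The reporting layer turns per-patient migration results into the three
artifacts a migration study must present:

* group-level outcome tables (mean with 95% CI of the mean by default;
  mean ± SD and median/IQR styles on request, plus between-group
  differences for two-group designs),
* the reporting checklist — the study-level item list with each item
  marked provided or missing, derivable items computed from the data,
* a CONSORT-style flow report accounting for every expected examination
  (analyzed, or missing with a reason).

Numbers are rendered at 2 decimals in markdown; the CSV/JSON outputs keep
full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .migration import MigrationResult, to_right_side
from .quality import GateReport, OUTCOME_COLUMNS, WindowFinding

__all__ = [
    "outcome_table",
    "OutcomeTables",
    "CHECKLIST_ITEMS",
    "ChecklistReport",
    "checklist_report",
    "FlowReport",
    "flow_report",
    "render_markdown_table",
]


def _mean_ci(vals: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    m = float(np.mean(vals))
    n = len(vals)
    if n < 2:
        return m, float("nan"), float("nan")
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
    return m, m - float(half), m + float(half)


@dataclass
class OutcomeTables:
    """Per-cell outcome summaries plus optional between-group differences."""

    table: pd.DataFrame
    group_difference: pd.DataFrame | None = None
    caveats: list[str] = field(default_factory=list)


def outcome_table(
    results: Sequence[MigrationResult],
    group_of: Mapping[str, str] | None = None,
    style: str = "mean_ci",
    timepoints_days: Sequence[int] | None = None,
    convert_left: bool = True,
    late_baseline: bool = False,
) -> OutcomeTables:
    """Summarize migration outcomes per group × timepoint × outcome.

    Left-sided results are converted to the right-side convention before
    aggregation. Styles: ``mean_ci`` (mean and 95% CI of the mean),
    ``mean_sd``, ``median_iqr``. Empty cells are reported with n = 0, not
    dropped. For exactly two groups the mean difference with a Welch 95%
    CI is attached per timepoint and outcome.
    """
    if style not in ("mean_ci", "mean_sd", "median_iqr"):
        raise ValueError(f"unknown style {style!r}")
    if convert_left:
        results = [to_right_side(r) for r in results]
    group_of = group_of or {}

    def nearest_tp(days: int) -> int:
        if timepoints_days:
            return int(min(timepoints_days, key=lambda t: abs(t - days)))
        return int(days)

    rows = []
    for r in results:
        rec = r.components()
        rec["group"] = group_of.get(r.patient_id, "all")
        rec["timepoint_days"] = nearest_tp(r.days_since_surgery)
        rows.append(rec)
    frame = pd.DataFrame(rows)
    groups = sorted(frame["group"].unique()) if len(frame) else []
    tps = sorted(frame["timepoint_days"].unique()) if len(frame) else []

    out_rows = []
    caveats: list[str] = []
    for group in groups:
        for tp in tps:
            cell = frame[(frame["group"] == group) & (frame["timepoint_days"] == tp)]
            for outcome in OUTCOME_COLUMNS:
                vals = cell[outcome].to_numpy(dtype=float) if len(cell) else np.array([])
                row = {
                    "group": group, "timepoint_days": tp, "outcome": outcome,
                    "n": len(vals),
                    "unit": "deg" if outcome in ("rx", "ry", "rz", "tr") else "mm",
                }
                if len(vals) == 0:
                    row.update(center=float("nan"), low=float("nan"), high=float("nan"))
                elif style == "mean_ci":
                    m, lo, hi = _mean_ci(vals)
                    row.update(center=m, low=lo, high=hi)
                    if len(vals) == 1:
                        caveats.append(
                            f"{group}/day {tp}/{outcome}: single observation, CI not estimable"
                        )
                elif style == "mean_sd":
                    row.update(
                        center=float(np.mean(vals)),
                        low=float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                        high=float("nan"),
                    )
                else:
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    row.update(center=float(med), low=float(q1), high=float(q3))
                out_rows.append(row)
    table = pd.DataFrame(out_rows)

    diff = None
    if len(groups) == 2:
        g1, g2 = groups
        drows = []
        for tp in tps:
            for outcome in OUTCOME_COLUMNS:
                a = frame[(frame["group"] == g1) & (frame["timepoint_days"] == tp)][outcome].to_numpy(float)
                b = frame[(frame["group"] == g2) & (frame["timepoint_days"] == tp)][outcome].to_numpy(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                d = float(np.mean(a) - np.mean(b))
                se = np.sqrt(np.var(a, ddof=1) / len(a) + np.var(b, ddof=1) / len(b))
                if se == 0.0:
                    half = 0.0
                else:
                    dof = se**4 / (
                        (np.var(a, ddof=1) / len(a)) ** 2 / (len(a) - 1)
                        + (np.var(b, ddof=1) / len(b)) ** 2 / (len(b) - 1)
                    )
                    half = stats.t.ppf(0.975, dof) * se
                drows.append({
                    "timepoint_days": tp, "outcome": outcome,
                    "difference": d, "low": d - float(half), "high": d + float(half),
                    "groups": f"{g1} - {g2}",
                })
        diff = pd.DataFrame(drows)
    if late_baseline:
        caveats.append(
            "baseline examinations later than 2 weeks postoperatively present: "
            "migration values have limited comparability with the literature"
        )
    return OutcomeTables(table=table, group_difference=diff, caveats=caveats)


# --------------------------------------------------------------------------
# checklist

#: the study-reporting checklist items: (item_id, section, description, how)
#: how: "derived" items are computed from the supplied data; "declared"
#: items must be provided in the study config
CHECKLIST_ITEMS: tuple[tuple[str, str, str, str], ...] = (
    ("title_identification", "Title and abstract",
     "Identification as an RSA or CT-RSA study in the title", "declared"),
    ("abstract_identification", "Title and abstract",
     "Identification as an RSA or CT-RSA study in the abstract and keywords", "declared"),
    ("prior_reports", "Methods/Study details",
     "References to prior or partial results", "declared"),
    ("inclusion_period", "Methods/Study details",
     "First and last inclusion dates", "declared"),
    ("country_hospitals", "Methods/Study details",
     "Country and hospital(s) where surgeries were performed", "declared"),
    ("surgeons", "Methods/Study details",
     "Number of surgeons and surgeries per surgeon", "declared"),
    ("prosthesis_description", "Methods/Study groups",
     "Prosthesis, cement/coating and liner description per group", "declared"),
    ("weightbearing_status", "Methods/Follow-up",
     "Whether the first postoperative examination preceded weightbearing", "declared"),
    ("baseline_timing_mean_sd", "Methods/Follow-up",
     "Mean and SD of days between surgery and baseline examination", "derived"),
    ("primary_endpoint_timing_mean_sd", "Methods/Follow-up",
     "Mean and SD of days between surgery and primary endpoint examination", "derived"),
    ("measurement_method", "Methods/RSA technique",
     "Migration measurement method (marker-based RSA, model-based RSA, CT-RSA)", "declared"),
    ("patient_position", "Methods/RSA technique",
     "Patient position (supine, weightbearing)", "declared"),
    ("software_version", "Methods/RSA technique",
     "Software used, including version number", "declared"),
    ("coordinate_system", "Methods/RSA technique",
     "Location and orientation of the migration coordinate system", "declared"),
    ("fictive_points", "Methods/RSA technique",
     "Use of fictive/feature points to calculate MTPM", "declared"),
    ("image_resolution", "Methods/Marker-based technique",
     "Image resolution (DPI) and detector type", "derived"),
    ("marker_material_size", "Methods/Marker-based technique",
     "Material and size of markers", "declared"),
    ("calibration_cage", "Methods/Marker-based technique",
     "Calibration cage used, including type (uniplanar, biplanar)", "declared"),
    ("cn_me_cutoffs", "Methods/Marker-based technique",
     "Cut-off values for condition number and mean error", "derived"),
    ("marker_method", "Methods/Marker-based technique",
     "Consistent- or all-marker method", "derived"),
    ("ct_scanner", "Methods/CT-RSA technique",
     "CT scanner brand and model", "declared"),
    ("ct_acquisition", "Methods/CT-RSA technique",
     "Voxel size, slice thickness, kV, mAs", "declared"),
    ("ct_mar", "Methods/CT-RSA technique",
     "Whether metal artifact reduction was used", "declared"),
    ("ct_dose", "Methods/CT-RSA technique",
     "Effective radiation dose in mSv", "declared"),
    ("n_exams_per_cell", "Results/Study flow",
     "Number of migration examinations per group and timepoint", "derived"),
    ("missing_excluded_reasons", "Results/Study flow",
     "Number and reasons for missing or excluded examinations", "derived"),
    ("units_mm_deg", "Results/Outcome",
     "Migration presented in millimetres and degrees", "derived"),
    ("double_exam_table", "Results/Outcome",
     "Double examinations: mean, SD and n for all outcomes per group", "derived"),
    ("marker_quality_summary", "Results/Outcome",
     "Mean and SD of marker count, CN and ME per rigid body at primary timepoint", "derived"),
    ("raw_migration_table", "Results/Outcome",
     "Raw migration per group and timepoint (mean with CI/SD, or median/IQR)", "derived"),
    ("revisions_per_group", "Results/Revisions",
     "Number and reasons of revisions/failures per group", "declared"),
    ("migration_before_revision", "Results/Revisions",
     "Migration at last follow-up before revision", "declared"),
)


@dataclass
class ChecklistReport:
    """Per-item status of the reporting checklist."""

    items: list[dict]

    def to_json(self) -> str:
        return json.dumps({"checklist": self.items}, indent=2)

    def to_markdown(self) -> str:
        lines = [
            "| Section | Item | Status | Value |",
            "| --- | --- | --- | --- |",
        ]
        for item in self.items:
            value = item.get("value", "")
            if isinstance(value, float):
                value = f"{value:.2f}"
            lines.append(
                f"| {item['section']} | {item['description']} | {item['status']} | {value} |"
            )
        return "\n".join(lines) + "\n"

    def missing_items(self) -> list[str]:
        return [i["item_id"] for i in self.items if i["status"] == "missing"]


def checklist_report(
    manifest: Mapping,
    results: Sequence[MigrationResult],
    config: Mapping | None = None,
    double_table: pd.DataFrame | None = None,
    flow: "FlowReport | None" = None,
) -> ChecklistReport:
    """Fill in the reporting checklist from the study data and config.

    Items that are derivable (timing statistics, fit-quality summaries at
    the primary timepoint, flow counts) are computed; items that depend
    on the manuscript (title wording, prosthesis description, ...) are
    looked up in ``config`` by item id and flagged missing when absent.
    """
    config = config or {}
    modality = manifest.get("modality", "RSA")
    timepoints = manifest.get("timepoints_days", [])
    primary_tp = max(timepoints) if timepoints else None
    patients = manifest.get("patients", [])

    items: list[dict] = []
    for item_id, section, description, how in CHECKLIST_ITEMS:
        if modality == "RSA" and section == "Methods/CT-RSA technique":
            continue  # not applicable to marker-based studies
        if modality == "CT_RSA" and section == "Methods/Marker-based technique":
            continue
        entry = {"item_id": item_id, "section": section, "description": description}
        value = None
        status = "missing"
        if how == "declared":
            if item_id in config and config[item_id] not in (None, ""):
                status, value = "provided", config[item_id]
        elif item_id == "baseline_timing_mean_sd":
            days = [p["baseline_day"] for p in patients if "baseline_day" in p]
            if days:
                status = "provided"
                value = f"mean {np.mean(days):.1f}, SD {np.std(days, ddof=1) if len(days) > 1 else 0.0:.1f} days"
        elif item_id == "primary_endpoint_timing_mean_sd":
            if primary_tp is not None:
                days = [
                    r.days_since_surgery for r in results
                    if abs(r.days_since_surgery - primary_tp)
                    <= 0.2 * primary_tp
                ]
                if days:
                    status = "provided"
                    value = f"mean {np.mean(days):.1f}, SD {np.std(days, ddof=1) if len(days) > 1 else 0.0:.1f} days"
        elif item_id == "image_resolution":
            dpi = config.get("dpi")
            if dpi:
                status, value = "provided", f"{dpi} DPI, {config.get('detector_type', 'DR')}"
        elif item_id == "cn_me_cutoffs":
            thr = config.get("thresholds")
            if thr is not None:
                status = "provided"
                value = f"ME <= {thr.me_max} mm, CN <= {thr.cn_max:g}"
        elif item_id == "marker_method":
            methods = {r.marker_method for r in results}
            if len(methods) == 1:
                status, value = "provided", methods.pop()
            elif methods:
                status, value = "provided", "mixed: " + ", ".join(sorted(methods))
        elif item_id == "n_exams_per_cell":
            if flow is not None:
                status, value = "provided", "see flow report"
        elif item_id == "missing_excluded_reasons":
            if flow is not None:
                status, value = "provided", "see flow report"
        elif item_id == "units_mm_deg":
            status, value = "provided", "translations mm, rotations degrees"
        elif item_id == "double_exam_table":
            if double_table is not None and len(double_table):
                status, value = "provided", f"{int(double_table['n'].max())} pairs"
        elif item_id == "marker_quality_summary":
            if primary_tp is not None:
                sel = [
                    r for r in results
                    if abs(r.days_since_surgery - primary_tp) <= 0.2 * primary_tp
                ]
                if sel:
                    me = [r.quality_migrating.me for r in sel]
                    cn = [r.quality_migrating.cn for r in sel if np.isfinite(r.quality_migrating.cn)]
                    nm = [r.quality_migrating.n_markers for r in sel]
                    status = "provided"
                    value = (
                        f"markers mean {np.mean(nm):.1f}; CN mean {np.mean(cn):.1f}; "
                        f"ME mean {np.mean(me):.3f} mm"
                    )
        elif item_id == "raw_migration_table":
            if results:
                status, value = "provided", f"{len(results)} results"
        entry["status"] = status
        if value is not None:
            entry["value"] = value
        items.append(entry)
    return ChecklistReport(items=items)


# --------------------------------------------------------------------------
# study flow


@dataclass
class FlowReport:
    """Per group × timepoint accounting of expected/analyzed/missing exams."""

    rows: pd.DataFrame

    def check_conservation(self) -> bool:
        """expected = analyzed + missing, and the reasons sum to missing."""
        r = self.rows
        total_ok = bool(np.all(r["expected"] == r["analyzed"] + r["missing"]))
        reason_cols = [c for c in r.columns if c.startswith("reason_")]
        reasons_ok = bool(np.all(r[reason_cols].sum(axis=1) == r["missing"]))
        return total_ok and reasons_ok

    def to_markdown(self) -> str:
        cols = list(self.rows.columns)
        lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
        for _, row in self.rows.iterrows():
            lines.append("| " + " | ".join(str(v) for v in row.tolist()) + " |")
        return "\n".join(lines) + "\n"


def flow_report(
    manifest: Mapping,
    results: Sequence[MigrationResult],
    gate: GateReport | None = None,
    window_findings: Sequence[WindowFinding] | None = None,
) -> FlowReport:
    """Account for every expected migration examination.

    Expected counts come from the manifest (patients × protocol
    timepoints). An examination is *analyzed* when a migration result for
    it exists and passed the quality gate and the scheduling window;
    otherwise it is missing with one reason (first applicable of:
    dropout/absence per the manifest, quality exclusion, out-of-window).
    """
    patients = manifest.get("patients", [])
    timepoints = [int(t) for t in manifest.get("timepoints_days", [])]
    group_of = {p["patient_id"]: p.get("group", "all") for p in patients}
    manifest_missing = manifest.get("missing", {})

    excluded_quality = set(gate.reasons) if gate is not None else set()
    out_of_window = {
        f.exam_id for f in (window_findings or []) if f.status == "out_of_window"
    }

    def tp_of(r: MigrationResult) -> int | None:
        if not timepoints:
            return None
        return int(min(timepoints, key=lambda t: abs(t - r.days_since_surgery)))

    by_cell: dict[tuple[str, int], list[MigrationResult]] = {}
    for r in results:
        tp = tp_of(r)
        if tp is not None:
            by_cell.setdefault((r.patient_id, tp), []).append(r)

    reason_names = ("dropout", "occlusion", "quality_exclusion", "out_of_window", "missing_exam")
    rows = []
    groups = sorted({g for g in group_of.values()})
    for group in groups:
        pids = [p["patient_id"] for p in patients if p.get("group", "all") == group]
        for tp in timepoints:
            expected = len(pids)
            analyzed = 0
            reason_counts = {k: 0 for k in reason_names}
            for pid in pids:
                cell = by_cell.get((pid, tp), [])
                cell = [r for r in cell if not r.followup_exam_id.endswith("-double")]
                if not cell:
                    reason = manifest_missing.get(pid, {}).get(str(tp)) or \
                        manifest_missing.get(pid, {}).get(tp) or "missing_exam"
                    reason_counts[reason if reason in reason_counts else "missing_exam"] += 1
                    continue
                r = cell[0]
                if r.followup_exam_id in excluded_quality:
                    reason_counts["quality_exclusion"] += 1
                elif r.followup_exam_id in out_of_window:
                    reason_counts["out_of_window"] += 1
                else:
                    analyzed += 1
            row = {
                "group": group, "timepoint_days": tp,
                "expected": expected, "analyzed": analyzed,
                "missing": expected - analyzed,
            }
            row.update({f"reason_{k}": v for k, v in reason_counts.items()})
            rows.append(row)
    return FlowReport(rows=pd.DataFrame(rows))


def render_markdown_table(df: pd.DataFrame, float_fmt: str = "{:.2f}") -> str:
    """Render a DataFrame as a GitHub-style markdown table (2-decimal display)."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for v in row.tolist():
            if isinstance(v, float) and np.isfinite(v):
                cells.append(float_fmt.format(v))
            else:
                cells.append(str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
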