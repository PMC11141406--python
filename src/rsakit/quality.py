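"""Quality gating, precision, accuracy and study-design statistics.

This module covers the statistical side of an RSA migration study:

* gating of migration results on the rigid-body fit quality metrics
  (ME <= 0.35 mm, CN <= 120 by default) into the *concise* dataset, with
  the *complete* dataset always retained for the mandated dual analysis;
* bias and precision from same-day double examinations (zero expected
  motion, so the measured "migration" is pure measurement error);
* trueness/precision of a method against a phantom gold standard;
* Bland-Altman agreement between two measurement methods;
* follow-up scheduling checks (±2 weeks before 12 months, ±10% from
  12 months; baseline within 2 weeks of surgery);
* the two-sample sample-size calculation with dropout inflation;
* the Bayesian post-test revision-risk update used in screening and
  diagnostic scenarios, and the continuous-vs-stable classification of
  second-year migration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .migration import MigrationResult

__all__ = [
    "QCThresholds",
    "GateReport",
    "qc_gate",
    "double_exam_stats",
    "accuracy_vs_gold",
    "bland_altman",
    "BlandAltmanResult",
    "followup_window_check",
    "WindowFinding",
    "sample_size",
    "posterior_revision_risk",
    "classify_migration",
    "OUTCOME_COLUMNS",
]

#: outcome variables of a migration study, in reporting order
OUTCOME_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz", "tt", "tr", "mtpm")
#: signed components (bias/precision on signed differences)
SIGNED_OUTCOMES = ("tx", "ty", "tz", "rx", "ry", "rz")
#: unsigned summary metrics
UNSIGNED_OUTCOMES = ("tt", "tr", "mtpm")


@dataclass(frozen=True)
class QCThresholds:
    """Guideline quality limits; the defaults are the recommended values.

    All comparisons in the toolkit are inclusive: a value exactly at an
    upper limit passes, since the limits are phrased as acceptable upper
    bounds.
    """

    me_max: float = 0.35            # mm, upper limit for mean error of rigid-body fitting
    cn_max: float = 120.0           # condition-number upper limit (THA/TKA/UKA/TSA)
    min_markers: int = 3            # non-collinear markers per rigid body
    tr_small_angle: float = 5.0     # degrees, Pythagorean-summary validity
    min_double_fraction: float = 0.25   # fraction of patients with double exams
    dpi_min: float = 150.0          # detector resolution minimum
    bit_depth_min: int = 8          # grayscale resolution minimum
    ct_slice_max_mm: float = 1.0    # CT-RSA slice thickness
    ct_pixel_max_mm: float = 0.5    # CT-RSA pixel size
    window_before_12m_days: float = 14.0   # ±2 weeks for timepoints before 12 months
    window_from_12m_fraction: float = 0.10  # ±10% for timepoints at/after 12 months
    baseline_max_days: float = 14.0  # baseline within 2 weeks postoperatively

    def __post_init__(self) -> None:
        for name in (
            "me_max", "cn_max", "min_markers", "tr_small_angle", "min_double_fraction",
            "dpi_min", "bit_depth_min", "ct_slice_max_mm", "ct_pixel_max_mm",
            "window_before_12m_days", "window_from_12m_fraction", "baseline_max_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


@dataclass
class GateReport:
    """Concise/complete split of a result collection with per-result reasons."""

    concise: list[MigrationResult]
    complete: list[MigrationResult]
    reasons: dict[str, list[str]]  # followup exam id -> exclusion reasons
    flags: dict[str, list[str]] = field(default_factory=dict)  # retained-with-flag notes


def qc_gate(
    results: Iterable[MigrationResult],
    thresholds: QCThresholds | None = None,
    cn_exception_with_4_markers: bool = False,
) -> GateReport:
    """Split results into the concise (criteria-passing) and complete datasets.

    A result enters the concise dataset when, for both rigid bodies,
    ME <= me_max, CN <= cn_max and the marker count >= min_markers.
    When ``cn_exception_with_4_markers`` is enabled, a higher CN is
    accepted in combination with >= 4 stable (low-ME) markers, and the
    result is retained with a flag. Every exclusion carries a
    machine-readable reason for the study-flow report.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    concise: list[MigrationResult] = []
    complete: list[MigrationResult] = []
    reasons: dict[str, list[str]] = {}
    flags: dict[str, list[str]] = {}
    for res in results:
        complete.append(res)
        res_reasons: list[str] = []
        res_flags: list[str] = []
        for label, q in (("reference", res.quality_reference), ("migrating", res.quality_migrating)):
            if q.me > thr.me_max:
                res_reasons.append(f"{label}: ME {q.me:.3f} above {thr.me_max}")
            if q.n_markers < thr.min_markers:
                res_reasons.append(f"{label}: {q.n_markers} markers below minimum {thr.min_markers}")
            if q.cn > thr.cn_max:
                if cn_exception_with_4_markers and q.n_markers >= 4 and q.me <= thr.me_max:
                    res_flags.append(
                        f"{label}: CN {q.cn:.1f} above {thr.cn_max} accepted with "
                        f"{q.n_markers} stable markers"
                    )
                else:
                    res_reasons.append(f"{label}: CN {q.cn:.1f} above {thr.cn_max}")
        if res_reasons:
            reasons[res.followup_exam_id] = res_reasons
        else:
            concise.append(res)
            if res_flags:
                flags[res.followup_exam_id] = res_flags
    return GateReport(concise=concise, complete=complete, reasons=reasons, flags=flags)


def _components_frame(
    results: Sequence[MigrationResult] | Sequence[Mapping[str, float]],
) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r, MigrationResult):
            rows.append(r.components())
        else:
            rows.append({k: r[k] for k in OUTCOME_COLUMNS if k in r})
    return pd.DataFrame(rows)


def double_exam_stats(
    pairs: Sequence[MigrationResult],
    group_labels: Sequence[str] | None = None,
    n_study_patients: int | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Bias and precision of zero-motion (double-examination) migrations.

    Each element of ``pairs`` is the migration computed between the two
    same-day examinations of one patient; since true motion is zero, the
    per-outcome mean is the bias and the sample standard deviation (n−1
    denominator) is the precision. Returns a tidy table with columns
    ``group, outcome, n, mean, sd, unit``.

    When ``n_study_patients`` is given, the fraction of study patients
    with a double examination is checked against the recommended minimum
    (25%) and recorded in the frame's ``attrs``.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    if len(pairs) == 0:
        raise ValueError("double-examination statistics require at least one pair")
    groups = list(group_labels) if group_labels is not None else ["all"] * len(pairs)
    if len(groups) != len(pairs):
        raise ValueError("group_labels must match pairs in length")
    frame = _components_frame(pairs)
    frame["group"] = groups
    rows = []
    warnings: list[str] = []
    for group, sub in frame.groupby("group", sort=True):
        for outcome in OUTCOME_COLUMNS:
            vals = sub[outcome].to_numpy(dtype=float)
            n = len(vals)
            sd = float(np.std(vals, ddof=1)) if n >= 2 else float("nan")
            if n < 2:
                warnings.append(f"group {group!r}: single pair, SD not estimable")
            rows.append({
                "group": group,
                "outcome": outcome,
                "n": n,
                "mean": float(np.mean(vals)),
                "sd": sd,
                "unit": "deg" if outcome in ("rx", "ry", "rz", "tr") else "mm",
            })
    table = pd.DataFrame(rows)
    table.attrs["warnings"] = warnings
    if n_study_patients is not None and n_study_patients > 0:
        fraction = len(pairs) / n_study_patients
        table.attrs["double_exam_fraction"] = fraction
        table.attrs["double_exam_fraction_ok"] = fraction >= thr.min_double_fraction
        if fraction < thr.min_double_fraction:
            table.attrs["warnings"] = warnings + [
                f"double-examination fraction {fraction:.2f} below recommended "
                f"minimum {thr.min_double_fraction}"
            ]
    return table


def accuracy_vs_gold(
    measured: Sequence[MigrationResult] | Sequence[Mapping[str, float]],
    truth: Sequence[Mapping[str, float]],
    pair_ids: Sequence[object] | None = None,
) -> pd.DataFrame:
    """Trueness and precision of measurements against a gold standard.

    ``measured`` and ``truth`` are paired by position (or by ``pair_ids``
    when given). For the signed components the signed difference
    (measured − truth) is summarized; for the unsigned metrics (TT, TR,
    MTPM) the difference of the unsigned values is used. Trueness is the
    mean difference (bias), precision the sample SD (random error).
    """
    if len(measured) != len(truth):
        raise ValueError("measured and truth must be paired (equal length)")
    if len(measured) == 0:
        raise ValueError("accuracy computation requires at least one pair")
    mf = _components_frame(measured)
    tf = _components_frame(list(truth))
    rows = []
    for outcome in OUTCOME_COLUMNS:
        if outcome not in mf.columns or outcome not in tf.columns:
            continue
        diff = mf[outcome].to_numpy(dtype=float) - tf[outcome].to_numpy(dtype=float)
        rows.append({
            "outcome": outcome,
            "kind": "signed" if outcome in SIGNED_OUTCOMES else "unsigned",
            "n": len(diff),
            "bias": float(np.mean(diff)),
            "sd": float(np.std(diff, ddof=1)) if len(diff) >= 2 else float("nan"),
            "unit": "deg" if outcome in ("rx", "ry", "rz", "tr") else "mm",
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two methods: bias, SD and limits of agreement."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray
    differences: np.ndarray


def bland_altman(method_a: Sequence[float], method_b: Sequence[float]) -> BlandAltmanResult:
    """Bland-Altman comparison of two paired measurement methods.

    Differences (A − B) are summarized by their mean (bias) and SD; the
    95% limits of agreement are bias ± 1.96·SD. The per-pair means and
    differences are returned for plotting.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("methods must be paired 1-D sequences")
    if len(a) < 3:
        raise ValueError("Bland-Altman comparison requires at least 3 pairs")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=len(a),
        means=(a + b) / 2.0,
        differences=diff,
    )


@dataclass(frozen=True)
class WindowFinding:
    """Scheduling finding for one examination."""

    exam_id: str
    days_since_surgery: float
    assigned_timepoint_days: float | None
    status: str  # "in_window" | "out_of_window" | "late_baseline"
    message: str


def followup_window_check(
    exams: Sequence[tuple[str, float]],
    protocol_timepoints_days: Sequence[float],
    baseline_days: float | None = None,
    thresholds: QCThresholds | None = None,
) -> list[WindowFinding]:
    """Check examination timing against the protocol windows.

    Each exam ``(exam_id, days_since_surgery)`` is assigned to the
    nearest protocol timepoint; exams outside ±2 weeks (timepoints before
    12 months) or ±10% (12 months and later) are flagged. A baseline
    acquired more than 2 weeks postoperatively is flagged as a
    comparability limitation.
    """
    thr = thresholds if thresholds is not None else QCThresholds()
    tps = sorted(float(t) for t in protocol_timepoints_days)
    if not tps:
        raise ValueError("protocol timepoints must be nonempty")
    findings: list[WindowFinding] = []
    if baseline_days is not None and baseline_days > thr.baseline_max_days:
        findings.append(WindowFinding(
            exam_id="baseline",
            days_since_surgery=float(baseline_days),
            assigned_timepoint_days=None,
            status="late_baseline",
            message=(
                f"baseline at day {baseline_days:g} exceeds {thr.baseline_max_days:g} days — "
                "comparability with literature migration values is limited"
            ),
        ))
    for exam_id, days in exams:
        target = min(tps, key=lambda t: abs(t - days))
        half_width = (
            thr.window_before_12m_days if target < 365.0
            else thr.window_from_12m_fraction * target
        )
        if abs(days - target) <= half_width:
            findings.append(WindowFinding(
                exam_id, float(days), target, "in_window",
                f"day {days:g} within {target:g} ± {half_width:g}",
            ))
        else:
            findings.append(WindowFinding(
                exam_id, float(days), target, "out_of_window",
                f"day {days:g} outside {target:g} ± {half_width:g}",
            ))
    return findings


def sample_size(
    delta: float,
    sd: float,
    alpha: float = 0.05,
    power: float = 0.80,
    dropout_fraction: float = 0.0,
) -> int:
    """Patients per group for a two-group comparison of mean migration.

    Normal-approximation formula n = 2·(z_{1−α/2} + z_{1−β})²·sd²/Δ²,
    rounded up, then inflated by 1/(1 − dropout_fraction) to compensate
    for expected dropouts (including RSA technical failures).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if sd <= 0:
        raise ValueError("sd must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if not (0 <= dropout_fraction < 1):
        raise ValueError("dropout_fraction must be in [0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = 2.0 * (z_a + z_b) ** 2 * sd**2 / delta**2
    n = math.ceil(n - 1e-12)
    if dropout_fraction > 0:
        n = math.ceil(n / (1.0 - dropout_fraction) - 1e-12)
    return int(n)


def posterior_revision_risk(
    prior: float,
    sensitivity: float,
    specificity: float,
    classified_positive: bool,
) -> float:
    """Post-test probability of revision given a migration classification.

    Bayes update in odds form: the prior odds are multiplied by the
    likelihood ratio of the observed classification — LR+ = sens/(1−spec)
    for a positive (continuous-migration) call, LR− = (1−sens)/spec for a
    negative one. With an uninformative test (LR = 1) the posterior
    equals the prior.
    """
    if not (0 <= prior <= 1):
        raise ValueError("prior must be a probability")
    if not (0 < sensitivity < 1) and sensitivity not in (0.0, 1.0):
        raise ValueError("sensitivity must be in [0, 1]")
    if not (0 <= specificity <= 1):
        raise ValueError("specificity must be in [0, 1]")
    if prior in (0.0, 1.0):
        return float(prior)
    if classified_positive:
        if specificity == 1.0:
            return 1.0  # degenerate: a positive call from a perfectly specific test
        lr = sensitivity / (1.0 - specificity)
    else:
        if specificity == 0.0:
            raise ValueError("specificity 0 with a negative call is undefined")
        lr = (1.0 - sensitivity) / specificity
    odds = prior / (1.0 - prior) * lr
    return float(odds / (1.0 + odds))


def classify_migration(
    second_year_interval: MigrationResult | None,
    threshold: float,
    outcome: str = "mtpm",
) -> str:
    """Classify second-year migration as ``continuous`` or ``stable``.

    The chosen unsigned outcome (MTPM or TT) of the 12-to-24-month
    interval migration is compared against a user-supplied threshold (the
    guideline prescribes the mechanism but no universal threshold value).
    Missing interval data yields ``indeterminate``.
    """
    if outcome not in ("mtpm", "tt"):
        raise ValueError("classification outcome must be 'mtpm' or 'tt'")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if second_year_interval is None:
        return "indeterminate"
    value = getattr(second_year_interval, outcome)
    return "continuous" if value > threshold else "stable"
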