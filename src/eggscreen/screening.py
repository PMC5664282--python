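"""Sample screening: identification, positivity, and compliance calls.

A study sample is *identified* for an analyte when both monitored MRM
transitions show S/N > 3, the major transition elutes at the expected
retention time, and the minor/major response ratio matches the reference
relative ion intensity within a tiered tolerance.  An identified sample is
*positive* when its major-transition response reaches the validated
cut-off factor Fc.  Positive samples are classified semiquantitatively as
compliant or noncompliant by comparing the major-transition response with
the mean response of the batch positive control — a sample spiked at 0.75x
the validation level — so that any sample reading above the control is
suspect of exceeding the permitted level and is routed to confirmation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .panel import AnalytePanel, TransitionRank
from .validation import (
    RT_TOLERANCE_DEFAULT,
    SN_THRESHOLD,
    ValidationResult,
    _snr,
)


class IncompleteSampleError(ValueError):
    """Sample records lack a required transition."""


class UnvalidatedAnalyteError(ValueError):
    """No validation result available for the analyte's transitions."""


class BatchControlError(ValueError):
    """No usable positive-control records for the batch."""


class Compliance(str, enum.Enum):
    compliant = "compliant"
    noncompliant = "noncompliant"
    not_detected = "not_detected"


#: Ion-ratio tolerance tiers: (reference relative intensity floor, relative
#: tolerance).  The permitted deviation of the measured minor/major ratio
#: from the reference widens as the reference intensity falls, following
#: the usual screening identification-criteria convention.
RATIO_TOLERANCE_TIERS: tuple[tuple[float, float], ...] = (
    (50.0, 0.20),
    (20.0, 0.25),
    (10.0, 0.30),
    (0.0, 0.50),
)


def ion_ratio_tolerance(
    reference_relative_intensity: float,
    tiers: Sequence[tuple[float, float]] = RATIO_TOLERANCE_TIERS,
) -> float:
    """Relative tolerance on the ion ratio for a given reference intensity."""
    if reference_relative_intensity < 0:
        raise ValueError("reference relative intensity must be >= 0")
    for floor, tol in tiers:
        if reference_relative_intensity > floor:
            return tol
    return tiers[-1][1]


@dataclass(frozen=True)
class TransitionReading:
    response: float
    noise: float
    observed_rt: float

    @property
    def snr(self) -> float:
        return _snr(self.response, self.noise)


@dataclass(frozen=True)
class IdentificationOutcome:
    identified: bool
    sn_ok: bool
    rt_ok: bool
    ion_ratio_ok: bool
    measured_ratio_pct: float | None
    readings: Mapping[str, TransitionReading]


@dataclass(frozen=True)
class ScreeningCall:
    """Identification + compliance decision for one sample/analyte."""

    sample_id: str
    analyte: str
    identified: bool
    positive: bool
    compliance: Compliance
    ion_ratio_ok: bool
    rt_ok: bool
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compliance is Compliance.noncompliant and not (self.identified and self.positive):
            raise ValueError("a noncompliant call requires an identified, positive sample")
        if self.compliance is Compliance.not_detected and self.identified:
            raise ValueError("an identified sample cannot be not_detected")


def _readings(sample_records: pd.DataFrame, analyte: str) -> dict[str, TransitionReading]:
    sub = sample_records[sample_records["analyte"] == analyte]
    out: dict[str, TransitionReading] = {}
    for rank in (TransitionRank.major, TransitionRank.minor1):
        rows = sub[sub["transition_rank"] == rank.value]
        if rows.empty:
            raise IncompleteSampleError(
                f"sample records lack the {rank.value} transition of {analyte!r}"
            )
        # Replicate injections of the same sample are averaged.
        out[rank.value] = TransitionReading(
            response=float(rows["response"].mean()),
            noise=float(rows["noise"].mean()),
            observed_rt=float(rows["observed_rt"].mean()),
        )
    return out


def identify(
    sample_records: pd.DataFrame,
    panel: AnalytePanel,
    analyte: str | None = None,
    rt_tolerance: float = RT_TOLERANCE_DEFAULT,
    ratio_tolerances: Sequence[tuple[float, float]] = RATIO_TOLERANCE_TIERS,
) -> IdentificationOutcome:
    """Two-transition identification of one analyte in one sample.

    Requires S/N > 3 on both transitions, the major transition's retention
    time inside the relative window, and — when the panel provides a
    reference relative intensity — the measured minor/major ratio within
    the tiered tolerance of that reference.
    """
    if analyte is None:
        names = sample_records["analyte"].unique()
        if len(names) != 1:
            raise ValueError("records cover several analytes; pass `analyte` explicitly")
        analyte = str(names[0])
    spec = panel.get(analyte)
    readings = _readings(sample_records, analyte)
    major, minor = readings["major"], readings["minor1"]

    sn_ok = major.snr > SN_THRESHOLD and minor.snr > SN_THRESHOLD

    window = rt_tolerance * spec.major.expected_rt
    rt_ok = abs(major.observed_rt - spec.major.expected_rt) <= window

    ratio_pct: float | None = None
    ref = spec.minor1.reference_relative_intensity
    if major.response > 0:
        ratio_pct = 100.0 * minor.response / major.response
    if ref is None:
        ion_ratio_ok = True
    elif ratio_pct is None:
        ion_ratio_ok = False
    else:
        tol = ion_ratio_tolerance(ref, ratio_tolerances)
        ion_ratio_ok = abs(ratio_pct - ref) <= tol * ref

    return IdentificationOutcome(
        identified=sn_ok and rt_ok and ion_ratio_ok,
        sn_ok=sn_ok,
        rt_ok=rt_ok,
        ion_ratio_ok=ion_ratio_ok,
        measured_ratio_pct=ratio_pct,
        readings=readings,
    )


def screen(
    sample_records: pd.DataFrame,
    validation: Mapping[TransitionRank, ValidationResult],
    panel: AnalytePanel,
    analyte: str | None = None,
    rt_tolerance: float = RT_TOLERANCE_DEFAULT,
) -> tuple[bool, IdentificationOutcome]:
    """Positivity call: identified and major response at or above Fc."""
    outcome = identify(sample_records, panel, analyte=analyte, rt_tolerance=rt_tolerance)
    major_val = validation.get(TransitionRank.major)
    if major_val is None:
        raise UnvalidatedAnalyteError("no validation result for the major transition")
    positive = outcome.identified and outcome.readings["major"].response >= major_val.fc
    return positive, outcome


def control_mean_response(
    positive_control_records: pd.DataFrame, analyte: str
) -> float:
    """Mean major-transition response of the batch positive control."""
    rows = positive_control_records[
        (positive_control_records["analyte"] == analyte)
        & (positive_control_records["transition_rank"] == TransitionRank.major.value)
    ]
    if rows.empty:
        raise BatchControlError(f"no positive-control records for {analyte!r}")
    return float(rows["response"].mean())


def classify_compliance(
    sample_records: pd.DataFrame,
    positive_control_records: pd.DataFrame,
    panel: AnalytePanel,
    analyte: str | None = None,
    validation: Mapping[TransitionRank, ValidationResult] | None = None,
    control_level: float | None = None,
    rt_tolerance: float = RT_TOLERANCE_DEFAULT,
) -> ScreeningCall:
    """Compliant / noncompliant / not-detected call for one sample.

    ``noncompliant`` requires an identified, positive sample whose
    major-transition response is *strictly* greater than the mean
    positive-control response (the control sits below the permitted level,
    so a sample at exactly the control response is still compliant).
    When validation results are supplied, positivity additionally requires
    the response to reach Fc; otherwise identification alone gates it.
    ``control_level`` (ug/kg), when given, yields a semiquantitative
    concentration estimate in ``details`` — informative only.
    """
    if analyte is None:
        names = sample_records["analyte"].unique()
        if len(names) != 1:
            raise ValueError("records cover several analytes; pass `analyte` explicitly")
        analyte = str(names[0])

    if validation is not None:
        positive, outcome = screen(
            sample_records, validation, panel, analyte=analyte, rt_tolerance=rt_tolerance
        )
    else:
        outcome = identify(sample_records, panel, analyte=analyte, rt_tolerance=rt_tolerance)
        positive = outcome.identified

    control_mean = control_mean_response(positive_control_records, analyte)
    major_resp = outcome.readings["major"].response

    if not outcome.identified:
        compliance = Compliance.not_detected
    elif positive and major_resp > control_mean:
        compliance = Compliance.noncompliant
    else:
        compliance = Compliance.compliant

    details: dict = {
        "major_response": major_resp,
        "major_snr": outcome.readings["major"].snr,
        "minor_response": outcome.readings["minor1"].response,
        "minor_snr": outcome.readings["minor1"].snr,
        "control_mean_response": control_mean,
        "measured_ratio_pct": outcome.measured_ratio_pct,
    }
    if control_level is not None and control_mean > 0:
        details["estimated_concentration"] = control_level * major_resp / control_mean

    sample_ids = sample_records.loc[sample_records["analyte"] == analyte, "sample_id"].unique()
    sample_id = str(sample_ids[0]) if len(sample_ids) == 1 else ",".join(map(str, sample_ids))

    return ScreeningCall(
        sample_id=sample_id,
        analyte=analyte,
        identified=outcome.identified,
        positive=positive,
        compliance=compliance,
        ion_ratio_ok=outcome.ion_ratio_ok,
        rt_ok=outcome.rt_ok,
        details=details,
    )


def compliance_timeline(
    daily_calls: Mapping[int, ScreeningCall | Compliance],
    treatment_end_day: int,
) -> int:
    """Days after the end of treatment with a noncompliant call.

    Returns the largest ``d >= 1`` such that the call on day
    ``treatment_end_day + d`` is noncompliant, or 0 when every
    post-treatment day is compliant or not detected.
    """
    days = sorted(daily_calls)
    if days and not (days[0] <= treatment_end_day <= days[-1]):
        raise ValueError("treatment_end_day outside the observed day range")
    last = 0
    for day in days:
        if day <= treatment_end_day:
            continue
        call = daily_calls[day]
        compliance = call.compliance if isinstance(call, ScreeningCall) else Compliance(call)
        if compliance is Compliance.noncompliant:
            last = day - treatment_end_day
    return last


@dataclass(frozen=True)
class StudyCall:
    """One screening call with its study metadata (group, collection day)."""

    group: str
    day: int
    call: ScreeningCall


def screen_study(
    records: pd.DataFrame,
    manifest: pd.DataFrame,
    panel: AnalytePanel,
    rt_tolerance: float = RT_TOLERANCE_DEFAULT,
    control_levels: Mapping[str, float] | None = None,
) -> list[StudyCall]:
    """Classify every study sample of a batch-manifested response table.

    Each sample is compared against the positive-control records of its own
    day (batch).  ``control_levels`` maps analyte to the control's spike
    concentration and enables the semiquantitative estimate in the call
    details.
    """
    study_ids = set(manifest.loc[manifest["role"] == "study", "sample_id"])
    pc_ids = set(manifest.loc[manifest["role"] == "positive_control", "sample_id"])
    if not pc_ids:
        raise BatchControlError("batch manifest lists no positive-control samples")
    day_of = dict(zip(manifest["sample_id"], manifest["day"]))
    group_of = dict(zip(manifest["sample_id"], manifest["group"]))
    pc_records = records[records["sample_id"].isin(pc_ids)]

    out: list[StudyCall] = []
    for sample_id, sub in records[records["sample_id"].isin(study_ids)].groupby("sample_id"):
        day = int(day_of[sample_id])
        pc_day = pc_records[pc_records["day"] == day]
        if pc_day.empty:
            raise BatchControlError(f"no positive-control records for day {day}")
        for analyte in sub["analyte"].unique():
            call = classify_compliance(
                sub[sub["analyte"] == analyte],
                pc_day,
                panel,
                analyte=analyte,
                control_level=(control_levels or {}).get(analyte),
                rt_tolerance=rt_tolerance,
            )
            out.append(StudyCall(group=str(group_of[sample_id]), day=day, call=call))
    return out


def group_timelines(
    study_calls: Sequence[StudyCall], treatment_end_day: int
) -> dict[tuple[str, str], int]:
    """Post-treatment noncompliance duration per (group, analyte)."""
    out: dict[tuple[str, str], int] = {}
    for group, analyte in sorted({(sc.group, sc.call.analyte) for sc in study_calls}):
        sel = [sc for sc in study_calls if sc.group == group and sc.call.analyte == analyte]
        daily = aggregate_daily([sc.call for sc in sel], [sc.day for sc in sel])
        out[(group, analyte)] = compliance_timeline(daily, treatment_end_day)
    return out


def aggregate_daily(calls: Sequence[ScreeningCall], days: Sequence[int]) -> dict[int, Compliance]:
    """Collapse replicate calls to one call per day.

    A day is noncompliant if any replicate is; detected-compliant beats
    not-detected.  Conservative in the screening direction.
    """
    if len(calls) != len(days):
        raise ValueError("calls and days must align")
    out: dict[int, Compliance] = {}
    order = {Compliance.not_detected: 0, Compliance.compliant: 1, Compliance.noncompliant: 2}
    for call, day in zip(calls, days):
        cur = out.get(day)
        if cur is None or order[call.compliance] > order[cur]:
            out[day] = call.compliance
    return out
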