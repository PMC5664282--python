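"""Validation statistics for a qualitative/semiquantitative screening method.

The screening-oriented validation scheme replaces the classical
trueness/precision/linearity battery with a small set of quantities
computed from many blank and spiked samples at the level of interest:

* **T-value** ``T = B + 1.64 * SD_B`` — the positivity threshold implied by
  blank-matrix noise, from the mean ``B`` and standard deviation ``SD_B``
  of the noise recorded in (by design) 20 blank samples.
* **Cut-off factor** ``Fc = M_an - 1.64 * SD_an`` — the operational
  detection cut-off, from the mean and standard deviation of the responses
  of spiked samples at the validation level (by design 20 replicates on
  each of 3 days, pooled to n = 60).
* **LOD** ``LOD = 3 * B * C / M_an`` — the concentration equivalent of
  three times the mean blank noise, scaled by the spike level ``C`` and
  the mean spiked response ``M_an``.
* **CCbeta verdict** — the detection capability is *below* the level of
  interest exactly when ``Fc > T``: then fewer than ~5% of truly
  contaminated samples fall under the positivity threshold (1.64 is the
  one-sided normal 95% quantile, to the printed precision of the method).
  ``Fc <= T`` means the method cannot see the level of interest with a
  <=5% false-negative rate, so CCbeta is *above* it.
* **Sensitivity** — the percent of spiked samples whose response reaches
  ``Fc`` ("positive agreement").
* **Selectivity** — blank samples must show no interfering signal
  (S/N > 3) in the retention window of any monitored transition.

Standard deviations use the n-1 (sample) denominator: the 20/60 replicates
are a sample from the blank/spiked population.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import check_response_frame
from .panel import AnalytePanel, TransitionRank, validation_level

#: One-sided normal 95% quantile as used in both threshold equations.
K_DEFAULT = 1.64
#: Relative retention-time window (fraction of the expected RT) within
#: which a signal is attributed to the analyte.
RT_TOLERANCE_DEFAULT = 0.025
#: Minimum signal-to-noise ratio for a transition to count as a signal.
SN_THRESHOLD = 3.0


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedLODError(ValueError):
    """LOD is undefined (non-positive mean spiked response)."""


class CoverageError(ValueError):
    """The response table does not cover the requested analytes/transitions."""


class CCBetaVerdict(str, enum.Enum):
    below_level = "below_level"
    above_level = "above_level"


def t_value(blank_noises: Sequence[float], k: float = K_DEFAULT) -> float:
    """Positivity threshold ``B + k * SD_B`` from blank-sample noise values."""
    x = np.asarray(blank_noises, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"t_value needs >= 2 blank noises, got {x.size}")
    if k <= 0:
        raise ValueError("k must be positive")
    return float(x.mean() + k * x.std(ddof=1))


def cutoff_factor(spiked_responses: Sequence[float], k: float = K_DEFAULT) -> float:
    """Detection cut-off ``M_an - k * SD_an`` from spiked-sample responses.

    A negative result is returned as-is; callers flag it as a low-signal
    condition rather than clamping, which would silently bias sensitivity.
    """
    x = np.asarray(spiked_responses, dtype=float)
    if x.size < 2:
        raise InsufficientDataError(f"cutoff_factor needs >= 2 responses, got {x.size}")
    if k <= 0:
        raise ValueError("k must be positive")
    return float(x.mean() - k * x.std(ddof=1))


def lod(mean_noise: float, spike_concentration: float, mean_spiked_response: float) -> float:
    """Limit of detection ``3 * B * C / M_an`` in concentration units."""
    if mean_spiked_response <= 0:
        raise UndefinedLODError(
            f"LOD undefined for mean spiked response {mean_spiked_response!r}"
        )
    if spike_concentration <= 0:
        raise ValueError("spike concentration must be positive")
    if mean_noise < 0:
        raise ValueError("mean noise must be non-negative")
    return 3.0 * mean_noise * spike_concentration / mean_spiked_response


def ccbeta_verdict(fc: float, t: float) -> CCBetaVerdict:
    """Detection-capability verdict: ``below_level`` iff ``Fc > T``.

    A tie resolves to ``above_level`` — the conservative call for consumer
    protection, since at ``Fc == T`` the <=5% false-negative guarantee is
    not strictly met.
    """
    if not (math.isfinite(fc) and math.isfinite(t)):
        raise ValueError("Fc and T must be finite")
    return CCBetaVerdict.below_level if fc > t else CCBetaVerdict.above_level


def sensitivity(spiked_responses: Sequence[float], fc: float) -> float:
    """Percent of spiked samples at or above the cut-off (positive agreement).

    A response exactly equal to ``Fc`` counts as detected.
    """
    x = np.asarray(spiked_responses, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("sensitivity needs >= 1 spiked response")
    return 100.0 * float(np.count_nonzero(x >= fc)) / x.size


@dataclass(frozen=True)
class InterferenceFlag:
    """A blank-matrix signal (S/N > 3) inside an analyte's retention window."""

    analyte: str
    transition_rank: TransitionRank
    sample_id: str
    observed_rt: float
    snr: float


def _snr(response: float, noise: float) -> float:
    if noise > 0:
        return response / noise
    return math.inf if response > 0 else 0.0


def selectivity_check(
    blank_records: pd.DataFrame,
    panel: AnalytePanel,
    rt_tolerance: float = RT_TOLERANCE_DEFAULT,
) -> list[InterferenceFlag]:
    """Flag blank signals co-eluting with any monitored transition.

    Every blank record attributed to an (analyte, transition) whose observed
    retention time falls within ``rt_tolerance * expected_rt`` of the
    expected RT and whose S/N exceeds 3 is reported as an interference.
    """
    check_response_frame(blank_records, "blank records")
    if not (blank_records["sample_kind"] == "blank").all():
        raise ValueError("selectivity_check expects blank records only")
    flags: list[InterferenceFlag] = []
    for row in blank_records.itertuples(index=False):
        if row.analyte not in panel:
            continue
        analyte = panel.get(row.analyte)
        try:
            spec = analyte.transition(row.transition_rank)
        except KeyError:
            continue
        window = rt_tolerance * spec.expected_rt
        if abs(row.observed_rt - spec.expected_rt) > window:
            continue
        snr = _snr(row.response, row.noise)
        if snr > SN_THRESHOLD:
            flags.append(
                InterferenceFlag(
                    analyte=row.analyte,
                    transition_rank=TransitionRank(row.transition_rank),
                    sample_id=str(row.sample_id),
                    observed_rt=float(row.observed_rt),
                    snr=float(snr),
                )
            )
    return flags


@dataclass(frozen=True)
class ValidationDesign:
    """Replication scheme and thresholds of a validation run."""

    n_blanks: int = 20
    n_per_day: int = 20
    n_days: int = 3
    k: float = K_DEFAULT
    rt_tolerance: float = RT_TOLERANCE_DEFAULT

    @property
    def n_spiked(self) -> int:
        return self.n_per_day * self.n_days


@dataclass(frozen=True)
class ValidationResult:
    """Per-analyte, per-transition validation outcome (one report row)."""

    analyte: str
    transition_rank: TransitionRank
    t_value: float
    fc: float
    lod: float
    ccbeta_verdict: CCBetaVerdict
    sensitivity_pct: float
    n_blanks: int
    n_spiked_fc: int
    n_spiked_sens: int
    flags: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return self.ccbeta_verdict is CCBetaVerdict.below_level


def validate_panel(
    records: pd.DataFrame,
    panel: AnalytePanel,
    design: ValidationDesign = ValidationDesign(),
    analytes: Iterable[str] | None = None,
) -> list[ValidationResult]:
    """Run the full validation calculus over a blank + spiked response table.

    One :class:`ValidationResult` is produced per (analyte, transition) for
    the major and first minor transitions of every analyte present in the
    table (or the explicit ``analytes`` subset).  The cut-off factor pools
    the spiked responses of all days; the LOD's mean spiked response and the
    sensitivity comparison use the first day's replicates, mirroring the
    20-sample design of those two quantities.
    """
    check_response_frame(records)
    if analytes is None:
        analyte_names = [n for n in panel.names if n in set(records["analyte"])]
    else:
        analyte_names = list(analytes)
    if not analyte_names:
        raise CoverageError("response table covers no panel analyte")

    gaps: list[str] = []
    results: list[ValidationResult] = []
    ranks = (TransitionRank.major, TransitionRank.minor1)

    blanks_all = records[records["sample_kind"] == "blank"]
    spiked_all = records[records["sample_kind"] == "spiked"]
    interferences = selectivity_check(blanks_all, panel, design.rt_tolerance) if len(blanks_all) else []

    for name in analyte_names:
        analyte = panel.get(name)
        level = validation_level(analyte, panel)
        for rank in ranks:
            blanks = blanks_all[
                (blanks_all["analyte"] == name) & (blanks_all["transition_rank"] == rank.value)
            ]
            spiked = spiked_all[
                (spiked_all["analyte"] == name) & (spiked_all["transition_rank"] == rank.value)
            ]
            if len(blanks) < design.n_blanks:
                gaps.append(f"{name}/{rank.value}: {len(blanks)}/{design.n_blanks} blanks")
                continue
            if len(spiked) < design.n_spiked:
                gaps.append(f"{name}/{rank.value}: {len(spiked)}/{design.n_spiked} spiked")
                continue

            t = t_value(blanks["noise"].to_numpy(), design.k)
            fc = cutoff_factor(spiked["response"].to_numpy(), design.k)
            first_day = spiked[spiked["day"] == spiked["day"].min()]
            sens = sensitivity(first_day["response"].to_numpy(), fc)
            mean_noise = float(blanks["noise"].mean())
            mean_resp = float(first_day["response"].mean())
            lod_val = lod(mean_noise, level, mean_resp)

            flags: list[str] = []
            if fc < 0:
                flags.append("negative_fc")
            for itf in interferences:
                if itf.analyte == name and itf.transition_rank is rank:
                    flags.append(f"interference:{itf.sample_id}")

            results.append(
                ValidationResult(
                    analyte=name,
                    transition_rank=rank,
                    t_value=t,
                    fc=fc,
                    lod=lod_val,
                    ccbeta_verdict=ccbeta_verdict(fc, t),
                    sensitivity_pct=sens,
                    n_blanks=len(blanks),
                    n_spiked_fc=len(spiked),
                    n_spiked_sens=len(first_day),
                    flags=tuple(flags),
                )
            )

    if gaps:
        raise CoverageError("incomplete validation coverage: " + "; ".join(gaps))
    return results


def results_by_transition(
    results: Iterable[ValidationResult],
) -> dict[str, dict[TransitionRank, ValidationResult]]:
    """Index validation results as ``{analyte: {rank: result}}``."""
    out: dict[str, dict[TransitionRank, ValidationResult]] = {}
    for r in results:
        out.setdefault(r.analyte, {})[r.transition_rank] = r
    return out
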