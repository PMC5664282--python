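"""Synthetic data generators: validation runs and egg-residue depletion.

Two generators stand in for the instrument and the animal study:

* :func:`simulate_validation` emulates the validation design — 20 blank
  samples plus 20 spiked replicates at the level of interest on each of 3
  days — as 0-truncated normal response/noise draws, with an optional
  shared day effect and an optional co-eluting interferent on one
  transition (the mechanism by which a blank-matrix peak inflates the
  T-value and sinks the CCbeta verdict).

* :func:`simulate_depletion` is a deliberately minimal linear
  two-compartment deposition model for residues in eggs.  Plasma follows
  first-order accumulation during dosing and exponential washout after;
  the albumen of an egg laid on day *t* reflects the previous day's plasma
  (albumen is deposited over a few hours from freshly secreted proteins),
  while its yolk integrates plasma over the preceding 10-day rapid-growth
  window with exponentially increasing deposition weights.  The packaged
  per-drug defaults are calibrated so the noise-free curves reproduce the
  observed post-treatment noncompliance durations of the feeding study;
  they are fixtures for the classifier contract, not pharmacokinetic
  estimates.

* :func:`study_fixture` converts depletion curves into the response-table
  + batch-manifest formats of the screening pipeline for a 6-replicate,
  16-day (pre-treatment day 0 + 5 dosing + 10 washout) two-group design,
  via a fixed linear response factor per drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .io import MANIFEST_COLUMNS, RESPONSE_COLUMNS
from .panel import (
    AnalytePanel,
    AnalyteSpec,
    TransitionRank,
    load_panel,
    positive_control_level,
)


class InterferentSpec(BaseModel):
    """A co-eluting matrix signal on one transition.

    In a blank the interferent peak is the only thing in the analyte's
    window, so its response is recorded as the blank's apparent signal;
    a fraction ``noise_fraction`` of it is picked up as window noise (and
    likewise inflates the window noise of spiked samples, whose analyte
    peak is integrated separately).  Through the blank-noise route the
    interferent inflates the T-value without raising the cut-off factor —
    the mechanism by which a co-eluting matrix compound sinks the
    detection-capability verdict of an otherwise sound transition.
    """

    model_config = ConfigDict(frozen=True)

    transition_rank: TransitionRank
    added_mean: float = Field(gt=0)
    added_sd: Optional[float] = Field(default=None, ge=0)
    noise_fraction: float = Field(default=0.25, gt=0, le=1.0)

    @property
    def sd(self) -> float:
        return self.added_sd if self.added_sd is not None else 0.05 * self.added_mean


class ValidationSimConfig(BaseModel):
    """Parameters of a simulated validation run for one analyte.

    Response units are arbitrary area counts; the defaults (spike mean 40x
    the noise mean) describe a comfortably detectable analyte at its
    validation level.
    """

    model_config = ConfigDict(frozen=True)

    n_blanks: int = Field(default=20, ge=1)
    n_per_day: int = Field(default=20, ge=1)
    n_days: int = Field(default=3, ge=1)
    noise_mean: float = Field(default=5.0, ge=0)
    noise_sd: float = Field(default=1.0, ge=0)
    spike_mean: float = Field(default=200.0, ge=0)
    spike_sd: float = Field(default=20.0, ge=0)
    day_effect_sd: float = Field(default=5.0, ge=0)
    interferent: Optional[InterferentSpec] = None
    seed: int = 0


def _trunc_normal(rng: np.random.Generator, mean, sd, size=None):
    return np.clip(rng.normal(mean, sd, size=size), 0.0, None)


def simulate_validation(
    config: ValidationSimConfig,
    panel: AnalytePanel,
    analyte: str | AnalyteSpec,
) -> pd.DataFrame:
    """Generate the blank + spiked response table of one validation run.

    Blanks carry a 0-truncated normal baseline recorded as both response
    and noise (S/N ~ 1).  Spiked samples draw their major-transition
    response around ``spike_mean`` plus a normal day offset shared within
    each day; minor-transition responses are scaled by the panel's
    reference relative intensity.  An interferent, when configured, adds
    its peak response to the blank trace and a fraction of it to the
    recorded window noise of blanks and spiked samples on the targeted
    transition.  Identical seeds give identical tables.
    """
    if isinstance(analyte, str):
        analyte = panel.get(analyte)
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    ranks = (TransitionRank.major, TransitionRank.minor1)
    scales = {
        TransitionRank.major: 1.0,
        TransitionRank.minor1: (analyte.minor1.reference_relative_intensity or 100.0) / 100.0,
    }

    def interferes(rank: TransitionRank) -> bool:
        return config.interferent is not None and config.interferent.transition_rank is rank

    for i in range(config.n_blanks):
        for rank in ranks:
            baseline = float(_trunc_normal(rng, config.noise_mean, config.noise_sd))
            response = noise = baseline
            if interferes(rank):
                extra = float(_trunc_normal(rng, config.interferent.added_mean, config.interferent.sd))
                response += extra
                noise += config.interferent.noise_fraction * extra
            rows.append(
                dict(
                    sample_id=f"blank-{i + 1:02d}",
                    day=1,
                    replicate=i + 1,
                    analyte=analyte.name,
                    transition_rank=rank.value,
                    response=response,
                    noise=noise,
                    observed_rt=analyte.transition(rank).expected_rt,
                    sample_kind="blank",
                )
            )

    for day in range(1, config.n_days + 1):
        day_offset = float(rng.normal(0.0, config.day_effect_sd)) if config.day_effect_sd > 0 else 0.0
        for rep in range(1, config.n_per_day + 1):
            for rank in ranks:
                s = scales[rank]
                response = float(
                    _trunc_normal(rng, (config.spike_mean + day_offset) * s, config.spike_sd * s)
                )
                noise = float(_trunc_normal(rng, config.noise_mean, config.noise_sd))
                if interferes(rank):
                    noise += config.interferent.noise_fraction * float(
                        _trunc_normal(rng, config.interferent.added_mean, config.interferent.sd)
                    )
                rows.append(
                    dict(
                        sample_id=f"spiked-d{day}-{rep:02d}",
                        day=day,
                        replicate=rep,
                        analyte=analyte.name,
                        transition_rank=rank.value,
                        response=response,
                        noise=noise,
                        observed_rt=analyte.transition(rank).expected_rt,
                        sample_kind="spiked",
                    )
                )

    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


class DepletionSimConfig(BaseModel):
    """Parameters of the egg-residue deposition model for one drug.

    ``absorption_fraction`` scales the per-dose plasma input (0 models a
    drug that never reaches circulation); ``elimination_rate`` is the
    first-order plasma washout constant (per day); the two partition
    coefficients convert plasma level to albumen/yolk concentration
    (ug/kg per plasma unit); ``yolk_growth_rate`` sets how steeply
    deposition weights rise across the 10-day yolk growth window — an
    effective constant that also absorbs drug-specific deposition
    kinetics; ``yolk_mass_fraction`` mixes the two compartments into the
    whole-egg concentration.
    """

    model_config = ConfigDict(frozen=True)

    drug: str
    dose_days: int = Field(default=5, ge=1)
    washout_days: int = Field(default=10, ge=0)
    absorption_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    elimination_rate: float = Field(default=0.5, ge=0)  # per day
    albumen_partition: float = Field(default=10.0, ge=0)
    yolk_partition: float = Field(default=100.0, ge=0)
    yolk_growth_rate: float = Field(default=0.35, ge=0)  # per day, 10-day window
    yolk_mass_fraction: float = Field(default=0.36, gt=0, lt=1)
    noise_cv: float = Field(default=0.0, ge=0)
    seed: int = 0


YOLK_WINDOW_DAYS = 10


@dataclass(frozen=True)
class DepletionSeries:
    """Per-day pooled-egg concentrations for one drug (day 0 = pre-treatment)."""

    drug: str
    days: np.ndarray
    concentration: np.ndarray  # ug/kg
    plasma: np.ndarray
    albumen: np.ndarray
    yolk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "day": self.days,
                "concentration": self.concentration,
                "albumen": self.albumen,
                "yolk": self.yolk,
            }
        )


def simulate_depletion(config: DepletionSimConfig) -> DepletionSeries:
    """Run the deposition model over dosing + washout days.

    Day 0 is the pre-treatment collection (all compartments zero); dosing
    spans days 1..dose_days.  With ``noise_cv`` > 0, each day's egg
    concentration is multiplied by a unit-mean lognormal factor.
    """
    n_days = config.dose_days + config.washout_days
    p = np.zeros(n_days + 1)
    kel = np.exp(-config.elimination_rate)
    for t in range(1, n_days + 1):
        dose = config.absorption_fraction if t <= config.dose_days else 0.0
        p[t] = p[t - 1] * kel + dose

    w = np.exp(config.yolk_growth_rate * np.arange(1, YOLK_WINDOW_DAYS + 1))
    w /= w.sum()

    albumen = np.zeros(n_days + 1)
    yolk = np.zeros(n_days + 1)
    for t in range(1, n_days + 1):
        albumen[t] = config.albumen_partition * p[t - 1]
        acc = 0.0
        for j in range(1, YOLK_WINDOW_DAYS + 1):
            idx = t - YOLK_WINDOW_DAYS - 1 + j
            if idx >= 0:
                acc += w[j - 1] * p[idx]
        yolk[t] = config.yolk_partition * acc

    egg = config.yolk_mass_fraction * yolk + (1 - config.yolk_mass_fraction) * albumen
    if config.noise_cv > 0:
        rng = np.random.default_rng(config.seed)
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        egg = egg * rng.lognormal(-(sigma**2) / 2.0, sigma, size=egg.shape)
    egg = np.clip(egg, 0.0, None)

    return DepletionSeries(
        drug=config.drug,
        days=np.arange(n_days + 1),
        concentration=egg,
        plasma=p,
        albumen=albumen,
        yolk=yolk,
    )


# Packaged per-drug defaults, calibrated so the noise-free egg curves
# reproduce the feeding study's post-treatment noncompliance durations
# (days above the positive-control level after dosing ends): enrofloxacin
# 9, its metabolite ciprofloxacin 6, doxycycline 4, lincomycin 1,
# oxytetracycline never, neomycin never absorbed.  See docs for the
# calibration rationale; these are fixtures, not PK estimates.
DEPLETION_DEFAULTS: dict[str, DepletionSimConfig] = {
    "neomycin": DepletionSimConfig(
        drug="neomycin",
        absorption_fraction=0.0,  # negligible gastrointestinal absorption
        elimination_rate=0.5,
        albumen_partition=10.0,
        yolk_partition=50.0,
    ),
    "enrofloxacin": DepletionSimConfig(
        drug="enrofloxacin",
        elimination_rate=0.60,
        albumen_partition=6.0,
        yolk_partition=144.0,  # fluoroquinolones deposit mainly in yolk
        yolk_growth_rate=0.35,
    ),
    "ciprofloxacin": DepletionSimConfig(
        drug="ciprofloxacin",
        absorption_fraction=0.5,  # formed as a metabolite of enrofloxacin
        elimination_rate=0.80,
        albumen_partition=12.0,
        yolk_partition=287.0,
        yolk_growth_rate=0.60,
    ),
    "lincomycin": DepletionSimConfig(
        drug="lincomycin",
        elimination_rate=0.85,
        albumen_partition=44.8,  # protein-bound: albumen-dominant, fast decline
        yolk_partition=1.35,
        yolk_growth_rate=0.35,
    ),
    "oxytetracycline": DepletionSimConfig(
        drug="oxytetracycline",
        elimination_rate=0.25,  # poorly absorbed: low, slowly declining levels
        albumen_partition=25.0,
        yolk_partition=74.8,
        yolk_growth_rate=0.20,
    ),
    "doxycycline": DepletionSimConfig(
        drug="doxycycline",
        elimination_rate=0.80,
        albumen_partition=250.0,  # lipophilic: high absorption, both compartments
        yolk_partition=1876.0,
        yolk_growth_rate=0.80,
    ),
}

#: Analytes emitted by each treatment-group fixture (enrofloxacin treatment
#: also produces its metabolite ciprofloxacin).
STUDY_ANALYTES: dict[str, tuple[str, ...]] = {
    "neomycin": ("neomycin",),
    "enrofloxacin": ("enrofloxacin", "ciprofloxacin"),
    "lincomycin": ("lincomycin",),
    "oxytetracycline": ("oxytetracycline",),
    "doxycycline": ("doxycycline",),
}

#: Replicate pooled-egg samples collected per group per day.
STUDY_REPLICATES = 6
#: Positive-control replicates measured per batch (day).
CONTROL_REPLICATES = 2
#: Baseline instrument noise (area units) of the fixture.
BASELINE_NOISE_MEAN = 2.0
BASELINE_NOISE_SD = 0.3
#: Linear response factor: the positive control reads ~1000 area units.
CONTROL_RESPONSE = 1000.0
#: Replicate-to-replicate coefficient of variation of pooled-egg samples.
STUDY_NOISE_CV = 0.05


def study_fixture(
    drug: str,
    panel: AnalytePanel | None = None,
    seed: int = 0,
    noise_cv: float = STUDY_NOISE_CV,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Response table + batch manifest for one treatment group and controls.

    Emits, for every day 0..15, ``STUDY_REPLICATES`` pooled-egg samples for
    the treated and untreated (control) groups and ``CONTROL_REPLICATES``
    positive-control samples spiked at 0.75x the validation level, for
    each analyte the treatment produces.  Concentrations come from the
    packaged depletion defaults (noise-free curve, then per-replicate
    unit-mean lognormal variation of ``noise_cv``); responses are a fixed
    linear factor per analyte plus baseline noise.
    """
    if drug not in STUDY_ANALYTES:
        raise KeyError(
            f"no packaged depletion defaults for {drug!r}; "
            f"known drugs: {sorted(STUDY_ANALYTES)}"
        )
    if panel is None:
        panel = load_panel()
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    manifest: list[dict] = []
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def lognoise() -> float:
        if sigma == 0.0:
            return 1.0
        return float(rng.lognormal(-(sigma**2) / 2.0, sigma))

    def emit_sample(sample_id, day, rep, analyte_name, conc, factor, kind):
        spec = panel.get(analyte_name)
        ref = (spec.minor1.reference_relative_intensity or 100.0) / 100.0
        for rank, scale in ((TransitionRank.major, 1.0), (TransitionRank.minor1, ref)):
            baseline = float(_trunc_normal(rng, BASELINE_NOISE_MEAN, BASELINE_NOISE_SD))
            signal = factor * conc * scale * (1.0 + rng.normal(0.0, 0.02))
            rows.append(
                dict(
                    sample_id=sample_id,
                    day=day,
                    replicate=rep,
                    analyte=analyte_name,
                    transition_rank=rank.value,
                    response=max(signal, 0.0) + baseline,
                    noise=baseline,
                    observed_rt=spec.transition(rank).expected_rt,
                    sample_kind=kind,
                )
            )

    analytes = STUDY_ANALYTES[drug]
    curves = {
        name: simulate_depletion(DEPLETION_DEFAULTS[name].model_copy(update={"noise_cv": 0.0}))
        for name in analytes
    }
    factors = {
        name: CONTROL_RESPONSE / positive_control_level(name, panel) for name in analytes
    }
    n_days = DEPLETION_DEFAULTS[drug].dose_days + DEPLETION_DEFAULTS[drug].washout_days

    for day in range(0, n_days + 1):
        for group in ("control", "treated"):
            for rep in range(1, STUDY_REPLICATES + 1):
                sample_id = f"{drug}-{group}-d{day:02d}-r{rep}"
                for name in analytes:
                    conc = float(curves[name].concentration[day]) if group == "treated" else 0.0
                    emit_sample(sample_id, day, rep, name, conc * lognoise(), factors[name], "study")
                manifest.append(
                    dict(sample_id=sample_id, day=day, group=group, role="study")
                )
        for rep in range(1, CONTROL_REPLICATES + 1):
            sample_id = f"{drug}-pc-d{day:02d}-r{rep}"
            for name in analytes:
                emit_sample(
                    sample_id, day, rep, name, positive_control_level(name, panel),
                    factors[name], "spiked",
                )
            manifest.append(
                dict(sample_id=sample_id, day=day, group="positive_control", role="positive_control")
            )

    records = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    manifest_df = pd.DataFrame(manifest, columns=MANIFEST_COLUMNS)
    return records, manifest_df
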