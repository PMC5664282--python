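"""Analyte panel definitions and level-of-interest rules.

The panel is the registry of screened antimicrobials: for each analyte it
stores the family, the monitored MRM transitions with their tuned MS/MS
parameters, the regulatory status, and — when one exists — the maximum
residue limit (MRL) in eggs.

Two derived concentrations drive everything downstream:

* the **validation level** (``C_val``) — the concentration at which the
  method is validated.  For an analyte with an established MRL this is the
  MRL itself, or ``0.75 x MRL`` when the MRL covers a combined residue
  definition (parent plus epimer/metabolite), so that the parent alone is
  screened with a safety margin.  Analytes that are banned or have no MRL
  in eggs are screened qualitatively at a fixed per-family level.
* the **positive-control level** — ``0.75 x C_val``, the spike level of the
  batch positive control against which study samples are classified as
  compliant or noncompliant.

Concentrations are ug/kg throughout.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class PanelConfigError(ValueError):
    """Raised when a panel file violates the panel contract."""


class Family(str, enum.Enum):
    tetracyclines = "tetracyclines"
    aminoglycosides = "aminoglycosides"
    quinolones = "quinolones"
    lincosamides = "lincosamides"
    beta_lactams = "beta_lactams"
    sulfonamides = "sulfonamides"
    macrolides = "macrolides"


class RegulatoryStatus(str, enum.Enum):
    mrl_established = "mrl_established"
    banned = "banned"
    not_established = "not_established"
    no_mrl_in_eggs = "no_mrl_in_eggs"


class TransitionRank(str, enum.Enum):
    major = "major"
    minor1 = "minor1"
    minor2 = "minor2"


class ExtractionRoute(str, enum.Enum):
    tca = "tca"
    acetonitrile = "acetonitrile"


class TransitionSpec(BaseModel):
    """One monitored MRM transition (precursor -> product ion pair).

    ``reference_relative_intensity`` is the expected response of this
    transition as a percent of the major transition's response; it is the
    reference for the ion-ratio identification criterion and is absent for
    the major transition itself.
    """

    model_config = ConfigDict(frozen=True)

    rank: TransitionRank
    precursor_mz: float = Field(gt=0)
    product_mz: float = Field(gt=0)
    declustering_potential: float  # V
    collision_energy: float  # eV
    expected_rt: float = Field(gt=0)  # minutes
    reference_relative_intensity: Optional[float] = Field(default=None, ge=0)
    reference_relative_intensity_sd: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "TransitionSpec":
        if not self.precursor_mz > self.product_mz:
            raise ValueError(
                f"precursor m/z {self.precursor_mz} must exceed product m/z {self.product_mz}"
            )
        if self.rank is TransitionRank.major and self.reference_relative_intensity is not None:
            raise ValueError("the major transition carries no reference relative intensity")
        return self


class AnalyteSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    family: Family
    transitions: tuple[TransitionSpec, ...] = Field(min_length=2)
    regulatory_status: RegulatoryStatus
    mrl: Optional[float] = Field(default=None, gt=0)
    combined_residue: bool = False
    extraction_route: ExtractionRoute
    # Explicit validation-level override for analytes whose screening level
    # follows neither the MRL rule nor the family default (e.g. doxycycline,
    # screened at the tetracycline level despite having no MRL of its own).
    level_override: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "AnalyteSpec":
        majors = [t for t in self.transitions if t.rank is TransitionRank.major]
        if len(majors) != 1:
            raise ValueError(f"analyte {self.name!r} must have exactly one major transition")
        ranks = [t.rank for t in self.transitions]
        if len(set(ranks)) != len(ranks):
            raise ValueError(f"analyte {self.name!r} has duplicate transition ranks")
        if self.regulatory_status is RegulatoryStatus.mrl_established:
            if self.mrl is None:
                raise ValueError(f"analyte {self.name!r} is mrl_established but has no MRL")
        elif self.mrl is not None:
            raise ValueError(
                f"analyte {self.name!r} ({self.regulatory_status.value}) must not carry an MRL"
            )
        return self

    def transition(self, rank: TransitionRank | str) -> TransitionSpec:
        rank = TransitionRank(rank)
        for t in self.transitions:
            if t.rank is rank:
                return t
        raise KeyError(f"analyte {self.name!r} has no {rank.value} transition")

    @property
    def major(self) -> TransitionSpec:
        return self.transition(TransitionRank.major)

    @property
    def minor1(self) -> TransitionSpec:
        return self.transition(TransitionRank.minor1)


class AnalytePanel(BaseModel):
    model_config = ConfigDict(frozen=True)

    analytes: tuple[AnalyteSpec, ...]
    qualitative_default_levels: dict[Family, float]

    @model_validator(mode="after")
    def _check(self) -> "AnalytePanel":
        names = [a.name for a in self.analytes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate analyte names in panel: {sorted(dupes)}")
        missing = {a.family for a in self.analytes} - set(self.qualitative_default_levels)
        if missing:
            raise ValueError(
                "families without a qualitative default level: "
                + ", ".join(sorted(f.value for f in missing))
            )
        return self

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self):
        return iter(self.analytes)

    def get(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(f"analyte {name!r} not in panel")

    def __contains__(self, name: object) -> bool:
        return any(a.name == name for a in self.analytes)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]


def _panel_from_mapping(doc: dict) -> AnalytePanel:
    try:
        return AnalytePanel.model_validate(doc)
    except Exception as exc:  # pydantic.ValidationError or ValueError
        raise PanelConfigError(str(exc)) from exc


def load_panel(path: str | Path | None = None) -> AnalytePanel:
    """Load a panel from a YAML file, or the packaged default panel.

    The packaged default covers the full 45-analyte, 7-family egg screening
    panel with its validated MRM parameters and regulatory levels.
    """
    if path is None:
        text = resources.files("eggscreen.data").joinpath("default_panel.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise PanelConfigError(f"panel file not found: {path}")
        text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise PanelConfigError("panel file must contain a mapping at top level")
    return _panel_from_mapping(doc)


def save_panel(panel: AnalytePanel, path: str | Path) -> None:
    """Write a panel back to YAML; ``load_panel`` round-trips it exactly."""
    doc = panel.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def validation_level(analyte: AnalyteSpec | str, panel: AnalytePanel) -> float:
    """Concentration (ug/kg) at which the analyte is validated (``C_val``).

    MRL established and combined residue definition -> 0.75 x MRL;
    MRL established otherwise -> MRL; an explicit per-analyte override wins;
    otherwise the family's qualitative screening level.
    """
    if isinstance(analyte, str):
        analyte = panel.get(analyte)
    elif analyte.name not in panel:
        raise KeyError(f"analyte {analyte.name!r} not in panel")
    if analyte.level_override is not None:
        return analyte.level_override
    if analyte.regulatory_status is RegulatoryStatus.mrl_established:
        assert analyte.mrl is not None
        return 0.75 * analyte.mrl if analyte.combined_residue else analyte.mrl
    return panel.qualitative_default_levels[analyte.family]


def positive_control_level(analyte: AnalyteSpec | str, panel: AnalytePanel) -> float:
    """Spike level of the batch positive control: 0.75 x validation level."""
    return 0.75 * validation_level(analyte, panel)
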