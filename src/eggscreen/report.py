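"""Report rendering: formatted validation/screening tables and exports.

The formatted validation report mirrors the conventional two-transition
layout — an ``Fc > T`` / ``Fc < T`` comparison string, a ``<C_val`` /
``>C_val`` detection-capability verdict, the LOD with a ``<1`` ug/kg
reporting floor, and the sensitivity as an integer percent — while a
parallel machine-readable export keeps every quantity at full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .screening import ScreeningCall
from .validation import CCBetaVerdict, ValidationResult

#: LODs below this value (ug/kg) are printed as "<1".
LOD_FLOOR_DEFAULT = 1.0


def format_lod(value: float, floor: float = LOD_FLOOR_DEFAULT, precision: int = 2) -> str:
    if value < floor:
        return f"<{floor:g}"
    return f"{value:.{precision}f}"


def validation_report_frame(
    results: Sequence[ValidationResult],
    lod_floor: float = LOD_FLOOR_DEFAULT,
    precision: int = 2,
) -> pd.DataFrame:
    """Formatted per-transition validation report (one row per result)."""
    rows = []
    for r in results:
        below = r.ccbeta_verdict is CCBetaVerdict.below_level
        rows.append(
            {
                "analyte": r.analyte,
                "transition": r.transition_rank.value,
                "fc_vs_t": "Fc > T" if below else "Fc < T",
                "ccbeta": "<C_val" if below else ">C_val",
                "lod": format_lod(r.lod, lod_floor, precision),
                "sensitivity_pct": int(round(r.sensitivity_pct)),
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def validation_export_frame(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """Full-precision machine-readable export of validation results."""
    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "transition": r.transition_rank.value,
                "t_value": r.t_value,
                "fc": r.fc,
                "lod": r.lod,
                "ccbeta_verdict": r.ccbeta_verdict.value,
                "sensitivity_pct": r.sensitivity_pct,
                "n_blanks": r.n_blanks,
                "n_spiked_fc": r.n_spiked_fc,
                "n_spiked_sens": r.n_spiked_sens,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


def screening_calls_frame(calls: Iterable[ScreeningCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id,
            "analyte": c.analyte,
            "identified": c.identified,
            "positive": c.positive,
            "compliance": c.compliance.value,
            "ion_ratio_ok": c.ion_ratio_ok,
            "rt_ok": c.rt_ok,
        }
        row.update({k: v for k, v in c.details.items() if isinstance(v, (int, float))})
        rows.append(row)
    return pd.DataFrame(rows)


def write_run_manifest(
    path: str | Path,
    inputs: dict[str, str | Path],
    seed: int | None = None,
    extra: dict | None = None,
) -> None:
    """Record input-file hashes, seed and version for run auditability."""
    from . import __version__

    digest = {}
    for name, p in inputs.items():
        p = Path(p)
        digest[name] = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
    doc = {"version": __version__, "seed": seed, "input_sha256": digest}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
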