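"""Delimited-text I/O for response tables and batch manifests.

A *response table* holds one row per measured MRM transition of one sample:
identifiers, the integrated instrument response, the noise in the analyte's
retention window (both in arbitrary area units), the observed retention
time, and the sample kind (blank / spiked / study).  Both comma- and
tab-delimited files are accepted; the delimiter is inferred from the header.

A *batch manifest* links study samples to their batch (day) and to the
positive-control samples measured alongside them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RESPONSE_COLUMNS = [
    "sample_id",
    "day",
    "replicate",
    "analyte",
    "transition_rank",
    "response",
    "noise",
    "observed_rt",
    "sample_kind",
]

MANIFEST_COLUMNS = ["sample_id", "day", "group", "role"]

SAMPLE_KINDS = {"blank", "spiked", "study"}
MANIFEST_ROLES = {"study", "positive_control", "blank"}


class ResponseTableError(ValueError):
    """Raised on malformed response tables or manifests."""


def _infer_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _check_columns(df: pd.DataFrame, required: list[str], what: str, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ResponseTableError(
            f"{what} {path} is missing required column(s): {', '.join(missing)}"
        )


def check_response_frame(df: pd.DataFrame, what: str = "response table") -> pd.DataFrame:
    """Validate schema and value domains of an in-memory response table."""
    _check_columns(df, RESPONSE_COLUMNS, what, "<in-memory>")
    bad_kind = set(df["sample_kind"].unique()) - SAMPLE_KINDS
    if bad_kind:
        raise ResponseTableError(f"unknown sample_kind value(s): {sorted(bad_kind)}")
    for col in ("response", "noise"):
        if (df[col] < 0).any():
            raise ResponseTableError(f"negative values in column {col!r}")
    return df


def read_response_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ResponseTableError(f"response table not found: {path}")
    df = pd.read_csv(path, sep=_infer_sep(path))
    _check_columns(df, RESPONSE_COLUMNS, "response table", path)
    df = df[RESPONSE_COLUMNS + [c for c in df.columns if c not in RESPONSE_COLUMNS]]
    return check_response_frame(df)


def write_response_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    check_response_frame(df)
    df.to_csv(path, sep=sep, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ResponseTableError(f"batch manifest not found: {path}")
    df = pd.read_csv(path, sep=_infer_sep(path))
    _check_columns(df, MANIFEST_COLUMNS, "batch manifest", path)
    bad = set(df["role"].unique()) - MANIFEST_ROLES
    if bad:
        raise ResponseTableError(f"unknown manifest role(s): {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    _check_columns(df, MANIFEST_COLUMNS, "batch manifest", path)
    df.to_csv(path, sep=sep, index=False)
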