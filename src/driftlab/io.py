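"""Trial-table and fit-table readers/writers.

Trial tables are plain CSV with a required header and columns::

    participant_id, study, side, orientation, label, choice, rt_s, responded

``side`` is -1/+1 (side of the familiar configuration), ``orientation``
1 = upright / 0 = inverted, ``label`` 1 = valid / 0 = invalid and *empty*
for the control arm, ``choice`` is "left"/"right" (empty when the deadline
lapsed), ``rt_s`` is the response time in seconds, ``responded`` is 0/1.
RTs are stored in seconds at full float precision, so a write/read
round-trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TRIAL_COLUMNS", "read_trials", "write_trials", "read_fits", "write_fits"]

TRIAL_COLUMNS = [
    "participant_id",
    "study",
    "side",
    "orientation",
    "label",
    "choice",
    "rt_s",
    "responded",
]

_STUDIES = ("control", "study1", "study2")


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"trial table is missing required columns {missing}; "
            f"expected header {TRIAL_COLUMNS}"
        )
    bad_study = set(df["study"].unique()) - set(_STUDIES)
    if bad_study:
        raise ValueError(f"unknown study values {sorted(bad_study)}; expected {_STUDIES}")
    if not df["side"].isin([-1, 1]).all():
        raise ValueError("column 'side' must be -1 or +1")
    if not df["orientation"].isin([0, 1]).all():
        raise ValueError("column 'orientation' must be 0 or 1")
    control = df["study"] == "control"
    if df.loc[control, "label"].notna().any():
        raise ValueError("control trials must have an empty 'label' column")
    if df.loc[~control, "label"].isna().any():
        raise ValueError("labels-present trials require 'label' 0 or 1")
    responded = df["responded"].astype(bool)
    if (df.loc[responded, "rt_s"] <= 0).any():
        raise ValueError("responded trials require rt_s > 0")
    if not df.loc[responded, "choice"].isin(["left", "right"]).all():
        raise ValueError("responded trials require choice 'left' or 'right'")
    return df


def coerce_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise dtypes of a trial table (in place-safe copy)."""
    out = df.copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["study"] = out["study"].astype(str)
    out["side"] = out["side"].astype(np.int64)
    out["orientation"] = out["orientation"].astype(np.int64)
    out["label"] = out["label"].astype("Int64")
    out["choice"] = out["choice"].astype(object).where(out["choice"].notna(), np.nan)
    out["rt_s"] = out["rt_s"].astype(float)
    out["responded"] = out["responded"].astype(bool)
    return _validate_trials(out)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial-table CSV, validating the dialect described above."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}"
        )
    return coerce_trials(df)


def write_trials(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as CSV (full-precision RTs, empty control labels).

    RTs are written with 17 significant digits, so a write/read round-trip
    reproduces every float bit-exactly.
    """
    coerce_trials(df)[TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def write_fits(df: pd.DataFrame, path: str | Path) -> None:
    """Write a fit table (one row per participant) as CSV."""
    df.to_csv(path, index=False)


def read_fits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("participant_id", "study"):
        if col not in df.columns:
            raise ValueError(f"{path}: fit table is missing column {col!r}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df
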