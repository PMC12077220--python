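"""Spot-table and track I/O in the TrackMate CSV dialect.

The interchange unit between simulation, detection and linking is the
"spot table": one row per detection with columns ``TRACK_ID`` (empty for
raw detections), ``FRAME``, ``POSITION_T`` (s), ``POSITION_X`` /
``POSITION_Y`` (µm) and ``QUALITY``.  Real TrackMate spot exports carry up
to three extra non-numeric header rows below the column names; the reader
tolerates and drops them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["TRACK_ID", "FRAME", "POSITION_T", "POSITION_X", "POSITION_Y", "QUALITY"]

_MANDATORY = ["FRAME", "POSITION_T", "POSITION_X", "POSITION_Y"]


class SpotTableError(ValueError):
    """Raised when a spot CSV is missing mandatory columns."""


def empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in SPOT_COLUMNS})


def make_spot_table(track_id, frame, t_s, x_um, y_um, quality=None) -> pd.DataFrame:
    """Assemble a spot table from parallel arrays (track_id may be None)."""
    frame = np.asarray(frame, dtype=int)
    n = frame.size
    if quality is None:
        quality = np.ones(n)
    if track_id is None:
        track_id = np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "TRACK_ID": np.asarray(track_id, dtype=float),
            "FRAME": frame,
            "POSITION_T": np.asarray(t_s, dtype=float),
            "POSITION_X": np.asarray(x_um, dtype=float),
            "POSITION_Y": np.asarray(y_um, dtype=float),
            "QUALITY": np.asarray(quality, dtype=float),
        }
    )
    return df.sort_values(["FRAME", "POSITION_X", "POSITION_Y"], kind="stable").reset_index(drop=True)


def write_spot_csv(spots: pd.DataFrame, path) -> None:
    spots.to_csv(path, index=False)


def read_spot_csv(path, position_unit_um: float = 1.0) -> pd.DataFrame:
    """Read a spot CSV, tolerating the TrackMate export's extra header rows.

    Parameters
    ----------
    path : str or Path
        CSV file with at least the mandatory columns FRAME, POSITION_T,
        POSITION_X, POSITION_Y.  TRACK_ID and QUALITY are optional.
    position_unit_um : float
        µm per spatial unit of the file (TrackMate exports may be in
        pixels or calibrated units); positions are multiplied by this.
    """
    df = pd.read_csv(Path(path))
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SpotTableError(f"spot CSV is missing mandatory column(s): {', '.join(missing)}")
    # TrackMate writes up to 3 descriptive rows (long names, units, dimension)
    # under the header; they are non-numeric in FRAME.
    frame_num = pd.to_numeric(df["FRAME"], errors="coerce")
    df = df.loc[frame_num.notna()].copy()
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if "TRACK_ID" not in df.columns:
        df["TRACK_ID"] = np.nan
    if "QUALITY" not in df.columns:
        df["QUALITY"] = 1.0
    df["FRAME"] = df["FRAME"].astype(int)
    df["POSITION_X"] = df["POSITION_X"] * position_unit_um
    df["POSITION_Y"] = df["POSITION_Y"] * position_unit_um
    return df[SPOT_COLUMNS].sort_values(["FRAME"], kind="stable").reset_index(drop=True)
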