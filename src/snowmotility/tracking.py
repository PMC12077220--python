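"""Spot detection and LAP track linking.

Detection is difference-of-Gaussians band-pass filtering with sub-pixel
local-maximum refinement, on bright-spots-on-dark-background image stacks.
Linking follows the two-stage Jaqaman linear-assignment formulation:
frame-to-frame one-to-one assignment minimising summed squared distances,
then track-segment gap closing, both solved exactly with a rectangular
assignment solver and a non-linking alternative whose cost equals the
squared distance cutoff.  No splitting or merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .io import SPOT_COLUMNS, make_spot_table, read_spot_csv


@dataclass(frozen=True)
class Spot:
    """One detection: frame index, time (s) and position (µm)."""

    frame: int
    t_s: float
    x_um: float
    y_um: float
    quality: float = 1.0


@dataclass
class Track:
    """An ordered sequence of spots for one cell.

    Frames are strictly increasing; positions are in µm and times in
    seconds.  Arrays are parallel.
    """

    track_id: int
    frames: np.ndarray
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    quality: np.ndarray = field(default=None)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.quality is None:
            self.quality = np.ones_like(self.t_s)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def n_spots(self) -> int:
        return int(self.frames.size)

    @property
    def span_frames(self) -> int:
        """Number of frames from first to last spot, inclusive."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def duration_s(self) -> float:
        return float(self.t_s[-1] - self.t_s[0])

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


@dataclass
class LinkConfig:
    """LAP linker settings (distances in pixels, as tuned on video)."""

    link_max_dist_px: float = 30.0
    gap_max_dist_px: float = 50.0
    gap_max_frames: int = 30
    min_track_frames: int = 75
    pixel_size_um: float = 1.0

    def __post_init__(self):
        if min(self.link_max_dist_px, self.gap_max_dist_px, self.pixel_size_um) <= 0:
            raise ValueError("distances and pixel size must be positive")
        if self.gap_max_frames < 1 or self.min_track_frames < 2:
            raise ValueError("gap_max_frames >= 1 and min_track_frames >= 2 required")


# ---------------------------------------------------------------------------
# Detection


def detect_spots_dog(
    frames: np.ndarray,
    diameter_px: float,
    quality_threshold: float,
    fps: float = 30.0,
    pixel_size_um: float = 1.0,
) -> pd.DataFrame:
    """Detect bright spots per frame with a difference-of-Gaussians filter.

    The band-pass scale is set by ``diameter_px`` (sigma = d / (2*sqrt(2)),
    second sigma sqrt(2) larger, the classic DoG blob pair).  Local maxima
    of the response above ``quality_threshold`` are kept and refined to
    sub-pixel position by a separable quadratic fit; quality is the DoG
    response at the maximum.

    Returns a spot table with TRACK_ID empty and positions in µm.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.size == 0:
        raise ValueError("empty image stack")
    if diameter_px <= 0:
        raise ValueError("diameter_px must be positive")
    sigma1 = diameter_px / (2.0 * np.sqrt(2.0))
    sigma2 = sigma1 * np.sqrt(2.0)
    rows = {k: [] for k in ("frame", "x", "y", "q")}
    for f, im in enumerate(frames):
        dog = gaussian_filter(im, sigma1) - gaussian_filter(im, sigma2)
        peaks = peak_local_max(
            dog,
            min_distance=max(1, int(round(diameter_px / 2))),
            threshold_abs=quality_threshold,
            exclude_border=False,
        )
        for r, c in peaks:
            dr = _subpixel_offset(dog, r, c, axis=0)
            dc = _subpixel_offset(dog, r, c, axis=1)
            rows["frame"].append(f)
            rows["x"].append((c + dc) * pixel_size_um)
            rows["y"].append((r + dr) * pixel_size_um)
            rows["q"].append(dog[r, c])
    frame = np.array(rows["frame"], dtype=int)
    return make_spot_table(None, frame, frame / fps, rows["x"], rows["y"], rows["q"])


def _subpixel_offset(img: np.ndarray, r: int, c: int, axis: int) -> float:
    """Quadratic 3-point interpolation of a peak along one axis."""
    idx = [r, c]
    lo, hi = idx[axis] - 1, idx[axis] + 1
    if lo < 0 or hi >= img.shape[axis]:
        return 0.0
    sel = [r, c]
    sel[axis] = slice(lo, hi + 1)
    fm, f0, fp = img[tuple(sel)]
    denom = fm - 2.0 * f0 + fp
    if denom >= 0:  # not a strict local max along this axis
        return 0.0
    return float(0.5 * (fm - fp) / denom)


# ---------------------------------------------------------------------------
# Linking


def _solve_lap(cost: np.ndarray, alt_cost: float) -> list[tuple[int, int]]:
    """One-to-one assignment with a per-item non-linking alternative.

    ``cost`` is (n_left, n_right) with np.inf for forbidden links.  Each
    left item gets a private dummy column of cost ``alt_cost`` so that
    expensive links are dropped rather than forced.  Returns accepted
    (left, right) pairs.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        return []
    big = 1e12
    padded = np.full((n, m + n), big)
    padded[:, :m] = np.where(np.isfinite(cost), cost, big)
    padded[np.arange(n), m + np.arange(n)] = alt_cost
    rows, cols = linear_sum_assignment(padded)
    # a link at exactly the cutoff distance (cost == alt_cost) is accepted
    return [(r, c) for r, c in zip(rows, cols) if c < m and padded[r, c] <= alt_cost and padded[r, c] < big]


def link_tracks(spots: pd.DataFrame, cfg: LinkConfig | None = None) -> list[Track]:
    """Link a spot table into tracks (frame-to-frame LAP + gap closing).

    Stage 1 links consecutive frames one-to-one, minimising summed squared
    distance subject to distance <= ``link_max_dist_px``; unlinked spots
    start new track segments.  Stage 2 joins segment ends to later segment
    starts when the spatial distance is <= ``gap_max_dist_px`` and the
    frame gap <= ``gap_max_frames``, again by minimum-cost assignment.
    Deterministic for a fixed input ordering (assignment ties resolved by
    the solver's fixed row-scan order, i.e. lowest spot index).
    """
    if cfg is None:
        cfg = LinkConfig()
    df = spots.sort_values(["FRAME"], kind="stable").reset_index(drop=True)
    link_max_um = cfg.link_max_dist_px * cfg.pixel_size_um
    gap_max_um = cfg.gap_max_dist_px * cfg.pixel_size_um

    frames_arr = df["FRAME"].to_numpy(dtype=int)
    pos = df[["POSITION_X", "POSITION_Y"]].to_numpy(dtype=float)

    # stage 1: frame-to-frame segments (lists of row indices into df)
    segments: list[list[int]] = []
    open_by_frame: dict[int, list[int]] = {}  # frame -> segment idx ending there
    unique_frames = np.unique(frames_arr)
    frame_rows = {f: np.flatnonzero(frames_arr == f) for f in unique_frames}
    for f in unique_frames:
        rows = frame_rows[f]
        prev = open_by_frame.pop(f - 1, [])
        matched_rows = set()
        if prev:
            prev_ends = np.array([segments[s][-1] for s in prev])
            d = np.linalg.norm(pos[prev_ends][:, None, :] - pos[rows][None, :, :], axis=2)
            cost = np.where(d <= link_max_um, d**2, np.inf)
            for i, j in _solve_lap(cost, link_max_um**2):
                segments[prev[i]].append(int(rows[j]))
                open_by_frame.setdefault(f, []).append(prev[i])
                matched_rows.add(int(rows[j]))
        for r in rows:
            if int(r) not in matched_rows:
                segments.append([int(r)])
                open_by_frame.setdefault(f, []).append(len(segments) - 1)

    # stage 2: gap closing between segment ends and later segment starts
    ends = np.array([s[-1] for s in segments])
    starts = np.array([s[0] for s in segments])
    n_seg = len(segments)
    if n_seg > 1:
        dt = frames_arr[starts][None, :] - frames_arr[ends][:, None]
        d = np.linalg.norm(pos[starts][None, :, :] - pos[ends][:, None, :], axis=2)
        feasible = (dt >= 1) & (dt <= cfg.gap_max_frames) & (d <= gap_max_um)
        cost = np.where(feasible, d**2, np.inf)
        links = _solve_lap(cost, gap_max_um**2)
        successor = {i: j for i, j in links}
        has_pred = set(successor.values())
        merged: list[list[int]] = []
        for i in range(n_seg):
            if i in has_pred:
                continue
            chain, j = list(segments[i]), i
            while j in successor:
                j = successor[j]
                chain.extend(segments[j])
            merged.append(chain)
        segments = merged

    tracks = []
    for tid, seg in enumerate(segments):
        rows = np.asarray(seg, dtype=int)
        tracks.append(
            Track(
                track_id=tid,
                frames=frames_arr[rows],
                t_s=df["POSITION_T"].to_numpy()[rows],
                x_um=pos[rows, 0],
                y_um=pos[rows, 1],
                quality=df["QUALITY"].to_numpy()[rows],
            )
        )
    return tracks


def filter_tracks(tracks: list[Track], min_track_frames: int = 75) -> list[Track]:
    """Keep tracks spanning at least ``min_track_frames`` frames.

    Span is last-frame minus first-frame plus one (gap frames inside a
    closed track count toward the span, matching a duration filter).
    """
    return [t for t in tracks if t.span_frames >= min_track_frames]


def filter_spot_columns(
    spots: pd.DataFrame, thresholds: dict[str, float] | None = None
) -> pd.DataFrame:
    """Generic column-threshold spot filters (e.g. intensity, SNR).

    Per-batch tuned filters have no honest fixed default, so ``thresholds``
    is empty by default; entries map column name -> minimum value kept.
    """
    if not thresholds:
        return spots
    keep = np.ones(len(spots), dtype=bool)
    for col, thr in thresholds.items():
        if col not in spots.columns:
            raise KeyError(f"spot table has no column {col!r}")
        keep &= spots[col].to_numpy() >= thr
    return spots.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Interop


def tracks_from_spot_table(spots: pd.DataFrame) -> list[Track]:
    """Group an already-linked spot table (TRACK_ID filled) into tracks."""
    df = spots.dropna(subset=["TRACK_ID"])
    tracks = []
    for tid, g in df.groupby("TRACK_ID", sort=True):
        g = g.sort_values("FRAME")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=g["FRAME"].to_numpy(dtype=int),
                t_s=g["POSITION_T"].to_numpy(),
                x_um=g["POSITION_X"].to_numpy(),
                y_um=g["POSITION_Y"].to_numpy(),
                quality=g["QUALITY"].to_numpy(),
            )
        )
    return tracks


def tracks_to_spot_table(tracks: list[Track]) -> pd.DataFrame:
    parts = []
    for t in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "TRACK_ID": float(t.track_id),
                    "FRAME": t.frames,
                    "POSITION_T": t.t_s,
                    "POSITION_X": t.x_um,
                    "POSITION_Y": t.y_um,
                    "QUALITY": t.quality,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=SPOT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def read_trackmate_export(path, position_unit_um: float = 1.0) -> list[Track]:
    """Read a TrackMate spots export CSV and group it into tracks.

    Tolerates the export's extra descriptive header rows; positions are
    interpreted in the file's spatial unit, scaled by ``position_unit_um``.
    """
    return tracks_from_spot_table(read_spot_csv(path, position_unit_um))
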