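"""Synthetic microswimmer data with the statistical structure the
analysis assumes.

The generator emulates the study conditions of the tracking assay:
10-second recordings at 30 frames/s of a mixed population confined to a
shallow (20 µm) chamber, projected to the 2-D focal plane.  Three cell
categories are simulated:

* **motile** — constant-speed heading process with Gaussian rotational
  noise plus a constant angular drift ("loop bias") that reproduces the
  loop-and-straight-line, quasi-helical paths of biciliate swimmers;
* **drifting** — passive advection at a constant drift velocity plus
  Brownian positional jitter (cells carried by residual flow);
* **stationary** — pure Brownian jitter.

Walls are reflective (billiard bounce), detections can be dropped
i.i.d. per spot to exercise gap closing, and everything is reproducible
bit-for-bit for a fixed seed.  A deciliated-control generator (drifting
+ stationary only) supports threshold calibration, and a Petri-dish
image generator with a tunable front-half intensity bias supports the
phototaxis assay.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import make_spot_table
from .metrics import PopulationSample, duration_scaled_threshold, population_summary, track_metrics
from .tracking import tracks_from_spot_table

CATEGORIES = ("motile", "drifting", "stationary")


@dataclass(frozen=True)
class SimConfig:
    """Arena, population and noise settings for one simulated recording."""

    arena_width_um: float = 2000.0
    arena_height_um: float = 2000.0
    duration_s: float = 10.0
    fps: float = 30.0
    pixel_size_um: float = 1.0
    n_motile: int = 20
    n_drifting: int = 10
    n_stationary: int = 10
    speed_mean_um_s: float = 50.0
    speed_sd_um_s: float = 10.0
    turn_rate_sd_rad_s: float = 1.5
    loop_bias_rad_s: float = 1.0
    drift_velocity_um_s: tuple = (2.0, 0.0)
    # per-frame positional jitter; ~sqrt(2 D / fps) for a ~6 µm cell in
    # near-freezing water (D ~ 0.04 µm²/s at 30 fps)
    brownian_sd_um: float = 0.05
    detection_dropout_p: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_motile, self.n_drifting, self.n_stationary) < 0:
            raise ValueError("population counts must be non-negative")
        if not 0 <= self.detection_dropout_p < 1:
            raise ValueError("detection_dropout_p must be in [0, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.speed_mean_um_s < 0 or self.speed_sd_um_s < 0:
            raise ValueError("speeds must be non-negative")
        nf = self.fps * self.duration_s
        if abs(nf - round(nf)) > 1e-9:
            raise ValueError("fps * duration_s must be an integer number of frames")

    @property
    def n_frames(self) -> int:
        """Number of sampled positions, t = 0 .. duration inclusive."""
        return int(round(self.fps * self.duration_s)) + 1

    @property
    def n_cells(self) -> int:
        return self.n_motile + self.n_drifting + self.n_stationary


def load_sim_config(path) -> SimConfig:
    """Read a flat key: value config file (YAML subset)."""
    with open(Path(path)) as fh:
        raw = yaml.safe_load(fh) or {}
    if "drift_velocity_um_s" in raw:
        raw["drift_velocity_um_s"] = tuple(raw["drift_velocity_um_s"])
    return SimConfig(**raw)


def save_sim_config(cfg: SimConfig, path) -> None:
    d = vars(cfg).copy()
    d["drift_velocity_um_s"] = list(d["drift_velocity_um_s"])
    with open(Path(path), "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def _reflect(pos: np.ndarray, direction: np.ndarray | None, w: float, h: float):
    """Billiard reflection of positions (and headings) into [0,w]x[0,h]."""
    for axis, lim in ((0, w), (1, h)):
        for _ in range(8):  # a step never crosses the arena many times
            below = pos[:, axis] < 0
            above = pos[:, axis] > lim
            if not (below.any() or above.any()):
                break
            pos[below, axis] = -pos[below, axis]
            pos[above, axis] = 2 * lim - pos[above, axis]
            if direction is not None:
                flip = below | above
                direction[flip, axis] = -direction[flip, axis]
    return pos, direction


def simulate_tracks(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one recording.

    Returns ``(spots, ground_truth)``: a spot table whose TRACK_ID column
    carries the true cell identity, and a per-cell table with columns
    ``cell_id``, ``category``, ``true_mean_speed_um_s``.
    """
    rng = np.random.default_rng(config.seed)
    nf = config.n_frames
    dt = 1.0 / config.fps
    w, h = config.arena_width_um, config.arena_height_um
    nm, nd, ns = config.n_motile, config.n_drifting, config.n_stationary
    n = config.n_cells

    categories = np.array(
        ["motile"] * nm + ["drifting"] * nd + ["stationary"] * ns, dtype=object
    )
    pos = rng.uniform([0, 0], [w, h], size=(n, 2))
    speeds = np.zeros(n)
    if nm:
        speeds[:nm] = np.clip(
            rng.normal(config.speed_mean_um_s, config.speed_sd_um_s, size=nm), 0.0, None
        )
    theta0 = rng.uniform(0, 2 * np.pi, size=max(nm, 1))
    direction = np.column_stack([np.cos(theta0[:nm]), np.sin(theta0[:nm])]) if nm else None
    drift = np.asarray(config.drift_velocity_um_s, dtype=float)

    xs = np.empty((nf, n))
    ys = np.empty((nf, n))
    xs[0], ys[0] = pos[:, 0], pos[:, 1]
    for f in range(1, nf):
        if nm:
            dtheta = (
                config.loop_bias_rad_s * dt
                + config.turn_rate_sd_rad_s * np.sqrt(dt) * rng.standard_normal(nm)
            )
            cos_d, sin_d = np.cos(dtheta), np.sin(dtheta)
            dx = direction[:, 0] * cos_d - direction[:, 1] * sin_d
            dy = direction[:, 0] * sin_d + direction[:, 1] * cos_d
            direction = np.column_stack([dx, dy])
            pos[:nm] += speeds[:nm, None] * dt * direction
        if nd:
            pos[nm : nm + nd] += drift * dt
        if nd + ns and config.brownian_sd_um > 0:
            pos[nm:] += config.brownian_sd_um * rng.standard_normal((nd + ns, 2))
        mot_dir = direction if nm else None
        if nm:
            pos[:nm], mot_dir = _reflect(pos[:nm], direction, w, h)
            direction = mot_dir
        if nd + ns:
            pos[nm:], _ = _reflect(pos[nm:], None, w, h)
        xs[f], ys[f] = pos[:, 0], pos[:, 1]

    frames = np.repeat(np.arange(nf), n)
    cell_ids = np.tile(np.arange(n), nf)
    x_flat = xs.ravel()
    y_flat = ys.ravel()
    keep = np.ones(frames.size, dtype=bool)
    if config.detection_dropout_p > 0:
        keep = rng.random(frames.size) >= config.detection_dropout_p
    spots = make_spot_table(
        cell_ids[keep], frames[keep], frames[keep] / config.fps, x_flat[keep], y_flat[keep]
    )
    truth = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "category": categories,
            "true_mean_speed_um_s": np.where(
                categories == "motile",
                speeds,
                np.where(categories == "drifting", np.linalg.norm(drift), 0.0),
            ),
        }
    )
    return spots, truth


def simulate_deciliated_control(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A cilia-removed control recording: drifting + stationary cells only.

    Any requested motile cells are reassigned to the stationary pool so
    the population size is preserved.
    """
    cfg = replace(config, n_motile=0, n_stationary=config.n_stationary + config.n_motile)
    return simulate_tracks(cfg)


def simulate_population(
    tpc_params,
    temperature: float,
    n_cells: int = 300,
    motile_fraction: float = 0.5,
    noise_cv: float = 0.10,
    seed: int | None = None,
    species: str = "synthetic",
    replicate: str = "r1",
    duration_s: float = 10.0,
    fps: float = 30.0,
) -> PopulationSample:
    """One replicate population whose motile speeds follow a known TPC.

    Motile-cell speeds are drawn around the TPC rate at ``temperature``
    with coefficient of variation ``noise_cv``; the number of motile
    cells is binomial in ``motile_fraction``; the remainder are split
    between drifting and stationary cells.  At temperatures where the
    TPC rate is non-positive the whole population is non-motile.
    """
    rng = np.random.default_rng(seed)
    rate = float(np.asarray(tpc_params.rate(temperature)))
    if not np.isfinite(rate) or rate <= 0:
        rate, n_motile = 0.0, 0
    else:
        n_motile = int(rng.binomial(n_cells, motile_fraction))
    n_rest = n_cells - n_motile
    n_drift = n_rest // 2
    cfg = SimConfig(
        arena_width_um=max(1000.0, 60.0 * np.sqrt(n_cells)),
        arena_height_um=max(1000.0, 60.0 * np.sqrt(n_cells)),
        duration_s=duration_s,
        fps=fps,
        n_motile=n_motile,
        n_drifting=n_drift,
        n_stationary=n_rest - n_drift,
        speed_mean_um_s=rate,
        speed_sd_um_s=rate * noise_cv,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    spots, _ = simulate_tracks(cfg)
    tracks = tracks_from_spot_table(spots)
    metrics = [track_metrics(t) for t in tracks]
    return population_summary(
        metrics,
        species=species,
        temperature_C=temperature,
        replicate=replicate,
        distance_threshold_um=duration_scaled_threshold(duration_s),
    )


def simulate_tpc_dataset(
    tpc_params,
    temperatures=(0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
    n_replicates: int = 3,
    noise_cv: float = 0.10,
    noise_floor_um_s: float = 0.5,
    seed: int | None = None,
    drop_inactive: bool = True,
) -> pd.DataFrame:
    """Per-temperature rate table drawn from a known TPC.

    Temperatures where the true rate is non-positive are dropped by
    default (``drop_inactive``): a fully inactivated population has no
    motile cells, hence no mean motile speed to report — matching how
    per-temperature speed summaries arise from the tracking assay.

    Each replicate mean speed is Gaussian around the true curve with a
    relative component ``noise_cv`` and a small absolute floor
    ``noise_floor_um_s``; the magnitude is taken (apparent path speeds
    are positive, and tracking jitter gives even non-moving populations
    sub-µm/s apparent speeds, so the observed spread never collapses to
    zero).  Returns columns temperature_C, rate, sd, n — the
    TPC-fitting input format.
    """
    rng = np.random.default_rng(seed)
    temps = np.asarray(temperatures, dtype=float)
    mu = np.asarray(tpc_params.rate(temps), dtype=float)
    if drop_inactive:
        keep = mu > 0
        temps, mu = temps[keep], mu[keep]
    mu = np.maximum(mu, 0.0)
    sd_true = np.sqrt((noise_cv * mu) ** 2 + noise_floor_um_s**2)
    obs = np.abs(rng.normal(mu, sd_true, size=(n_replicates, temps.size)))
    return pd.DataFrame(
        {
            "temperature_C": temps,
            "rate": obs.mean(axis=0),
            "sd": obs.std(axis=0, ddof=1),
            "n": n_replicates,
        }
    )


def render_frames(
    spots: pd.DataFrame,
    psf_sigma_px: float = 2.0,
    background_level: float = 100.0,
    noise_sd: float = 2.0,
    seed: int | None = None,
    shape_px: tuple | None = None,
    pixel_size_um: float = 1.0,
    spot_intensity: float = 1000.0,
) -> np.ndarray:
    """Render a spot table as a bright-on-dark 16-bit grayscale stack.

    Each spot becomes a Gaussian blob of scale ``psf_sigma_px`` and peak
    amplitude ``spot_intensity`` on a noisy flat background.  ``shape_px``
    is (height, width); by default it is taken from the spot extent.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(spots["FRAME"].max()) + 1 if len(spots) else 1
    if shape_px is None:
        hx = int(np.ceil(spots["POSITION_X"].max() / pixel_size_um)) + 10 if len(spots) else 64
        hy = int(np.ceil(spots["POSITION_Y"].max() / pixel_size_um)) + 10 if len(spots) else 64
        shape_px = (hy, hx)
    h, w = shape_px
    stack = rng.normal(background_level, noise_sd, size=(n_frames, h, w))
    half = max(1, int(np.ceil(4 * psf_sigma_px)))
    for _, row in spots.iterrows():
        f = int(row["FRAME"])
        cx = row["POSITION_X"] / pixel_size_um
        cy = row["POSITION_Y"] / pixel_size_um
        x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        stack[f, y0:y1, x0:x1] += spot_intensity * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * psf_sigma_px**2)
        )
    return np.clip(stack, 0, 65535).astype(np.uint16)


def simulate_phototaxis_dish(
    n_cells: int = 5000,
    bias: float = 0.5,
    dish_diameter_px: int = 200,
    cell_intensity: float = 30.0,
    seed: int | None = None,
    blob_sigma_px: float = 2.0,
    background_level: float = 100.0,
    vignette: float = 0.2,
) -> tuple[np.ndarray, np.ndarray]:
    """Petri-dish image pair for the phototaxis assay.

    ``bias`` is the expected fraction of total cell intensity in the
    light-facing half; the light sits on the +x side (light axis
    ``(1, 0)``).  The background image has the dish vignette but no
    cells; the assay image adds Gaussian cell blobs.  Blob centres are
    kept a 3-sigma band away from the dividing line so each cell's
    intensity lands almost entirely in its assigned half; ``bias=0.5``
    reproduces the no-phototaxis null.

    Returns ``(background, assay)`` as float images of identical shape.
    """
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    rng = np.random.default_rng(seed)
    margin = 10
    size = dish_diameter_px + 2 * margin
    if size % 2:
        size += 1  # even size keeps the half-dish split pixel-symmetric
    c = (size - 1) / 2.0
    radius = dish_diameter_px / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    inside = r2 <= radius**2
    background = np.full((size, size), 10.0)
    background[inside] = background_level * (1.0 - vignette * r2[inside] / radius**2)

    assay = background.copy()
    band = 3.0 * blob_sigma_px
    r_place = radius - 4.0 * blob_sigma_px
    placed = 0
    while placed < n_cells:
        m = n_cells - placed
        ang = rng.uniform(0, 2 * np.pi, size=m)
        rad = r_place * np.sqrt(rng.uniform(0, 1, size=m))
        dx, dy = rad * np.cos(ang), rad * np.sin(ang)
        ok = np.abs(dx) >= band
        dx, dy = dx[ok], dy[ok]
        front = rng.random(dx.size) < bias
        dx = np.where(front, np.abs(dx), -np.abs(dx))
        for px, py in zip(c + dx, c + dy):
            x0, x1 = int(px) - int(band), int(px) + int(band) + 1
            y0, y1 = int(py) - int(band), int(py) + int(band) + 1
            gy, gx = np.mgrid[y0:y1, x0:x1]
            assay[y0:y1, x0:x1] += cell_intensity * np.exp(
                -((gx - px) ** 2 + (gy - py) ** 2) / (2 * blob_sigma_px**2)
            )
        placed += dx.size
    return background, assay
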