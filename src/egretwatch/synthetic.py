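"""Synthetic data generators with known ground truth.

Everything downstream of a bird detector — daily counts, schedules,
heatmaps, weather regression — is tested against streams produced here,
where the quantities those estimators target (daily maxima, peak minutes,
occupancy bands, regression coefficients) are *planted* and recorded in a
ground-truth ledger.

Defaults emulate the monitoring setting: 2139 x 1281 px frames, detections
recorded 04:00-20:00 daily, bounding-box sides in [42, 160] px, three
species labels, a diurnal profile with a morning departure peak and an
evening return peak, a multi-day rise-and-fall count trend with a
migration surge, vertical stratification of the two egret species, and a
62-day weather table whose log-counts follow a quadratic time trend plus a
known linear combination of 12 weather factors.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, ellipse, polygon

from .compositor import Sprite

__all__ = [
    "SpeciesProfile",
    "SimulationConfig",
    "SPECIES",
    "FACTOR_COLUMNS",
    "TABLE1_BETA",
    "generate_sprites",
    "generate_background",
    "simulate_detections",
    "simulate_weather",
    "generate_feature_stack",
]

SPECIES = ("great_egret", "little_egret", "other")

# 12 weather factors, in report order
FACTOR_COLUMNS = [
    "mean_pressure_hpa",
    "abs_max_temp_c",
    "mean_temp_c",
    "abs_min_temp_c",
    "mean_dew_point_c",
    "mean_rel_humidity_pct",
    "mean_cloud_pct",
    "total_rainfall_mm",
    "total_bright_sunshine_h",
    "mean_wind_speed_kmh",
    "wind_dir_ew_deg",
    "wind_dir_ns_deg",
]

# default planted coefficients for the simulated count-weather link
TABLE1_BETA = np.array(
    [-0.0098, 0.2460, -0.8448, 0.0005, 0.7026, -0.1921,
     -0.0029, -0.0105, -0.1303, 0.0109, 0.0070, 0.0019]
)

_FACTOR_MEANS = np.array(
    [1012.0, 28.0, 25.0, 22.0, 21.0, 75.0, 60.0, 4.0, 6.0, 12.0, 0.0, 0.0]
)


# ---------------------------------------------------------------------------
# sprites and backgrounds
# ---------------------------------------------------------------------------

_SPECIES_STYLE = {
    "great_egret": dict(
        body=(26, 40), neck_len=58, neck_r=5, beak_len=22,
        body_color=(248, 246, 240), beak_color=(226, 182, 52),
    ),
    "little_egret": dict(
        body=(20, 30), neck_len=38, neck_r=4, beak_len=15,
        body_color=(250, 250, 248), beak_color=(45, 45, 45),
    ),
    "other": dict(
        body=(24, 30), neck_len=22, neck_r=5, beak_len=11,
        body_color=(128, 130, 142), beak_color=(96, 82, 60),
    ),
}


def _paint(canvas, rr, cc, color):
    h, w = canvas.shape[:2]
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    rr, cc = rr[keep], cc[keep]
    canvas[rr, cc, :3] = color
    canvas[rr, cc, 3] = 255


def _draw_bird(species: str, rng: np.random.Generator) -> np.ndarray:
    style = _SPECIES_STYLE[species]
    canvas = np.zeros((220, 200, 4), dtype=np.uint8)
    by, bx = 140, 95
    ry, rx = style["body"]

    # legs first so the body overlaps their tops
    for sign in (-1, 1):
        ang = sign * 0.08 + rng.uniform(-0.06, 0.06)
        for t in np.linspace(0, 1, 24):
            rr, cc = disk(
                (by + ry - 4 + t * 34, bx + sign * 6 + t * 34 * np.sin(ang)), 1.6
            )
            _paint(canvas, rr, cc, (62, 60, 56))

    rr, cc = ellipse(by, bx, ry, rx)
    _paint(canvas, rr, cc, style["body_color"])

    # neck: quadratic bezier from the body's front-top to the head
    base = np.array([by - ry * 0.55, bx + rx * 0.55])
    theta = rng.uniform(-0.45, 0.45)  # head angle from vertical (the pose)
    head = base + style["neck_len"] * np.array([-np.cos(theta), np.sin(theta)])
    ctrl = (base + head) / 2 + np.array(
        [rng.uniform(-8, 8), 10 + rng.uniform(-6, 6)]
    )
    for t in np.linspace(0, 1, 48):
        pt = (1 - t) ** 2 * base + 2 * t * (1 - t) * ctrl + t**2 * head
        rr, cc = disk(tuple(pt), style["neck_r"])
        _paint(canvas, rr, cc, style["body_color"])
    rr, cc = disk(tuple(head), style["neck_r"] + 2.5)
    _paint(canvas, rr, cc, style["body_color"])

    # beak: thin wedge pointing away from the body
    phi = theta + np.pi / 2 + rng.uniform(-0.15, 0.15)
    direction = np.array([np.sin(phi - np.pi / 2), np.cos(phi - np.pi / 2)])
    perp = np.array([-direction[1], direction[0]])
    tip = head + style["beak_len"] * direction
    b1 = head + 2.6 * perp
    b2 = head - 2.6 * perp
    rr, cc = polygon([b1[0], b2[0], tip[0]], [b1[1], b2[1], tip[1]])
    _paint(canvas, rr, cc, style["beak_color"])

    ys, xs = np.nonzero(canvas[..., 3])
    return canvas[ys.min() : ys.max() + 1, xs.min() : xs.max() + 1].copy()


def generate_sprites(seed: int, n_poses: int) -> list[Sprite]:
    """Procedural bird sprites: ``n_poses`` per species, deterministic in seed.

    Species differ in fixed geometric attributes (neck length, beak length,
    beak colour) so a classifier could in principle separate them; poses
    vary the head/neck angle.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    rng = np.random.default_rng(seed)
    return [
        Sprite(_draw_bird(species, rng), species)
        for species in SPECIES
        for _ in range(n_poses)
    ]


def generate_background(width: int, height: int, seed: int) -> np.ndarray:
    """Deterministic textured RGB background: sky gradient + tree-crown blobs."""
    if width < 64 or height < 64:
        raise ValueError("background must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    yy = np.linspace(0.0, 1.0, height)[:, None]
    top = np.array([128.0, 185.0, 232.0])
    bottom = np.array([208.0, 228.0, 244.0])
    img = top[None, None, :] + yy[..., None] * (bottom - top)[None, None, :]
    img = np.broadcast_to(img, (height, width, 3)).copy()

    coarse = rng.random((height // 32 + 2, width // 32 + 2))
    blobs = ndimage.zoom(coarse, (height / coarse.shape[0], width / coarse.shape[1]),
                         order=3)[:height, :width]
    canopy = (blobs > 0.52) & (yy > 0.35)
    shade = 0.7 + 0.3 * blobs[canopy]
    tree = np.array([46.0, 92.0, 52.0])
    img[canopy] = tree[None, :] * shade[:, None]
    noise = rng.normal(0, 2.0, size=img.shape)
    return np.clip(img + noise, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# detection-record streams
# ---------------------------------------------------------------------------


@dataclass
class SpeciesProfile:
    """Piecewise diurnal count profile (minutes since midnight).

    High pre-departure: a ramp climbs from ``c_base`` to ``c_peak_morning``
    peaking exactly at ``departure_minute``, then steps down to the midday
    ``c_trough``; an evening ramp peaks at ``return_minute`` with
    ``c_peak_evening`` and settles to ``c_evening``.  The step drops exceed
    (ramp slope x 60 min) so the backward 1-h moving average attains its
    window maximum exactly at the planted peak minutes.
    """

    c_base: float = 2.0
    c_peak_morning: float = 10.0
    c_trough: float = 2.0
    c_peak_evening: float = 12.0
    c_evening: float = 6.0
    ramp_minutes: float = 120.0
    departure_minute: int = 390  # 06:30
    return_minute: int = 1080  # 18:00

    def value(self, minute: float) -> float:
        if minute <= self.departure_minute:
            start = self.departure_minute - self.ramp_minutes
            if minute < start:
                return self.c_base
            return self.c_base + (self.c_peak_morning - self.c_base) * (
                (minute - start) / self.ramp_minutes
            )
        if minute <= self.return_minute:
            start = self.return_minute - self.ramp_minutes
            if minute < start:
                return self.c_trough
            return self.c_trough + (self.c_peak_evening - self.c_trough) * (
                (minute - start) / self.ramp_minutes
            )
        return self.c_evening

    @classmethod
    def constant(cls, count: float) -> "SpeciesProfile":
        return cls(c_base=count, c_peak_morning=count, c_trough=count,
                   c_peak_evening=count, c_evening=count)


def _default_profiles() -> dict:
    return {
        "great_egret": SpeciesProfile(),
        "little_egret": SpeciesProfile(
            c_peak_morning=8.0, c_peak_evening=9.0, c_evening=4.0,
            departure_minute=400, return_minute=1125,  # returns 45 min later
        ),
        "other": SpeciesProfile.constant(1.0),
    }


def _default_bands() -> dict:
    # fraction of frame height occupied per species (vertical stratification)
    return {
        "great_egret": (0.10, 0.70),
        "little_egret": (0.35, 0.65),
        "other": (0.25, 0.85),
    }


@dataclass
class SimulationConfig:
    """Knobs for the detection-stream simulator.

    The recording window must lie within one day, counts are non-negative
    and vertical bands are fractions of the frame height in [0, 1].
    """

    frame_width: int = 2139
    frame_height: int = 1281
    days: list = field(
        default_factory=lambda: [dt.date(2019, 9, 23) + dt.timedelta(d) for d in range(7)]
    )
    window_start_minute: int = 240   # 04:00
    window_end_minute: int = 1200    # 20:00
    frame_interval_s: int = 60
    species: tuple = SPECIES
    profiles: dict = field(default_factory=_default_profiles)
    bands: dict = field(default_factory=_default_bands)
    hotspots_x: tuple = ((0.62, 0.05, 0.7), (0.30, 0.04, 0.3))  # (mean, sd, weight)
    day_cycle_days: float = 13.0
    day_trend_amp: float = 0.35
    surge_window: tuple = (35, 45)   # day indices [start, end)
    surge_amp: float = 0.8
    box_side_range: tuple = (42, 160)
    count_noise: bool = False
    score_range: tuple = (0.6, 1.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.window_start_minute < self.window_end_minute <= 1440):
            raise ValueError("recording window must lie within one day")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        window_s = (self.window_end_minute - self.window_start_minute) * 60
        if self.frame_interval_s > window_s:
            raise ValueError("frame_interval_s exceeds the recording window")
        for sp, (lo, hi) in self.bands.items():
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"vertical band for {sp} must satisfy 0 <= lo < hi <= 1")
        for sp, prof in self.profiles.items():
            if min(prof.c_base, prof.c_peak_morning, prof.c_trough,
                   prof.c_peak_evening, prof.c_evening) < 0:
                raise ValueError(f"occupancy counts for {sp} must be >= 0")

    def day_factor(self, day_index: int) -> float:
        f = 1.0 + self.day_trend_amp * np.sin(2 * np.pi * day_index / self.day_cycle_days)
        if self.surge_window[0] <= day_index < self.surge_window[1]:
            f += self.surge_amp
        return float(f)


def _sample_positions(n, species, config, rng):
    """Box centres and sizes for n birds of one species; boxes fit the frame."""
    W, H = config.frame_width, config.frame_height
    lo_s, hi_s = config.box_side_range
    w = rng.uniform(lo_s, hi_s, size=n)
    h = rng.uniform(lo_s, hi_s, size=n)
    lo, hi = config.bands[species]
    y_lo = np.maximum(lo * H, h / 2)
    y_hi = np.minimum(hi * H, H - h / 2)
    y = y_lo + rng.random(n) * np.maximum(y_hi - y_lo, 0.0)
    means = np.array([m for m, _, _ in config.hotspots_x])
    sds = np.array([s for _, s, _ in config.hotspots_x])
    weights = np.array([wgt for _, _, wgt in config.hotspots_x], dtype=float)
    comp = rng.choice(len(means), size=n, p=weights / weights.sum())
    x = rng.normal(means[comp] * W, sds[comp] * W)
    x = np.clip(x, w / 2, W - w / 2)
    return x, y, w, h


def simulate_detections(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Emit a detection-record stream plus its ground-truth ledger.

    Columns: ``timestamp, species, x_min, y_min, x_max, y_max, score``
    (0-based half-open pixel boxes).  The ledger records, per species, the
    realized per-day maximum frame count and the planted departure/return
    peak minutes, plus the occupancy-band and hotspot parameters.
    """
    rng = np.random.default_rng(config.rng_seed)
    rows = []
    daily_max: dict[str, dict[str, int]] = {sp: {} for sp in config.species}
    step = dt.timedelta(seconds=config.frame_interval_s)
    for d_idx, day in enumerate(config.days):
        factor = config.day_factor(d_idx)
        t = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(
            minutes=config.window_start_minute
        )
        end = dt.datetime.combine(day, dt.time(0)) + dt.timedelta(
            minutes=config.window_end_minute
        )
        maxima = {sp: 0 for sp in config.species}
        while t <= end:
            minute = t.hour * 60 + t.minute + t.second / 60.0
            for sp in config.species:
                mean = config.profiles[sp].value(minute) * factor
                count = int(rng.poisson(mean)) if config.count_noise else int(round(mean))
                if count > maxima[sp]:
                    maxima[sp] = count
                if count == 0:
                    continue
                x, y, w, h = _sample_positions(count, sp, config, rng)
                scores = rng.uniform(*config.score_range, size=count)
                for k in range(count):
                    rows.append(
                        (t, sp, x[k] - w[k] / 2, y[k] - h[k] / 2,
                         x[k] + w[k] / 2, y[k] + h[k] / 2, scores[k])
                    )
            t += step
        for sp in config.species:
            daily_max[sp][day.isoformat()] = maxima[sp]
    records = pd.DataFrame(
        rows,
        columns=["timestamp", "species", "x_min", "y_min", "x_max", "y_max", "score"],
    )
    ledger = {
        "daily_max": daily_max,
        "departure_minute": {
            sp: config.profiles[sp].departure_minute for sp in config.species
        },
        "return_minute": {
            sp: config.profiles[sp].return_minute for sp in config.species
        },
        "bands": {sp: list(config.bands[sp]) for sp in config.species},
        "hotspots_x": [list(h) for h in config.hotspots_x],
        "day_factor": {
            day.isoformat(): config.day_factor(i) for i, day in enumerate(config.days)
        },
        "frame_interval_s": config.frame_interval_s,
    }
    return records, ledger


# ---------------------------------------------------------------------------
# weather series
# ---------------------------------------------------------------------------


def simulate_weather(
    n_days: int = 62,
    coefficients: np.ndarray | None = None,
    seed: int = 0,
    noise_sd: float = 0.15,
    trend: tuple[float, float, float] | None = None,
    start_date: dt.date = dt.date(2019, 9, 23),
) -> tuple[pd.DataFrame, dict]:
    """Daily weather factors plus a count linked through known coefficients.

    ``ln(count_all) = a0 + a1*t + a2*t^2 + sum_i beta_i * x_i + N(0, sd)``.
    The 12 factors are drawn from independent plausible marginals; wind
    direction is drawn uniform on [0, 360) and stored as its EW/NS
    components.  ``count_all`` is stored unrounded so the planted linear
    combination is exactly recoverable at ``noise_sd = 0``.
    """
    beta = TABLE1_BETA if coefficients is None else np.asarray(coefficients, float)
    if beta.shape != (12,) or not np.all(np.isfinite(beta)):
        raise ValueError("coefficients must be 12 finite values")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)

    X = np.empty((n_days, 12))
    X[:, 0] = rng.normal(1012.0, 3.0, n_days)          # mean pressure hPa
    X[:, 2] = rng.normal(25.0, 2.0, n_days)            # mean temp
    X[:, 1] = X[:, 2] + np.abs(rng.normal(3.0, 1.0, n_days))   # abs max temp
    X[:, 3] = X[:, 2] - np.abs(rng.normal(3.0, 1.0, n_days))   # abs min temp
    X[:, 4] = rng.normal(21.0, 2.0, n_days)            # dew point
    X[:, 5] = np.clip(rng.normal(75.0, 6.0, n_days), 20, 100)  # RH %
    X[:, 6] = np.clip(rng.normal(60.0, 18.0, n_days), 0, 100)  # cloud %
    X[:, 7] = rng.exponential(4.0, n_days)             # rainfall mm
    X[:, 8] = rng.uniform(0.0, 11.0, n_days)           # sunshine h
    X[:, 9] = np.clip(rng.normal(12.0, 4.0, n_days), 0.5, None)  # wind km/h
    theta = rng.uniform(0.0, 360.0, n_days)
    X[:, 10] = np.sin(np.deg2rad(theta)) * 90.0        # EW component
    X[:, 11] = np.cos(np.deg2rad(theta)) * 90.0        # NS component

    if trend is None:
        a0 = float(np.log(60.0) - _FACTOR_MEANS @ beta)
        trend = (a0, 0.05, -0.0008)
    a0, a1, a2 = trend
    lny = a0 + a1 * t + a2 * t**2 + X @ beta
    if noise_sd > 0:
        lny = lny + rng.normal(0.0, noise_sd, n_days)
    table = pd.DataFrame(X, columns=FACTOR_COLUMNS)
    table.insert(0, "date", [start_date + dt.timedelta(int(d)) for d in range(n_days)])
    table["count_all"] = np.exp(lny)
    ledger = {
        "beta": beta.tolist(),
        "trend": [a0, a1, a2],
        "noise_sd": noise_sd,
        "factor_columns": FACTOR_COLUMNS,
    }
    return table, ledger


# ---------------------------------------------------------------------------
# feature stacks (fixtures for the subspace-visualization stage)
# ---------------------------------------------------------------------------


def generate_feature_stack(
    seed: int,
    height: int = 16,
    width: int = 16,
    dim: int = 8,
    out_dim: int = 3,
    noise_in_null: float = 1.0,
) -> dict:
    """Random feature grid plus affine operator, with noise planted in the
    operator's null space so row/null splitting provably denoises it.

    Returns ``{"x": (H, W, D), "A": (M, D)}`` suitable for ``np.savez``.
    """
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(out_dim, dim))
    base = rng.normal(size=(height, width, dim))
    # signal in the row space of A
    signal = np.einsum("md,hwm->hwd", A, np.einsum("md,hwd->hwm", A, base))
    q, _ = np.linalg.qr(A.T)
    null_proj = np.eye(dim) - q @ q.T
    noise = np.einsum("de,hwe->hwd", null_proj, rng.normal(size=(height, width, dim)))
    return {"x": signal + noise_in_null * noise, "A": A}
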