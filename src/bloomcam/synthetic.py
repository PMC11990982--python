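"""Synthetic phenocamera scenarios with known ground truth.

The generator emulates what a fixed camera pointed at one plant crown
records over a year: a seasonal canopy color trajectory (dormant branches,
green-up, a stable full-leaf plateau, senescence), a flowering window in
which a growing fraction of ROI pixels takes the petal color (shifting the
chromatic means and inflating the within-ROI standard deviations), pixel
texture and frame-level illumination noise, near-black night frames,
high-brightness/low-GEI snow days, and color-shifted artificial-light
frames during configured evening windows.

The flowering pulse is modeled as a petal-pixel mixture fraction that ramps
up and down linearly at the window edges, because both signals the
classifier exploits — the mean color shift and the gei.sd inflation from
petal/foliage contrast — follow directly from such a mixture.

Every frame draws its pixels from an RNG keyed by (seed, year, doy,
minute), so the full-frame renderer and the fast feature-table shortcut
produce bit-identical statistics and everything is reproducible from the
scenario seed.
"""

from __future__ import annotations

import datetime as dt
import json
import os
from dataclasses import dataclass
from typing import Iterator
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from . import solar
from .features import (
    FEATURES,
    ExclusionWindow,
    ImageFrame,
    RoiPolygon,
    SiteConfig,
    pixel_statistics,
)
from .labeling import BbchObservation, FloweringInterval

_UTC = ZoneInfo("UTC")

# default site: a mid-latitude Central European arboretum
_DEFAULT_LAT, _DEFAULT_LON = 52.4267, 16.8957


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that defines one synthetic plant-year."""

    year: int = 2022
    start_doy: int = 1
    end_doy: int = 365
    cadence_minutes: int = 10
    roi_size: tuple[int, int] = (16, 16)          # (height, width) pixel block
    lat: float = _DEFAULT_LAT
    lon: float = _DEFAULT_LON
    timezone: str = "UTC"

    # seasonal canopy trajectory (DOY anchors and channel levels)
    dormant_rgb: tuple[float, float, float] = (105.0, 95.0, 80.0)
    summer_rgb: tuple[float, float, float] = (70.0, 115.0, 60.0)
    senescent_rgb: tuple[float, float, float] = (140.0, 110.0, 50.0)
    greenup_start: int = 100
    greenup_end: int = 122
    senescence_start: int = 270
    senescence_end: int = 300

    # flowering pulse
    flowering_onset: int = 128
    flowering_end: int = 143
    petal_rgb: tuple[float, float, float] = (235.0, 235.0, 240.0)  # white petals
    petal_fraction: float = 0.45
    ramp_days: int = 3

    # noise model
    texture_sd: float = 10.0       # per-pixel within-ROI texture, DN
    noise_sd: float = 6.0          # frame-level illumination jitter, DN
    night_level: float = 3.0       # constant DN of night frames

    # artifacts
    snow_days: tuple[int, ...] = (330, 331, 332)
    snow_rgb: tuple[float, float, float] = (228.0, 230.0, 236.0)
    #: (doy, start_minute, end_minute) evening artificial-light windows (UTC)
    artificial_windows: tuple[tuple[int, int, int], ...] = (
        (309, 16 * 60, 21 * 60),
        (310, 16 * 60, 21 * 60),
    )
    artificial_rgb: tuple[float, float, float] = (205.0, 130.0, 55.0)

    seed: int = 0

    def __post_init__(self) -> None:
        if not self.flowering_onset <= self.flowering_end:
            raise ValueError("flowering onset must not exceed end")
        if self.petal_fraction < 0 or self.texture_sd < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def site(self) -> SiteConfig:
        return SiteConfig(
            lat=self.lat, lon=self.lon, timezone=self.timezone,
            exclusion_windows=self.exclusions(),
        )

    def exclusions(self) -> list[ExclusionWindow]:
        wins = []
        for doy, m0, m1 in self.artificial_windows:
            base = dt.datetime(self.year, 1, 1, tzinfo=_UTC) + dt.timedelta(days=doy - 1)
            wins.append(ExclusionWindow(
                start=base + dt.timedelta(minutes=m0),
                end=base + dt.timedelta(minutes=m1),
                reason="artificial-light",
            ))
        return wins


@dataclass
class GroundTruth:
    interval: FloweringInterval
    bbch_by_doy: dict[int, int]
    roi: RoiPolygon
    site: SiteConfig


# ---------------------------------------------------------------------------
# scenario internals
# ---------------------------------------------------------------------------

def _base_rgb(cfg: ScenarioConfig, doy: int) -> np.ndarray:
    """Piecewise-linear seasonal canopy color for a day of year."""
    anchors = np.array([
        1, cfg.greenup_start, cfg.greenup_end,
        cfg.senescence_start, cfg.senescence_end, 366,
    ], dtype=float)
    levels = np.array([
        cfg.dormant_rgb, cfg.dormant_rgb, cfg.summer_rgb,
        cfg.summer_rgb, cfg.senescent_rgb, cfg.dormant_rgb,
    ], dtype=float)
    return np.array([np.interp(doy, anchors, levels[:, c]) for c in range(3)])


def petal_fraction(cfg: ScenarioConfig, doy: int) -> float:
    """Petal-pixel mixture fraction, ramping linearly at the window edges."""
    if not cfg.flowering_onset <= doy <= cfg.flowering_end:
        return 0.0
    ramp = max(cfg.ramp_days, 1)
    up = (doy - cfg.flowering_onset + 1) / ramp
    down = (cfg.flowering_end - doy + 1) / ramp
    return cfg.petal_fraction * min(1.0, up, down)


def bbch_for_doy(cfg: ScenarioConfig, doy: int) -> int:
    """A plausible BBCH code schedule consistent with the flowering window."""
    onset, end = cfg.flowering_onset, cfg.flowering_end
    if doy < onset - 21:
        return 39
    if doy < onset - 2:
        step = (doy - (onset - 21)) / max(onset - 2 - (onset - 21), 1)
        return 51 + min(8, int(step * 9))
    if doy < onset:
        return 60
    if doy <= end:
        if end == onset:
            return 61
        return 61 + round(6 * (doy - onset) / (end - onset))
    if doy <= end + 3:
        return 68
    if doy <= end + 6:
        return 69
    return 71


def _frame_rng(cfg: ScenarioConfig, doy: int, minute: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, cfg.year, doy, minute])


def _day_window(cfg: ScenarioConfig, doy: int) -> tuple[dt.datetime, dt.datetime]:
    date = dt.date(cfg.year, 1, 1) + dt.timedelta(days=doy - 1)
    return solar.sun_times(date, cfg.lat, cfg.lon)


def _in_artificial(cfg: ScenarioConfig, doy: int, minute: int) -> bool:
    return any(d == doy and m0 <= minute <= m1 for d, m0, m1 in cfg.artificial_windows)


def render_pixels(cfg: ScenarioConfig, doy: int, minute: int,
                  daylight: bool) -> np.ndarray:
    """Render one frame's ROI pixel block as a flat ``(n, 3)`` uint8 array."""
    h, w = cfg.roi_size
    n = h * w
    rng = _frame_rng(cfg, doy, minute)
    if not daylight:
        if _in_artificial(cfg, doy, minute):
            base = np.tile(cfg.artificial_rgb, (n, 1))
            px = base + rng.normal(0.0, cfg.texture_sd, size=(n, 3))
        else:
            px = np.full((n, 3), cfg.night_level)
    else:
        if doy in cfg.snow_days:
            base = np.tile(cfg.snow_rgb, (n, 1))
            px = base + rng.normal(0.0, cfg.texture_sd / 3.0, size=(n, 3))
        else:
            base = np.tile(_base_rgb(cfg, doy), (n, 1))
            p = petal_fraction(cfg, doy)
            if p > 0:
                petal = rng.random(n) < p
                base[petal] = cfg.petal_rgb
            px = base + rng.normal(0.0, cfg.texture_sd, size=(n, 3))
        px = px + rng.normal(0.0, cfg.noise_sd, size=(1, 3))  # shared illumination
    return np.clip(np.rint(px), 0, 255).astype(np.uint8)


def _schedule(cfg: ScenarioConfig) -> Iterator[tuple[int, int, dt.datetime, bool]]:
    """Yield (doy, minute, timestamp, daylight) for every frame of the scenario."""
    for doy in range(cfg.start_doy, cfg.end_doy + 1):
        rise, sset = _day_window(cfg, doy)
        base = dt.datetime(cfg.year, 1, 1, tzinfo=_UTC) + dt.timedelta(days=doy - 1)
        for minute in range(0, 24 * 60, cfg.cadence_minutes):
            ts = base + dt.timedelta(minutes=minute)
            yield doy, minute, ts, bool(rise <= ts <= sset)


def _ground_truth(cfg: ScenarioConfig) -> GroundTruth:
    h, w = cfg.roi_size
    roi = RoiPolygon("Syn", ((0, 0), (w - 1, 0), (w - 1, h - 1), (0, h - 1)))
    return GroundTruth(
        interval=FloweringInterval(cfg.flowering_onset, cfg.flowering_end, cfg.year),
        bbch_by_doy={d: bbch_for_doy(cfg, d) for d in range(cfg.start_doy, cfg.end_doy + 1)},
        roi=roi,
        site=cfg.site,
    )


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_frames(cfg: ScenarioConfig) -> tuple[list[ImageFrame], GroundTruth]:
    """Render the scenario as actual image frames (use short scenarios)."""
    h, w = cfg.roi_size
    frames = [
        ImageFrame(timestamp=ts, pixels=render_pixels(cfg, doy, minute, day).reshape(h, w, 3))
        for doy, minute, ts, day in _schedule(cfg)
    ]
    return frames, _ground_truth(cfg)


def generate_feature_table(cfg: ScenarioConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Shortcut generator: the 16-feature records without building frames.

    Statistically (and, given the per-frame RNG keying, bit-for-bit)
    identical to running :func:`bloomcam.features.extract_features` over
    :func:`generate_frames`; used for fast whole-year experiments.
    """
    truth = _ground_truth(cfg)
    h, w = cfg.roi_size
    mask = truth.roi.mask((h, w)).reshape(-1)
    rows = []
    for doy, minute, ts, day in _schedule(cfg):
        px = render_pixels(cfg, doy, minute, day)[mask]
        rec = {"roi_id": truth.roi.roi_id, "timestamp": ts}
        rec.update(pixel_statistics(px))
        rows.append(rec)
    df = pd.DataFrame(rows)[["roi_id", "timestamp", *FEATURES, "excluded_pixels"]]
    return df, truth


def generate_observation_schedule(
    truth: GroundTruth,
    seed: int = 0,
    gap_range: tuple[int, int] = (2, 4),
    start_doy: int | None = None,
    end_doy: int | None = None,
) -> list[BbchObservation]:
    """Emulated field visits at randomized 2-4 day gaps with truth-consistent codes."""
    rng = np.random.default_rng(seed)
    lo = start_doy if start_doy is not None else truth.interval.onset_doy - 30
    hi = end_doy if end_doy is not None else truth.interval.end_doy + 30
    lo = max(lo, min(truth.bbch_by_doy))
    hi = min(hi, max(truth.bbch_by_doy))
    obs = []
    d = lo
    while d <= hi:
        date = dt.date(truth.interval.year, 1, 1) + dt.timedelta(days=d - 1)
        obs.append(BbchObservation(plant=truth.roi.roi_id, date=date,
                                   bbch=truth.bbch_by_doy[d]))
        d += int(rng.integers(gap_range[0], gap_range[1] + 1))
    return obs


def write_scenario(cfg: ScenarioConfig, outdir: str, obs_seed: int = 0) -> GroundTruth:
    """Write a full scenario in the pipeline's public input formats.

    Produces ``images/`` (PNG frames named by timestamp), ``roi.json``,
    ``observations.csv`` and ``truth.json``.
    """
    from PIL import Image

    from .features import write_rois
    from .labeling import write_observations

    frames, truth = generate_frames(cfg)
    img_dir = os.path.join(outdir, "images")
    os.makedirs(img_dir, exist_ok=True)
    for f in frames:
        name = f.timestamp.strftime("%Y_%m_%d_%H%M%S") + ".png"
        Image.fromarray(f.pixels).save(os.path.join(img_dir, name))
    write_rois([truth.roi], os.path.join(outdir, "roi.json"))
    obs = generate_observation_schedule(truth, seed=obs_seed)
    write_observations(obs, os.path.join(outdir, "observations.csv"))
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump({
            "onset_doy": truth.interval.onset_doy,
            "end_doy": truth.interval.end_doy,
            "year": truth.interval.year,
            "bbch_by_doy": {str(k): v for k, v in truth.bbch_by_doy.items()},
        }, fh, indent=1)
    return truth
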