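"""ROI color-index extraction and time-series preprocessing.

For every camera frame and every plant region of interest (ROI) the module
computes 16 color indices: the mean and within-ROI standard deviation of the
three raw digital-number channels (R, G, B), of brightness
``BRI = R + G + B``, of the chromatic coordinates ``RI = R/BRI``,
``GI = G/BRI``, ``BI = B/BRI`` and of the green excess index
``GEI = 2G - (R + B)``.  Indices are computed per pixel inside the ROI mask
and then summarised, so the standard deviations carry real within-crown
heterogeneity (flowers against foliage), which is what the downstream
classifier exploits.

Three preprocessing filters clean the raw archive: a sunrise/sunset window
filter (night frames), explicit exclusion windows (e.g. evening light shows
with artificial illumination), and a zero-standard-deviation filter (frames
whose ROI is too dark to carry color information).
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon as _sk_polygon

from . import solar

logger = logging.getLogger(__name__)

#: Canonical order of the 16 features in every table this package writes.
FEATURES: tuple[str, ...] = (
    "r.av", "g.av", "b.av",
    "r.sd", "g.sd", "b.sd",
    "bri.av", "bri.sd",
    "ri.av", "ri.sd",
    "gi.av", "gi.sd",
    "bi.av", "bi.sd",
    "gei.av", "gei.sd",
)

#: The 8 standard-deviation features used by the too-dark-ROI filter.
SD_FEATURES: tuple[str, ...] = tuple(f for f in FEATURES if f.endswith(".sd"))

DEFAULT_FILENAME_PATTERN = "%Y_%m_%d_%H%M%S"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiPolygon:
    """A plant's region of interest as a pixel-coordinate polygon.

    Vertices are ``(x, y)`` pairs, origin at the top-left corner, 0-based.
    """

    roi_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(f"ROI {self.roi_id!r}: a polygon needs >=3 vertices")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask of the given ``(height, width)``."""
        h, w = shape
        xs = np.array([v[0] for v in self.vertices])
        ys = np.array([v[1] for v in self.vertices])
        if xs.min() < 0 or ys.min() < 0 or xs.max() > w - 1 or ys.max() > h - 1:
            raise ValueError(
                f"ROI {self.roi_id!r}: vertices outside image bounds {w}x{h}"
            )
        rr, cc = _sk_polygon(ys, xs, shape=shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        if not m.any():
            raise ValueError(f"ROI {self.roi_id!r}: rasterized mask is empty")
        return m


@dataclass
class ImageFrame:
    """One timestamped 8-bit RGB camera frame."""

    timestamp: dt.datetime
    pixels: np.ndarray  # (H, W, 3) uint8

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError("frame timestamp must be timezone-aware")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("frame must be height x width x 3 channels")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("digital numbers must lie in [0, 255]")
        self.pixels = px


@dataclass(frozen=True)
class ExclusionWindow:
    """A closed time window whose frames are dropped (e.g. light shows)."""

    start: dt.datetime
    end: dt.datetime
    reason: str = "excluded"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("exclusion window requires start < end")


@dataclass
class SiteConfig:
    """Camera-site configuration used by preprocessing.

    ``buffer_minutes`` shrinks the daylight window on both sides; camera
    clock is assumed UTC and converted to ``timezone`` for solar filtering
    and per-day (diel) grouping.
    """

    lat: float
    lon: float
    timezone: str = "UTC"
    buffer_minutes: int = 0
    filename_pattern: str = DEFAULT_FILENAME_PATTERN
    exclusion_windows: list[ExclusionWindow] = field(default_factory=list)

    @property
    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def pixel_statistics(px: np.ndarray, ddof: int = 1) -> dict:
    """The 16 color-index statistics of an ``(n_pixels, 3)`` DN array.

    Per-pixel indices are computed first, then the mean and sample standard
    deviation (``ddof`` denominator offset, default n-1) are taken across
    pixels.  Pixels with ``BRI = 0`` have undefined chromatic coordinates;
    they are excluded from the RI/GI/BI statistics and counted in
    ``excluded_pixels``.  If every pixel has ``BRI = 0`` the RI/GI/BI fields
    come back NaN (flagged missing).
    """
    px = np.asarray(px, dtype=np.float64)
    if px.ndim != 2 or px.shape[1] != 3 or px.shape[0] == 0:
        raise ValueError("expected a non-empty (n_pixels, 3) array")
    r, g, b = px[:, 0], px[:, 1], px[:, 2]
    bri = r + g + b
    gei = 2.0 * g - (r + b)
    lit = bri > 0

    def _stats(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return float("nan"), float("nan")
        m = float(np.mean(v))
        s = float(np.std(v, ddof=ddof)) if v.size > ddof else 0.0
        return m, s

    rec: dict = {}
    for name, v in (("r", r), ("g", g), ("b", b)):
        rec[f"{name}.av"], rec[f"{name}.sd"] = _stats(v)
    rec["bri.av"], rec["bri.sd"] = _stats(bri)
    with np.errstate(invalid="ignore"):
        for name, key in (("r", "ri"), ("g", "gi"), ("b", "bi")):
            v = {"r": r, "g": g, "b": b}[name]
            rec[f"{key}.av"], rec[f"{key}.sd"] = _stats(v[lit] / bri[lit])
    rec["gei.av"], rec["gei.sd"] = _stats(gei)
    rec["excluded_pixels"] = int((~lit).sum())
    return rec


def extract_features(frame: ImageFrame, roi: RoiPolygon, ddof: int = 1) -> dict:
    """Compute the 16 color indices of one frame inside one ROI.

    See :func:`pixel_statistics` for the per-pixel/summary convention and
    the BRI = 0 exclusion rule.
    """
    mask = roi.mask(frame.pixels.shape[:2])
    px = frame.pixels[mask]
    if px.shape[0] == 0:
        raise ValueError("empty ROI mask")
    rec: dict = {"roi_id": roi.roi_id, "timestamp": frame.timestamp}
    rec.update(pixel_statistics(px, ddof=ddof))
    return rec


def extract_feature_table(
    frames: Iterable[ImageFrame],
    rois: Sequence[RoiPolygon],
    ddof: int = 1,
) -> pd.DataFrame:
    """Extract features for every frame x ROI combination into one table."""
    rows = [extract_features(frame, roi, ddof=ddof) for frame in frames for roi in rois]
    if not rows:
        return pd.DataFrame(columns=["roi_id", "timestamp", *FEATURES, "excluded_pixels"])
    df = pd.DataFrame(rows)
    return df[["roi_id", "timestamp", *FEATURES, "excluded_pixels"]]


# ---------------------------------------------------------------------------
# frame / ROI / table I/O
# ---------------------------------------------------------------------------

def parse_timestamp(
    filename: str,
    pattern: str = DEFAULT_FILENAME_PATTERN,
    tz: str = "UTC",
) -> dt.datetime:
    """Parse a frame timestamp from an image file name (extension ignored)."""
    stem = os.path.splitext(os.path.basename(filename))[0]
    try:
        naive = dt.datetime.strptime(stem, pattern)
    except ValueError as exc:
        raise ValueError(f"cannot parse timestamp from {filename!r} with {pattern!r}") from exc
    return naive.replace(tzinfo=ZoneInfo(tz))


def read_frames(
    directory: str,
    pattern: str = DEFAULT_FILENAME_PATTERN,
    tz: str = "UTC",
) -> Iterator[ImageFrame]:
    """Lazily read all JPEG/PNG frames in a directory, sorted by timestamp."""
    names = [
        n for n in sorted(os.listdir(directory))
        if n.lower().endswith((".jpg", ".jpeg", ".png"))
    ]
    stamped = sorted((parse_timestamp(n, pattern, tz), n) for n in names)
    for ts, name in stamped:
        with Image.open(os.path.join(directory, name)) as im:
            px = np.asarray(im.convert("RGB"))
        yield ImageFrame(timestamp=ts, pixels=px)


def read_rois(path: str) -> list[RoiPolygon]:
    """Read ROI polygons from JSON: ``{roi_id: [[x, y], ...], ...}``."""
    with open(path) as fh:
        raw = json.load(fh)
    return [RoiPolygon(roi_id, tuple(map(tuple, verts))) for roi_id, verts in raw.items()]


def write_rois(rois: Sequence[RoiPolygon], path: str) -> None:
    with open(path, "w") as fh:
        json.dump({r.roi_id: [list(v) for v in r.vertices] for r in rois}, fh, indent=1)


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).map(lambda t: t.isoformat())
    out.to_csv(path, index=False)


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


# ---------------------------------------------------------------------------
# preprocessing filters
# ---------------------------------------------------------------------------

def solar_window_filter(
    records: pd.DataFrame,
    site: SiteConfig,
    buffer_minutes: int | None = None,
    schedule: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Retain records between local sunrise+buffer and sunset-buffer.

    Sunrise/sunset come from the built-in solar routine, or from a
    user-supplied ``schedule`` table with columns ``date, sunrise, sunset``
    (tz-aware datetimes) which also serves as the polar-day/night fallback.
    """
    if records.empty:
        return records
    buf = dt.timedelta(minutes=site.buffer_minutes if buffer_minutes is None else buffer_minutes)
    ts = pd.to_datetime(records["timestamp"])
    local_dates = ts.dt.tz_convert(site.tzinfo).dt.date

    table: dict[dt.date, tuple[dt.datetime, dt.datetime]] = {}
    if schedule is not None:
        for _, row in schedule.iterrows():
            d = pd.Timestamp(row["date"]).date()
            table[d] = (pd.Timestamp(row["sunrise"]), pd.Timestamp(row["sunset"]))

    keep = np.zeros(len(records), dtype=bool)
    for d in pd.unique(local_dates):
        if d in table:
            rise, sset = table[d]
        else:
            rise, sset = solar.sun_times(d, site.lat, site.lon)
        sel = (local_dates == d).to_numpy()
        keep[sel] = (ts[sel] >= rise + buf) & (ts[sel] <= sset - buf)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("solar_window_filter: dropped %d of %d records", dropped, len(records))
    return records.loc[keep]


def exclusion_filter(
    records: pd.DataFrame,
    windows: Sequence[ExclusionWindow],
) -> pd.DataFrame:
    """Drop records inside any exclusion window; drop counts logged per reason."""
    if records.empty or not windows:
        return records
    ts = pd.to_datetime(records["timestamp"])
    drop = pd.Series(False, index=records.index)
    per_reason: dict[str, int] = {}
    for w in windows:
        in_w = (ts >= w.start) & (ts <= w.end)
        per_reason[w.reason] = per_reason.get(w.reason, 0) + int((in_w & ~drop).sum())
        drop |= in_w
    for reason, n in per_reason.items():
        logger.info("exclusion_filter[%s]: dropped %d records", reason, n)
    return records.loc[~drop]


def zero_sd_filter(records: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Drop records whose ROI was too dark: any SD feature equal to zero.

    A zero within-ROI standard deviation on any of the 8 SD features is the
    signature of an under-exposed (night) frame.  Equality is tested within
    ``tol``; missing chromatic coordinates (all-dark ROI) imply zero raw-
    channel SDs and are therefore dropped by the same rule.
    """
    if records.empty:
        return records
    sds = records[list(SD_FEATURES)].to_numpy(dtype=float)
    bad = (np.abs(sds) <= tol) | np.isnan(sds)
    keep = ~bad.any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zero_sd_filter: dropped %d of %d records", dropped, len(records))
    return records.loc[keep]


def preprocess(
    records: pd.DataFrame,
    site: SiteConfig,
    schedule: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the three standard filters (solar window, exclusions, zero-SD)."""
    out = solar_window_filter(records, site, schedule=schedule)
    out = exclusion_filter(out, site.exclusion_windows)
    return zero_sd_filter(out)
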