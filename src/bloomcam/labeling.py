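"""Binary flowering labels from dated BBCH field observations.

Field visits record a two-digit BBCH growth-stage code per plant.  Codes 61
through 67 mark the flowering phase (61 = 10% open flowers, 65 = full
flowering, 67 = most petals dry or fallen); 60, 68 and 69 are transitional
edges of the phase.  Because visits happen every few days, the exact first
and last flowering days are uncertain, and three labeling treatments handle
that uncertainty differently:

* ``A`` — observer's perspective: days inside the observed BBCH 61-67
  interval are flowering, everything else (including 60, 68, 69 days) is
  non-flowering.
* ``B`` — uncertain-data removal: records on days between the last
  observation with no signs of flowering and the first in-range
  observation, and symmetrically after the phase, are dropped entirely.
* ``C`` — semi-supervised relabeling: a confident core (BBCH 62-67 days as
  positives, ten-day windows beyond the flanking no-signs observations as
  negatives) trains an inner classifier that predicts the labels of the
  ambiguous transitional days.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import kknn, tuning
from .kknn import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

FLOWERING_LOW, FLOWERING_HIGH = 61, 67
#: codes showing any sign of the flowering phase (transitional edges included)
SIGNS_LOW, SIGNS_HIGH = 60, 69


@dataclass(frozen=True)
class BbchObservation:
    plant: str
    date: dt.date
    bbch: int

    def __post_init__(self) -> None:
        if not 0 <= self.bbch <= 99:
            raise ValueError(f"BBCH code must be a two-digit code 00-99, got {self.bbch}")

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


@dataclass(frozen=True)
class FloweringInterval:
    """Observed [first, last] flowering day of year (BBCH 61-67)."""

    onset_doy: int
    end_doy: int
    year: int

    def __post_init__(self) -> None:
        if not self.onset_doy <= self.end_doy:
            raise ValueError("onset_doy must not exceed end_doy")
        if not (1 <= self.onset_doy <= 366 and 1 <= self.end_doy <= 366):
            raise ValueError("DOYs must lie in [1, 366]")


@dataclass
class LabeledDataset:
    treatment: str
    records: pd.DataFrame            # feature table + "class" column
    removed_days: list[int] = field(default_factory=list)
    inferred_days: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# observation I/O
# ---------------------------------------------------------------------------

def read_observations(path: str) -> list[BbchObservation]:
    """Read and validate a CSV of columns ``plant, date, bbch``."""
    df = pd.read_csv(path, dtype={"plant": str})
    for col in ("plant", "date", "bbch"):
        if col not in df.columns:
            raise ValueError(f"observations file must have a {col!r} column")
    obs: list[BbchObservation] = []
    seen: dict[tuple[str, dt.date], int] = {}
    for i, row in df.iterrows():
        try:
            date = dt.date.fromisoformat(str(row["date"]))
            code = int(row["bbch"])
            o = BbchObservation(plant=str(row["plant"]), date=date, bbch=code)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid observation in row {i}: {exc}") from exc
        key = (o.plant, o.date)
        if key in seen and seen[key] != o.bbch:
            raise ValueError(
                f"row {i}: duplicate observation for {o.plant} on {o.date} "
                f"with conflicting codes {seen[key]} and {o.bbch}"
            )
        seen[key] = o.bbch
        obs.append(o)
    return sorted(obs, key=lambda o: (o.plant, o.date))


def write_observations(obs: Sequence[BbchObservation], path: str) -> None:
    pd.DataFrame(
        {"plant": [o.plant for o in obs],
         "date": [o.date.isoformat() for o in obs],
         "bbch": [o.bbch for o in obs]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interval and flank helpers
# ---------------------------------------------------------------------------

def _in_range(o: BbchObservation) -> bool:
    return FLOWERING_LOW <= o.bbch <= FLOWERING_HIGH


def _no_signs(o: BbchObservation) -> bool:
    return not SIGNS_LOW <= o.bbch <= SIGNS_HIGH


def flowering_interval(
    observations: Sequence[BbchObservation],
    extend_before: int = 0,
    extend_after: int = 0,
) -> FloweringInterval:
    """First-to-last observed BBCH 61-67 day, optionally edge-extended.

    The optional per-side extension (in days) compensates for observation
    gaps at the phase edges when corroborating information (e.g. other
    seasons of the same plant) justifies it; it defaults to off.
    """
    inr = sorted((o for o in observations if _in_range(o)), key=lambda o: o.date)
    if not inr:
        raise ValueError("no flowering observed (no observation with BBCH 61-67)")
    onset, end = inr[0], inr[-1]
    return FloweringInterval(
        onset_doy=onset.doy - extend_before,
        end_doy=end.doy + extend_after,
        year=onset.date.year,
    )


def _flanks(observations: Sequence[BbchObservation]):
    """Last no-signs observation before, and first after, the flowering phase."""
    obs = sorted(observations, key=lambda o: o.date)
    inr = [o for o in obs if _in_range(o)]
    first, last = inr[0], inr[-1]
    pre = [o for o in obs if o.date < first.date and _no_signs(o)]
    post = [o for o in obs if o.date > last.date and _no_signs(o)]
    return (pre[-1] if pre else None), (post[0] if post else None), first, last


def _record_days(records: pd.DataFrame, timezone: str | None = None) -> pd.Series:
    ts = pd.to_datetime(records["timestamp"])
    if timezone is not None:
        ts = ts.dt.tz_convert(timezone)
    return ts.dt.dayofyear, ts.dt.year


# ---------------------------------------------------------------------------
# treatments
# ---------------------------------------------------------------------------

def label_treatment_a(
    records: pd.DataFrame,
    observations: Sequence[BbchObservation],
    timezone: str | None = None,
    extend_before: int = 0,
    extend_after: int = 0,
) -> LabeledDataset:
    """Treatment A: the observed interval is flowering, all else is not."""
    interval = flowering_interval(observations, extend_before, extend_after)
    doy, year = _record_days(records, timezone)
    pos = (year == interval.year) & (doy >= interval.onset_doy) & (doy <= interval.end_doy)
    out = records.copy()
    out["class"] = pos.map({True: POSITIVE, False: NEGATIVE}).to_numpy()
    return LabeledDataset(treatment="A", records=out)


def label_treatment_b(
    records: pd.DataFrame,
    observations: Sequence[BbchObservation],
    timezone: str | None = None,
) -> LabeledDataset:
    """Treatment B: drop the uncertain transitional days, label the rest as A.

    Uncertain days are those strictly between the last no-signs observation
    (BBCH outside 60-69) and the first BBCH 61-67 observation, and strictly
    between the last in-range observation and the first no-signs observation
    after blooming; BBCH 60/68/69 observation days inside those gaps are
    removed as well.  A missing flank degenerates to treatment A on that
    side.
    """
    a = label_treatment_a(records, observations, timezone)
    pre, post, first, last = _flanks(observations)
    interval_year = first.date.year
    removed: set[int] = set()
    if pre is not None:
        removed |= set(range(pre.doy + 1, first.doy))
    else:
        warnings.warn("treatment B: no no-signs observation before flowering; "
                      "keeping treatment-A labels on that side", stacklevel=2)
    if post is not None:
        removed |= set(range(last.doy + 1, post.doy))
    else:
        warnings.warn("treatment B: no no-signs observation after flowering; "
                      "keeping treatment-A labels on that side", stacklevel=2)
    doy, year = _record_days(records, timezone)
    drop = (year == interval_year) & doy.isin(removed)
    out = a.records.loc[(~drop).to_numpy()]
    return LabeledDataset(treatment="B", records=out, removed_days=sorted(removed))


@dataclass(frozen=True)
class InnerModelConfig:
    """Configuration of treatment C's inner semi-supervised classifier."""

    scheme: tuning.SubsampleScheme = tuning.SubsampleScheme()
    k_grid: tuple[int, ...] = tuning.K_GRID
    kernels: tuple[str, ...] = kknn.KERNELS
    patience: int = 30
    seed: int = 0
    window_days: int = 10


def label_treatment_c(
    records: pd.DataFrame,
    observations: Sequence[BbchObservation],
    inner: InnerModelConfig | None = None,
    timezone: str | None = None,
) -> LabeledDataset:
    """Treatment C: semi-supervised relabeling of the transitional days.

    A confident core is built from the observed BBCH 62-67 day span
    (positives) and the ``window_days`` days ending at / starting from the
    flanking no-signs observations (negatives).  An inner classifier, tuned
    on this core with the usual k/kernel search, predicts the class of the
    remaining transitional gap days; everywhere else the labels equal
    treatment A's.
    """
    inner = inner or InnerModelConfig()
    a = label_treatment_a(records, observations, timezone)
    pre, post, first, last = _flanks(observations)
    interval_year = first.date.year

    core62 = sorted(o.doy for o in observations if 62 <= o.bbch <= FLOWERING_HIGH)
    if not core62:
        warnings.warn("treatment C: no BBCH 62-67 observation; returning treatment-A "
                      "labels", stacklevel=2)
        return LabeledDataset(treatment="C", records=a.records)
    core_start, core_end = core62[0], core62[-1]

    neg_days: set[int] = set()
    gap_days: set[int] = set()
    if pre is not None:
        neg_days |= set(range(pre.doy - inner.window_days + 1, pre.doy + 1))
        gap_days |= set(range(pre.doy + 1, core_start))
    if post is not None:
        neg_days |= set(range(post.doy, post.doy + inner.window_days))
        gap_days |= set(range(core_end + 1, post.doy))

    doy, year = _record_days(records, timezone)
    doy = doy.to_numpy()
    in_year = (year == interval_year).to_numpy()
    core_pos = in_year & (doy >= core_start) & (doy <= core_end)
    core_neg = in_year & pd.Series(doy).isin(neg_days).to_numpy()
    gap = in_year & pd.Series(doy).isin(gap_days).to_numpy()

    out = a.records.copy()
    out.loc[core_pos, "class"] = POSITIVE
    out.loc[core_neg, "class"] = NEGATIVE

    if not gap.any():
        logger.info("treatment C: no transitional records to relabel; result equals "
                    "core plus treatment-A labels")
        return LabeledDataset(treatment="C", records=out)

    core = out.loc[core_pos | core_neg]
    try:
        result = tuning.tune_k_kernel(
            core, inner.scheme, k_grid=inner.k_grid, kernels=inner.kernels,
            patience=inner.patience, seed=inner.seed,
        )
        model = kknn.fit(core, result.best)
    except ValueError as exc:
        warnings.warn(f"treatment C: inner model could not be trained ({exc}); "
                      "keeping treatment-A labels on transitional days", stacklevel=2)
        return LabeledDataset(treatment="C", records=out)
    pred, _ = kknn.predict(model, out.loc[gap])
    out.loc[gap, "class"] = pred
    return LabeledDataset(
        treatment="C", records=out,
        inferred_days=sorted(set(doy[gap].tolist())),
    )
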