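"""Diel (per-day) aggregation of image predictions and phenology metrics.

Per-image predictions are aggregated to one flowering/non-flowering call per
day of year: a day is flowering when at least ``threshold`` percent of its
retained images were predicted positive (inclusive inequality, default
50%).  The year is partitioned into three assessment periods — the observed
flowering interval (BBCH 61-67), the flowering extremes (transitional gaps
between the flanking observations and the interval) and the remaining
non-flowering days — and model quality is summarized by the onset day shift
(ODS, predicted minus observed onset) and the flowering days share (FDS,
percent of a period's days classified as flowering).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .kknn import POSITIVE
from .labeling import (
    BbchObservation,
    FloweringInterval,
    _flanks,
    flowering_interval,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeriodPartition:
    """Disjoint day-of-year sets covering all days with retained images."""

    flowering: frozenset
    extremes: frozenset
    non_flowering: frozenset

    @property
    def covered(self) -> frozenset:
        return self.flowering | self.extremes | self.non_flowering


@dataclass(frozen=True)
class OnsetResult:
    od_pred: int
    od_obs: int

    @property
    def ods(self) -> int:
        return self.od_pred - self.od_obs


@dataclass(frozen=True)
class FdsResult:
    period: str
    fd_pred: int
    fd_obs: int

    @property
    def fds(self) -> float:
        return self.fd_pred * 100.0 / self.fd_obs

    @property
    def fds_rounded(self) -> float:
        """FDS to one decimal place, the reporting convention."""
        return round(self.fds, 1)


def aggregate_diel(
    predictions: pd.DataFrame,
    threshold: float = 50.0,
    timezone: str | None = None,
) -> pd.DataFrame:
    """Aggregate per-image classes to per-DOY classes.

    ``predictions`` needs ``timestamp`` and ``class`` columns.  Returns a
    frame with columns ``doy, P, N, cl, covered`` holding one row per day
    that has at least one retained image; days without images are uncovered
    and simply absent (they enter no period count).
    """
    if not 0.0 < threshold <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    ts = pd.to_datetime(predictions["timestamp"])
    if timezone is not None:
        ts = ts.dt.tz_convert(timezone)
    doy = ts.dt.dayofyear
    pos = (predictions["class"] == POSITIVE).groupby(doy.to_numpy()).agg(["sum", "count"])
    out = pd.DataFrame({
        "doy": pos.index.astype(int),
        "P": pos["sum"].astype(int).to_numpy(),
        "N": (pos["count"] - pos["sum"]).astype(int).to_numpy(),
    })
    out["cl"] = (out["P"] * 100.0 / (out["P"] + out["N"]) >= threshold).astype(int)
    out["covered"] = True
    return out.reset_index(drop=True)


def predicted_onset(diel: pd.DataFrame, rule: str = "longest_run") -> int:
    """Predicted onset day from the diel classes.

    ``longest_run`` (default) returns the first day of the longest maximal
    run of consecutive flowering days (earliest run on ties), so isolated
    out-of-season positives — snow days, lighting artifacts — cannot set
    the onset.  ``first_positive`` returns the first flowering day.
    """
    days = np.sort(diel.loc[diel["cl"] == 1, "doy"].to_numpy())
    if days.size == 0:
        raise ValueError("no flowering predicted")
    if rule == "first_positive":
        return int(days[0])
    if rule != "longest_run":
        raise ValueError(f"unknown onset rule {rule!r}")
    breaks = np.where(np.diff(days) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [days.size - 1]))
    lengths = ends - starts + 1
    best = int(np.argmax(lengths))  # argmax takes the earliest run on ties
    return int(days[starts[best]])


def onset_day_shift(od_pred: int, od_obs: int) -> int:
    """Signed onset day shift: predicted minus observed onset DOY."""
    return int(od_pred) - int(od_obs)


def partition_periods(
    observations: Sequence[BbchObservation],
    covered_days: Sequence[int],
) -> PeriodPartition:
    """Partition covered days into flowering / extremes / non-flowering.

    The extremes are the days strictly between the last observation before
    flowering and the observed onset, plus the days strictly between the
    observed end and the first observation after the phase that shows no
    signs of flowering (BBCH 68/69 observation days therefore fall in the
    extremes).
    """
    interval = flowering_interval(observations)
    covered = frozenset(int(d) for d in covered_days)
    flowering = frozenset(range(interval.onset_doy, interval.end_doy + 1)) & covered

    obs = sorted(observations, key=lambda o: o.date)
    pre_all = [o for o in obs if o.doy < interval.onset_doy and o.date.year == interval.year]
    pre, post, _, _ = _flanks(observations)
    extremes: set[int] = set()
    if pre_all:
        extremes |= set(range(pre_all[-1].doy + 1, interval.onset_doy))
    if post is not None:
        extremes |= set(range(interval.end_doy + 1, post.doy))
    extremes_f = frozenset(extremes) & covered - flowering
    non_flowering = covered - flowering - extremes_f
    return PeriodPartition(
        flowering=flowering, extremes=extremes_f, non_flowering=non_flowering
    )


def fds(diel: pd.DataFrame, period_days, period_name: str) -> FdsResult:
    """Flowering days share of one period: predicted days x 100 / period days."""
    period = {int(d) for d in period_days}
    if not period:
        raise ValueError(f"period {period_name!r} contains no days")
    fd_pred = int(diel.loc[diel["doy"].isin(period), "cl"].sum())
    return FdsResult(period=period_name, fd_pred=fd_pred, fd_obs=len(period))


def flowering_duration(interval: FloweringInterval) -> int:
    """Inclusive flowering duration in days (onset and end both count)."""
    return interval.end_doy - interval.onset_doy + 1


def evaluation_report(
    predictions: pd.DataFrame,
    observations: Sequence[BbchObservation],
    threshold: float = 50.0,
    onset_rule: str = "longest_run",
    timezone: str | None = None,
) -> dict:
    """Bundle diel classes, period FDS, ODS and duration into one report.

    ``predictions`` must carry ``timestamp`` and ``class`` columns and may
    carry a ``true_class`` column, in which case image-level REC/PREC/F are
    included.  Observations must belong to the predicted year.
    """
    from . import kknn  # local import to avoid cycle at module load

    interval = flowering_interval(observations)
    years = pd.to_datetime(predictions["timestamp"]).dt.year.unique()
    if interval.year not in years:
        raise ValueError(
            f"observations are from {interval.year} but predictions cover {sorted(years)}"
        )

    diel_df = aggregate_diel(predictions, threshold=threshold, timezone=timezone)
    partition = partition_periods(observations, diel_df["doy"].tolist())

    report: dict = {
        "threshold": threshold,
        "observed_onset": interval.onset_doy,
        "observed_end": interval.end_doy,
        "observed_duration": flowering_duration(interval),
        "diel": diel_df,
        "partition": partition,
    }
    try:
        od_pred = predicted_onset(diel_df, rule=onset_rule)
        report["onset"] = OnsetResult(od_pred=od_pred, od_obs=interval.onset_doy)
        report["ods"] = report["onset"].ods
    except ValueError:
        logger.warning("no flowering predicted; onset shift undefined")
        report["onset"] = None
        report["ods"] = None
        report["no_flowering_predicted"] = True

    report["fds"] = {}
    for name, days in (
        ("flowering", partition.flowering),
        ("extremes", partition.extremes),
        ("non_flowering", partition.non_flowering),
    ):
        report["fds"][name] = fds(diel_df, days, name) if days else None

    if "true_class" in predictions.columns:
        counts = kknn.confusion(
            predictions["class"].to_numpy(), predictions["true_class"].to_numpy()
        )
        report["image_metrics"] = kknn.rec_prec_fbeta(counts)
        report["confusion"] = counts
    return report
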