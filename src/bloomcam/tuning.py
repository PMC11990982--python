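"""Subsampling validation, k/kernel grid tuning and dataset transformations.

Model selection follows a recall-first strategy: with a whole growing season
in the data, the flowering class is rare and the cost of a false positive is
low, so candidates are ranked by mean recall over repeated 75/25 subsampling
splits.  The (k, kernel) grid — odd k in 3..15 crossed with the ten kernels,
70 candidates — is walked in a seeded random order and the search stops
after 30 consecutive evaluations without recall progress.

Two dataset transformations are provided besides the identity (``nt``):
``fs`` greedy forward feature selection, and ``df`` a per-day filter that
drops the half of each day's records with the lower green-excess-index
standard deviation (gei.sd), which removes poorly exposed frames.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import kknn
from .features import FEATURES
from .kknn import KERNELS, KknnConfig

logger = logging.getLogger(__name__)

K_GRID: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15)
TRANSFORMATIONS: tuple[str, ...] = ("nt", "fs", "df", "fs.df")


@dataclass(frozen=True)
class SubsampleScheme:
    """Repeated random 75/25 train/test subsampling."""

    train_fraction: float = 0.75
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class TuningResult:
    best: KknnConfig
    table: pd.DataFrame          # columns: k, kernel, rec, prec, fbeta
    order: list[tuple[int, str]]
    n_evaluated: int


def subsample_splits(
    n: int, scheme: SubsampleScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw the train/test index pairs for each repetition (seeded)."""
    if n < 4:
        raise ValueError(f"need at least 4 records to subsample, got {n}")
    rng = np.random.default_rng(scheme.seed)
    n_train = math.ceil(scheme.train_fraction * n)
    splits = []
    for _ in range(scheme.repetitions):
        perm = rng.permutation(n)
        splits.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return splits


def evaluate_config(
    dataset,
    config: KknnConfig,
    scheme: SubsampleScheme,
    feature_names: Sequence[str] | None = None,
) -> kknn.Metrics:
    """Mean REC/PREC/F over the subsampling repetitions for one config.

    Splits depend only on the scheme seed, so every candidate is scored on
    identical resampling instances.
    """
    df = getattr(dataset, "records", dataset).reset_index(drop=True)
    splits = subsample_splits(len(df), scheme)
    recs, precs, fbetas = [], [], []
    for train_idx, test_idx in splits:
        train, test = df.iloc[train_idx], df.iloc[test_idx]
        model = kknn.fit(train, config, feature_names=feature_names)
        pred, _ = kknn.predict(model, test)
        m = kknn.rec_prec_fbeta(kknn.confusion(pred, test["class"].to_numpy()))
        recs.append(m.rec)
        precs.append(m.prec)
        fbetas.append(m.fbeta)
    return kknn.Metrics(
        rec=float(np.mean(recs)), prec=float(np.mean(precs)), fbeta=float(np.mean(fbetas))
    )


def tune_k_kernel(
    dataset,
    scheme: SubsampleScheme,
    k_grid: Sequence[int] = K_GRID,
    kernels: Sequence[str] = KERNELS,
    patience: int = 30,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> TuningResult:
    """Grid-search (k, kernel) by mean subsampling recall.

    Candidates are visited in a seeded random permutation; the search
    terminates after ``patience`` consecutive evaluations without strict
    recall improvement (progress threshold 0) or when the grid is exhausted.
    Infeasible candidates (e.g. k+1 exceeding a training split) are skipped
    with a warning and still count as evaluations without progress.
    """
    grid = list(itertools.product(k_grid, kernels))
    rng = np.random.default_rng(seed)
    order = [grid[i] for i in rng.permutation(len(grid))]

    rows = []
    best: KknnConfig | None = None
    best_rec = -np.inf
    since_progress = 0
    n_eval = 0
    for k, kernel in order:
        cfg = KknnConfig(k=k, kernel=kernel)
        try:
            m = evaluate_config(dataset, cfg, scheme, feature_names=feature_names)
        except ValueError as exc:
            warnings.warn(f"skipping infeasible candidate k={k}, kernel={kernel}: {exc}",
                          stacklevel=2)
            m = kknn.Metrics(rec=np.nan, prec=np.nan, fbeta=np.nan)
        n_eval += 1
        rows.append({"k": k, "kernel": kernel, "rec": m.rec, "prec": m.prec,
                     "fbeta": m.fbeta})
        if np.isfinite(m.rec) and m.rec > best_rec:
            best_rec, best = m.rec, cfg
            since_progress = 0
        else:
            since_progress += 1
            if since_progress >= patience:
                break
    if best is None:
        raise ValueError("no feasible (k, kernel) candidate could be evaluated")
    logger.info("tune_k_kernel: best k=%d kernel=%s rec=%.4f after %d evaluations",
                best.k, best.kernel, best_rec, n_eval)
    return TuningResult(best=best, table=pd.DataFrame(rows), order=order[:n_eval],
                        n_evaluated=n_eval)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def gei_sd_diel_filter(records: pd.DataFrame, timezone: str | None = None) -> pd.DataFrame:
    """Per local day, drop records with gei.sd strictly below the day median.

    gei.sd pools contrast information from all three channels; frames biased
    by unfavourable exposure (shadowing, haze) sit low on it within their
    day.  Ties at the median are retained, so every day keeps at least half
    of its records and single-record days are untouched.
    """
    if records.empty:
        return records
    ts = pd.to_datetime(records["timestamp"])
    if timezone is not None:
        ts = ts.dt.tz_convert(timezone)
    day = ts.dt.date
    med = records.groupby(day)["gei.sd"].transform("median")
    return records.loc[records["gei.sd"] >= med]


def forward_feature_selection(
    dataset,
    scheme: SubsampleScheme,
    base_config: KknnConfig,
    candidate_features: Sequence[str] = FEATURES,
    explicit: Sequence[str] | None = None,
) -> list[str]:
    """Greedy forward wrapper selection maximizing mean subsampling recall.

    Adds one feature at a time while the mean recall strictly improves;
    ties break toward fewer features, then toward the documented canonical
    feature order.  An ``explicit`` feature list (e.g. a previously
    calibrated per-plant set) is passed through unchanged.
    """
    if explicit is not None:
        return list(explicit)
    selected: list[str] = []
    best_rec = -np.inf
    remaining = [f for f in candidate_features]
    while remaining:
        scores = []
        for f in remaining:
            m = evaluate_config(dataset, base_config, scheme,
                                feature_names=selected + [f])
            scores.append(m.rec)
        i_best = int(np.argmax(scores))  # first max: canonical order breaks ties
        if scores[i_best] > best_rec:
            best_rec = scores[i_best]
            selected.append(remaining.pop(i_best))
        else:
            break
    return selected


def apply_transformation(
    train: pd.DataFrame,
    transformation: str,
    scheme: SubsampleScheme,
    config: KknnConfig,
    timezone: str | None = None,
    explicit_features: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Materialize one of nt/fs/df/fs.df on a labeled training table.

    Returns the (possibly filtered) training table and the feature list to
    train on.  When ``df`` is active the same filter must also be applied to
    the test records (see :func:`gei_sd_diel_filter`).
    """
    if transformation not in TRANSFORMATIONS:
        raise ValueError(f"unknown transformation {transformation!r}")
    out = train
    if "df" in transformation.split("."):
        out = gei_sd_diel_filter(out, timezone=timezone)
    feats = list(FEATURES)
    if "fs" in transformation.split("."):
        feats = forward_feature_selection(
            out, scheme, config, explicit=explicit_features
        )
    return out, feats
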