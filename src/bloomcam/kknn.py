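"""Kernel-weighted k-nearest-neighbors binary classifier, from scratch.

A memory-based ("lazy") classifier: training consists of storing the
standardized feature matrix.  For a query, distances to all training rows
are computed (Minkowski, p=2 by default), the k nearest are taken, their
distances are normalized by the distance of the (k+1)-th neighbor so they
fall in [0, 1], a kernel converts each normalized distance into a vote
weight, and the class with the larger summed weight wins.  With the
rectangular kernel this reduces exactly to the classic unweighted majority
vote.

Ten kernels are supported: rectangular, triangular, epanechnikov, biweight,
triweight, cos, inv, gaussian, rank and optimal.  Multiplicative constants
that cannot change the argmax are immaterial and are simplified where
convenient.  The ``rank`` and ``optimal`` kernels weight neighbors by their
rank rather than by the distance value itself.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .features import FEATURES

POSITIVE = "flowering"
NEGATIVE = "non-flowering"

KERNELS: tuple[str, ...] = (
    "rectangular", "triangular", "epanechnikov", "biweight", "triweight",
    "cos", "inv", "gaussian", "rank", "optimal",
)

#: cap for the inverse-distance kernel as d -> 0, to keep votes finite
INV_CAP = 1e12

__all__ = [
    "POSITIVE", "NEGATIVE", "KERNELS", "KknnConfig", "KknnModel",
    "ConfusionCounts", "Metrics", "fit", "predict", "kernel_weight",
    "confusion", "rec_prec_fbeta", "featureless_baseline", "FeaturelessModel",
]


@dataclass(frozen=True)
class KknnConfig:
    """Hyperparameters of the classifier.

    k must be odd (>= 3) so unweighted votes cannot tie; exact weighted-vote
    ties can still occur and resolve to the non-flowering class.
    """

    k: int = 7
    kernel: str = "optimal"
    p: float = 2.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.k < 3 or self.k % 2 == 0:
            raise ValueError(f"k must be an odd integer >= 3, got {self.k}")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {KERNELS}")


@dataclass
class KknnModel:
    X: np.ndarray                  # (n_train, n_features), standardized
    y: np.ndarray                  # (n_train,) int8, 1 = flowering
    feature_names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    config: KknnConfig

    def save(self, path: str) -> None:
        """Serialize to a portable JSON file."""
        payload = {
            "feature_names": list(self.feature_names),
            "X": self.X.tolist(),
            "y": self.y.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "config": {
                "k": self.config.k, "kernel": self.config.kernel,
                "p": self.config.p, "standardize": self.config.standardize,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "KknnModel":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            X=np.asarray(raw["X"], dtype=float),
            y=np.asarray(raw["y"], dtype=np.int8),
            feature_names=tuple(raw["feature_names"]),
            center=np.asarray(raw["center"], dtype=float),
            scale=np.asarray(raw["scale"], dtype=float),
            config=KknnConfig(**raw["config"]),
        )


def _extract_xy(dataset, feature_names: Sequence[str] | None):
    """Accept a LabeledDataset or a DataFrame with a ``class`` column."""
    df = getattr(dataset, "records", dataset)
    names = tuple(feature_names) if feature_names else tuple(
        f for f in FEATURES if f in df.columns
    )
    missing = [f for f in names if f not in df.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    X = df[list(names)].to_numpy(dtype=float)
    y = (df["class"].to_numpy() == POSITIVE).astype(np.int8)
    return X, y, names


def fit(dataset, config: KknnConfig, feature_names: Sequence[str] | None = None) -> KknnModel:
    """Memorize the (standardized) training matrix.

    Standardization statistics are computed on the training data only.  A
    constant column gets scale 1 (with a warning) rather than dividing by
    zero.
    """
    X, y, names = _extract_xy(dataset, feature_names)
    n = X.shape[0]
    if config.k + 1 > n:
        raise ValueError(f"need at least k+1={config.k + 1} training records, got {n}")
    if y.min() == y.max():
        raise ValueError("training data must contain both classes")
    if np.isnan(X).any():
        raise ValueError("training matrix contains missing values")
    if config.standardize:
        center = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        flat = scale <= 0
        if flat.any():
            warnings.warn(
                f"constant feature column(s) {[names[i] for i in np.where(flat)[0]]}: "
                "scale set to 1", stacklevel=2,
            )
            scale = np.where(flat, 1.0, scale)
    else:
        center = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    return KknnModel(
        X=(X - center) / scale, y=y, feature_names=names,
        center=center, scale=scale, config=config,
    )


def kernel_weight(kernel: str, d, k: int | None = None, dim: int | None = None):
    """Vote weight(s) for normalized neighbor distance(s) ``d`` in [0, 1].

    Distance-based kernels are evaluated elementwise.  For the rank-based
    kernels (``rank``, ``optimal``) the last axis of ``d`` must hold the k
    sorted neighbor distances of one query: ``rank`` assigns k+1-i to the
    i-th nearest neighbor, and ``optimal`` assigns the asymptotically
    optimal rank weights for a ``dim``-dimensional feature space.
    """
    d = np.asarray(d, dtype=float)
    if kernel == "rectangular":
        return np.ones_like(d)
    if kernel == "triangular":
        return np.clip(1.0 - d, 0.0, None)
    if kernel == "epanechnikov":
        return 0.75 * np.clip(1.0 - d**2, 0.0, None)
    if kernel == "biweight":
        return (15.0 / 16.0) * np.clip(1.0 - d**2, 0.0, None) ** 2
    if kernel == "triweight":
        return (35.0 / 32.0) * np.clip(1.0 - d**2, 0.0, None) ** 3
    if kernel == "cos":
        return (math.pi / 4.0) * np.cos(np.clip(d, 0.0, 1.0) * math.pi / 2.0)
    if kernel == "inv":
        with np.errstate(divide="ignore"):
            return np.minimum(np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), INV_CAP), INV_CAP)
    if kernel == "gaussian":
        return np.exp(-0.5 * d**2)
    if kernel in ("rank", "optimal"):
        if k is None:
            k = d.shape[-1]
        if d.shape[-1] != k:
            raise ValueError(f"{kernel} kernel needs the k={k} sorted neighbor distances")
        if kernel == "rank":
            w = (k - np.arange(k)).astype(float)  # k+1 - rank, rank = 1..k
        else:
            dd = float(dim if dim is not None else 1)
            i = np.arange(1, k + 1, dtype=float)
            w = (1.0 / k) * (
                1.0 + dd / 2.0
                - dd / (2.0 * k ** (2.0 / dd)) * (i ** (1.0 + 2.0 / dd) - (i - 1.0) ** (1.0 + 2.0 / dd))
            )
            w = np.clip(w, 0.0, None)
        return np.broadcast_to(w, d.shape).copy()
    raise ValueError(f"unknown kernel {kernel!r}")


def predict(model: KknnModel, queries) -> tuple[np.ndarray, np.ndarray]:
    """Classify query records; returns (classes, positive-class scores).

    The score is the positive share of the summed kernel weight.  If the
    (k+1)-th neighbor distance is zero every neighbor duplicates the query
    and an unweighted vote is used; an exact weighted tie resolves to the
    non-flowering class.
    """
    if isinstance(queries, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in queries.columns]
        if missing:
            raise ValueError(f"query is missing feature columns: {missing}")
        Xq = queries[list(model.feature_names)].to_numpy(dtype=float)
    else:
        Xq = np.asarray(queries, dtype=float)
        if Xq.ndim == 1:
            Xq = Xq[None, :]
        if Xq.shape[1] != len(model.feature_names):
            raise ValueError(
                f"query has {Xq.shape[1]} features, model expects {len(model.feature_names)}"
            )
    Xq = (Xq - model.center) / model.scale
    k = model.config.k

    D = cdist(Xq, model.X, metric="minkowski", p=model.config.p)
    order = np.argsort(D, axis=1, kind="stable")  # stable: distance ties by row index
    rows = np.arange(Xq.shape[0])
    nn = order[:, :k]
    d_nn = D[rows[:, None], nn]
    d_norm = D[rows, order[:, k]]  # (k+1)-th neighbor distance

    y_nn = model.y[nn].astype(float)
    dup = d_norm <= 0.0
    W = np.empty_like(d_nn)
    if (~dup).any():
        dn = d_nn[~dup] / d_norm[~dup, None]
        W[~dup] = kernel_weight(
            model.config.kernel, dn, k=k, dim=len(model.feature_names)
        )
    if dup.any():
        W[dup] = 1.0  # all k neighbors duplicate the query: unweighted vote

    pos = (W * y_nn).sum(axis=1)
    total = W.sum(axis=1)
    neg = total - pos
    scores = np.where(total > 0, pos / np.where(total > 0, total, 1.0), 0.5)
    classes = np.where(pos > neg, POSITIVE, NEGATIVE)
    return classes, scores


# ---------------------------------------------------------------------------
# confusion-matrix metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metrics:
    rec: float
    prec: float
    fbeta: float
    undefined: frozenset = field(default_factory=frozenset)


def confusion(pred, true) -> ConfusionCounts:
    """Count TP/FP/FN/TN with the flowering class as positive."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth vectors differ in length")
    p = pred == POSITIVE
    t = true == POSITIVE
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()), tn=int((~p & ~t).sum()),
    )


def rec_prec_fbeta(counts: ConfusionCounts) -> Metrics:
    """Recall, precision and their harmonic mean (the F score).

    Zero denominators yield a defined 0 and are flagged in ``undefined``.
    """
    undef = set()
    rec = prec = fbeta = 0.0
    if counts.tp + counts.fn > 0:
        rec = counts.tp / (counts.tp + counts.fn)
    else:
        undef.add("rec")
    if counts.tp + counts.fp > 0:
        prec = counts.tp / (counts.tp + counts.fp)
    else:
        undef.add("prec")
    if prec + rec > 0:
        fbeta = 2.0 * prec * rec / (prec + rec)
    else:
        undef.add("fbeta")
    return Metrics(rec=rec, prec=prec, fbeta=fbeta, undefined=frozenset(undef))


# ---------------------------------------------------------------------------
# featureless baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeaturelessModel:
    majority: str

    def predict(self, queries) -> np.ndarray:
        n = len(queries)
        return np.full(n, self.majority, dtype=object)


def featureless_baseline(dataset) -> FeaturelessModel:
    """Baseline that always predicts the majority training class (ties -> non-flowering)."""
    df = getattr(dataset, "records", dataset)
    if len(df) == 0:
        raise ValueError("empty dataset")
    n_pos = int((df["class"] == POSITIVE).sum())
    n_neg = len(df) - n_pos
    return FeaturelessModel(majority=POSITIVE if n_pos > n_neg else NEGATIVE)
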