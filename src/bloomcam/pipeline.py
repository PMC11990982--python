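"""End-to-end workflow: label -> tune -> transform -> fit -> predict -> evaluate.

For each plant the training year is labeled under the requested treatments,
the (k, kernel) pair is tuned once per treatment on the untransformed
dataset and reused for every transformation of that treatment, a model is
fitted per treatment x transformation variant, the test year is predicted,
and the predictions are aggregated into a diel report with ODS and
per-period FDS.  A summary table with one row per variant and a per-plant
best-model selection close the loop.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import diel, kknn, labeling, tuning
from .labeling import BbchObservation, InnerModelConfig, LabeledDataset
from .tuning import SubsampleScheme, TRANSFORMATIONS

logger = logging.getLogger(__name__)

TREATMENTS: tuple[str, ...] = ("A", "B", "C")


@dataclass
class RunConfig:
    """One pipeline run over a plant set and a treatment/transformation grid."""

    train_year: int
    test_year: int
    plants: tuple[str, ...] | None = None            # None: every roi_id found
    treatments: tuple[str, ...] = TREATMENTS
    transformations: tuple[str, ...] = TRANSFORMATIONS
    threshold: float = 50.0
    onset_rule: str = "longest_run"
    scheme: SubsampleScheme = field(default_factory=SubsampleScheme)
    tune_seed: int = 0
    timezone: str | None = None
    inner: InnerModelConfig = field(default_factory=InnerModelConfig)
    #: optional per-plant explicit feature lists (skips the greedy search)
    explicit_features: dict = field(default_factory=dict)
    config_overrides: dict = field(default_factory=dict)  # plant -> KknnConfig

    def __post_init__(self) -> None:
        if self.train_year == self.test_year:
            raise ValueError("train year and test year must differ")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ValueError(f"unknown treatments: {sorted(unknown)}")
        unknown = set(self.transformations) - set(TRANSFORMATIONS)
        if unknown:
            raise ValueError(f"unknown transformations: {sorted(unknown)}")


def _label(treatment: str, records, obs, cfg: RunConfig) -> LabeledDataset:
    if treatment == "A":
        return labeling.label_treatment_a(records, obs, timezone=cfg.timezone)
    if treatment == "B":
        return labeling.label_treatment_b(records, obs, timezone=cfg.timezone)
    return labeling.label_treatment_c(records, obs, inner=cfg.inner,
                                      timezone=cfg.timezone)


def run_pipeline(
    features_by_year: dict[int, pd.DataFrame],
    observations: Sequence[BbchObservation],
    config: RunConfig,
) -> dict:
    """Execute the full grid; returns ``{"reports": [...], "summary": DataFrame}``.

    ``features_by_year`` maps the training and test years to preprocessed
    feature tables (night/exclusion/zero-SD filters already applied).  Each
    report carries full provenance: seeds, filter counts, chosen k/kernel
    and the feature list used.
    """
    for year in (config.train_year, config.test_year):
        if year not in features_by_year:
            raise ValueError(f"no feature table for year {year}")
    train_all = features_by_year[config.train_year]
    test_all = features_by_year[config.test_year]

    plants = config.plants or tuple(pd.unique(train_all["roi_id"]))
    reports: list[dict] = []
    for plant in plants:
        train_df = train_all.loc[train_all["roi_id"] == plant].reset_index(drop=True)
        test_df = test_all.loc[test_all["roi_id"] == plant].reset_index(drop=True)
        obs_train = [o for o in observations
                     if o.plant == plant and o.date.year == config.train_year]
        obs_test = [o for o in observations
                    if o.plant == plant and o.date.year == config.test_year]
        if not obs_train:
            raise ValueError(f"no training-year observations for plant {plant!r}")
        if not obs_test:
            warnings.warn(f"no test-year observations for plant {plant!r}; "
                          "evaluation limited to prediction outputs", stacklevel=2)

        for treatment in config.treatments:
            labeled = _label(treatment, train_df, obs_train, config)
            if plant in config.config_overrides:
                best = config.config_overrides[plant]
                tune_table = None
            else:
                tuned = tuning.tune_k_kernel(labeled, config.scheme,
                                             seed=config.tune_seed)
                best, tune_table = tuned.best, tuned.table
            for transformation in config.transformations:
                rep = _run_variant(
                    plant, treatment, transformation, labeled, best,
                    test_df, obs_test, config,
                )
                rep["tuning_table"] = tune_table
                reports.append(rep)
    return {"reports": reports, "summary": summarize(reports)}


def _run_variant(plant, treatment, transformation, labeled, best_config,
                 test_df, obs_test, config: RunConfig) -> dict:
    train_t, feats = tuning.apply_transformation(
        labeled.records, transformation, config.scheme, best_config,
        timezone=config.timezone,
        explicit_features=config.explicit_features.get(plant),
    )
    model = kknn.fit(train_t, best_config, feature_names=feats)
    test_t = test_df
    if "df" in transformation.split("."):
        test_t = tuning.gei_sd_diel_filter(test_df, timezone=config.timezone)
    pred, score = kknn.predict(model, test_t)
    pred_df = test_t[["roi_id", "timestamp"]].copy()
    pred_df["class"] = pred
    pred_df["score"] = score

    rep: dict = {
        "plant": plant,
        "treatment": treatment,
        "transformation": transformation,
        "variant": f"{treatment}.{transformation}",
        "k": best_config.k,
        "kernel": best_config.kernel,
        "features": list(feats),
        "scheme_seed": config.scheme.seed,
        "tune_seed": config.tune_seed,
        "threshold": config.threshold,
        "n_train": len(labeled.records),
        "n_train_used": len(train_t),
        "n_test": len(test_df),
        "n_test_used": len(test_t),
        "removed_days": labeled.removed_days,
        "inferred_days": labeled.inferred_days,
        "predictions": pred_df,
        "model": model,
    }
    if obs_test:
        truth = labeling.label_treatment_a(test_t, obs_test, timezone=config.timezone)
        pred_df["true_class"] = truth.records["class"].to_numpy()
        rep["evaluation"] = diel.evaluation_report(
            pred_df, obs_test, threshold=config.threshold,
            onset_rule=config.onset_rule, timezone=config.timezone,
        )
    return rep


def summarize(reports: Sequence[dict]) -> pd.DataFrame:
    """One row per variant, shaped like a diel-classification results table."""
    rows = []
    for rep in reports:
        row = {
            "plant": rep["plant"], "model": rep["variant"],
            "k": rep["k"], "kernel": rep["kernel"],
            "ods": None,
            "flowering_days": None, "flowering_pred": None, "flowering_fds": None,
            "extremes_days": None, "extremes_pred": None, "extremes_fds": None,
            "non_flowering_days": None, "non_flowering_pred": None,
            "non_flowering_fds": None,
        }
        ev = rep.get("evaluation")
        if ev is not None:
            row["ods"] = ev["ods"]
            for period, prefix in (("flowering", "flowering"),
                                   ("extremes", "extremes"),
                                   ("non_flowering", "non_flowering")):
                f = ev["fds"].get(period)
                if f is not None:
                    row[f"{prefix}_days"] = f.fd_obs
                    row[f"{prefix}_pred"] = f.fd_pred
                    row[f"{prefix}_fds"] = f.fds_rounded
        rows.append(row)
    return pd.DataFrame(rows)


def best_model_selection(reports: Sequence[dict]) -> dict:
    """Pick the best variant per plant from the diel results.

    Ranking (documented, configurable by re-sorting the summary): smallest
    |ODS| first (undefined onset ranks last), then highest flowering FDS,
    then lowest non-flowering FDS, then the lexicographic variant name.
    """
    def key(rep):
        ev = rep.get("evaluation") or {}
        ods = ev.get("ods")
        fl = (ev.get("fds") or {}).get("flowering")
        nf = (ev.get("fds") or {}).get("non_flowering")
        return (
            abs(ods) if ods is not None else np.inf,
            -(fl.fds if fl is not None else -np.inf),
            nf.fds if nf is not None else np.inf,
            rep["variant"],
        )

    best: dict = {}
    for rep in reports:
        plant = rep["plant"]
        if plant not in best or key(rep) < key(best[plant]):
            best[plant] = rep
    return best


def report_to_json(rep: dict, path: str) -> None:
    """Serialize one variant report (without the fitted model) to JSON."""
    ev = rep.get("evaluation")
    payload = {k: rep[k] for k in (
        "plant", "treatment", "transformation", "variant", "k", "kernel",
        "features", "scheme_seed", "tune_seed", "threshold",
        "n_train", "n_train_used", "n_test", "n_test_used",
        "removed_days", "inferred_days",
    )}
    if ev is not None:
        payload["ods"] = ev["ods"]
        payload["observed_onset"] = ev["observed_onset"]
        payload["observed_duration"] = ev["observed_duration"]
        payload["fds"] = {
            name: None if f is None else
            {"fd_pred": f.fd_pred, "fd_obs": f.fd_obs, "fds": f.fds,
             "fds_rounded": f.fds_rounded}
            for name, f in ev["fds"].items()
        }
        payload["diel"] = ev["diel"].to_dict(orient="records")
        if "image_metrics" in ev:
            m = ev["image_metrics"]
            payload["image_metrics"] = {"rec": m.rec, "prec": m.prec, "fbeta": m.fbeta}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
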