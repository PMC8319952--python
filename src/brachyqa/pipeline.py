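"""End-to-end experiment: cohort -> split -> four per-organ models -> reports.

This is the library behind the command-line interface and the QA check:
a plan whose actual D2cm3/Dprescription deviates from the model's
prediction by more than a per-organ delta threshold is flagged for
re-optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as svr
from .phantom import PhantomConfig, PlanRecord, cohort_to_frame, generate_cohort
from .structures import OAR_NAMES

FEATURE_COLS = ["V_global_cm3", "v1_cm3", "v2_cm3", "v3_cm3", "v4_cm3", "v5_cm3"]

#: default QA flag threshold on delta = |actual - predicted| ratio, per organ
DEFAULT_DELTA_THRESHOLD = 0.10


@dataclass
class ExperimentResult:
    """Trained models and evaluation reports for the four organs."""

    models: dict[str, svr.TrainedModel]
    train_reports: dict[str, svr.EvaluationReport]
    valid_reports: dict[str, svr.EvaluationReport]
    n_train: int
    n_valid: int


def organ_matrix(frame: pd.DataFrame, organ: str):
    """Feature matrix and ratio targets for one organ from the cohort table."""
    sub = frame[frame["organ"] == organ]
    return sub[FEATURE_COLS].to_numpy(), sub["ratio"].to_numpy()


def run_experiment(
    frame: pd.DataFrame,
    svr_config: svr.SVRConfig | None = None,
    n_train: int = 160,
    n_valid: int = 40,
    split_seed: int = 0,
) -> ExperimentResult:
    """Split a cohort feature table 160/40 and train/evaluate per organ.

    The split is by plan (all four organ rows of a plan stay together)
    and the validation plans are never seen during hyperparameter search.
    """
    cfg = svr_config or svr.SVRConfig()
    plan_ids = sorted(frame["plan_id"].unique())
    train_ids, valid_ids = svr.split_cohort(
        plan_ids, n_train=n_train, n_valid=n_valid, seed=split_seed
    )
    train_frame = frame[frame["plan_id"].isin(train_ids)]
    valid_frame = frame[frame["plan_id"].isin(valid_ids)]
    models, train_reports, valid_reports = {}, {}, {}
    for organ in OAR_NAMES:
        Xt, yt = organ_matrix(train_frame, organ)
        Xv, yv = organ_matrix(valid_frame, organ)
        m = svr.train_svr(Xt, yt, cfg, organ=organ)
        models[organ] = m
        train_reports[organ] = svr.evaluate(m, Xt, yt, FEATURE_COLS)
        valid_reports[organ] = svr.evaluate(m, Xv, yv, FEATURE_COLS)
    return ExperimentResult(
        models=models,
        train_reports=train_reports,
        valid_reports=valid_reports,
        n_train=len(train_ids),
        n_valid=len(valid_ids),
    )


def simulate_cohort(phantom_config: PhantomConfig | None = None) -> pd.DataFrame:
    """Generate the synthetic cohort and return its long-format table."""
    cfg = phantom_config or PhantomConfig()
    return cohort_to_frame(generate_cohort(cfg))


def qa_check(
    models: dict[str, svr.TrainedModel],
    features: dict[str, np.ndarray],
    actual_ratios: dict[str, float],
    delta_threshold: float | dict[str, float] = DEFAULT_DELTA_THRESHOLD,
) -> dict[str, dict]:
    """Flag organs whose planned dose deviates from the model prediction.

    For each organ, delta = |actual - predicted| D2cm3/Dprescription;
    the verdict is "flag" iff delta exceeds the (per-organ) threshold,
    else "pass".
    """
    verdicts = {}
    for organ, m in models.items():
        if organ not in features or organ not in actual_ratios:
            continue
        thr = (
            delta_threshold.get(organ, DEFAULT_DELTA_THRESHOLD)
            if isinstance(delta_threshold, dict)
            else delta_threshold
        )
        if thr < 0:
            raise ValueError("delta threshold must be >= 0")
        pred = float(svr.predict(m, np.atleast_2d(features[organ]))[0])
        delta = abs(actual_ratios[organ] - pred)
        verdicts[organ] = {
            "predicted_ratio": pred,
            "actual_ratio": float(actual_ratios[organ]),
            "delta": delta,
            "threshold": thr,
            "verdict": "flag" if delta > thr else "pass",
        }
    return verdicts
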