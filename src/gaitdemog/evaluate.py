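"""Evaluation: classification/regression reports and stratified breakdowns.

Classification (sex) reports accuracy, F1 for the male-positive class and
macro-averaged F1, AUC-ROC and the 2x2 confusion counts.  AUC is computed
from the rank statistic over all positive-negative pairs (equivalent to
trapezoidal integration of the ROC curve).  Regression (age) reports MAE,
MSE, RMSE and the coefficient of determination R^2 = 1 - SS_res/SS_tot —
all four are always carried explicitly so no scale ambiguity arises between
MSE and RMSE.  Stratified reports break these metrics down by age bin or by
sensor position (after down-sampling every position to the smallest
position's subject count so the comparison is size-matched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigurationError, DataError

#: decade bins with the sparse elderly decades merged
DEFAULT_AGE_BINS: tuple[tuple[int, int], ...] = (
    (1, 10), (11, 20), (21, 30), (31, 40), (41, 50), (51, 60), (61, 80),
)


@dataclass
class ClassificationReport:
    accuracy: float
    f1_male: float
    f1_macro: float
    auc_roc: float | None
    confusion: dict[str, int]  # tp, fp, fn, tn with male (1) as positive
    n: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1_male": self.f1_male,
            "f1_macro": self.f1_macro, "auc_roc": self.auc_roc,
            "confusion": dict(self.confusion), "n": self.n,
        }


@dataclass
class RegressionReport:
    mae: float
    mse: float
    rmse: float
    r2: float | None
    ss_res: float
    ss_tot: float
    y_mean: float
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse,
                "r2": self.r2, "ss_res": self.ss_res, "ss_tot": self.ss_tot,
                "y_mean": self.y_mean, "n": self.n}


@dataclass
class GroupReport:
    """Per-group metric tables for a grouping key (age bin or position)."""

    key: str
    groups: dict[str, object]  # group label -> report
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return {"key": self.key,
                "groups": {k: v.to_dict() for k, v in self.groups.items()},
                "counts": dict(self.counts)}


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rank_auc(truth, scores) -> float | None:
    """AUC-ROC via the rank statistic: the tie-corrected probability that a
    random positive outscores a random negative.  None if a class is absent."""
    y = np.asarray(truth, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = scipy.stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom > 0 else 0.0


def classification_metrics(truth, predictions, scores=None) -> ClassificationReport:
    """Accuracy, F1 (male-positive and macro), rank-based AUC and confusion
    counts; labels encoded male=1, female=0."""
    y = np.asarray(truth, dtype=int)
    yhat = np.asarray(predictions, dtype=int)
    if len(y) != len(yhat):
        raise DataError("truth and predictions have unequal lengths")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    n = len(y)
    f1_pos = _f1(tp, fp, fn)
    f1_neg = _f1(tn, fn, fp)
    auc = rank_auc(y, scores) if scores is not None else None
    return ClassificationReport(
        accuracy=(tp + tn) / n, f1_male=f1_pos, f1_macro=(f1_pos + f1_neg) / 2,
        auc_roc=auc, confusion={"tp": tp, "fp": fp, "fn": fn, "tn": tn}, n=n,
    )


def regression_metrics(truth, predictions) -> RegressionReport:
    """MAE, MSE, RMSE and R^2 from their defining sums; R^2 is None when the
    truth is constant (SS_tot = 0)."""
    y = np.asarray(truth, dtype=float)
    yhat = np.asarray(predictions, dtype=float)
    if len(y) != len(yhat):
        raise DataError("truth and predictions have unequal lengths")
    if len(y) < 2:
        raise DataError("regression metrics need at least 2 samples")
    resid = y - yhat
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    ss_res = float(np.sum(resid**2))
    y_mean = float(np.mean(y))
    ss_tot = float(np.sum((y - y_mean) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return RegressionReport(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2,
                            ss_res=ss_res, ss_tot=ss_tot, y_mean=y_mean, n=len(y))


# ---------------------------------------------------------------------------
# stratified analyses
# ---------------------------------------------------------------------------

def _bin_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def metrics_by_age_group(
    truth,
    predictions,
    ages,
    task: str,
    bins: Sequence[tuple[int, int]] = DEFAULT_AGE_BINS,
    scores=None,
) -> GroupReport:
    """Per-age-bin metric tables.  Every age must fall in exactly one
    (inclusive) bin; stray ages raise an error listing them."""
    ages = np.asarray(ages)
    assign = np.full(len(ages), -1)
    for i, (lo, hi) in enumerate(bins):
        mask = (ages >= lo) & (ages <= hi)
        assign[mask] = i
    stray = sorted(set(ages[assign < 0].tolist()))
    if stray:
        raise DataError(f"ages outside all bins: {stray}")
    groups: dict[str, object] = {}
    counts: dict[str, int] = {}
    for i, (lo, hi) in enumerate(bins):
        mask = assign == i
        if not mask.any():
            continue
        label = _bin_label(lo, hi)
        counts[label] = int(mask.sum())
        if task == "sex":
            groups[label] = classification_metrics(
                np.asarray(truth)[mask], np.asarray(predictions)[mask],
                None if scores is None else np.asarray(scores)[mask])
        else:
            groups[label] = regression_metrics(
                np.asarray(truth)[mask], np.asarray(predictions)[mask])
    return GroupReport(key="age_group", groups=groups, counts=counts)


def compare_sensor_positions(
    df: pd.DataFrame,
    task: str,
    seed: int = 0,
    columns: Sequence[str] | None = None,
    model_kind: str | None = None,
    train_fraction: float = 0.7,
) -> GroupReport:
    """Size-matched per-position comparison.

    Each sensor position's subjects are down-sampled (by subject, seeded) to
    the smallest position's subject count, then each position's data is
    split by subject, a model is trained (stacking for sex, kNN for age by
    default) and evaluated on its held-out subjects.  Positions with fewer
    than 2 subjects are excluded with a warning.
    """
    from .models import (ModelConfig, predict, split_dataset, train_predictor,
                         train_stacking)

    positions = sorted(df["position"].unique())
    subj_by_pos = {
        p: sorted(df.loc[df["position"] == p, "subject_id"].unique())
        for p in positions
    }
    usable = {p: s for p, s in subj_by_pos.items() if len(s) >= 2}
    for p in positions:
        if p not in usable:
            warnings.warn(f"position {p!r} has < 2 subjects; excluded")
    if len(usable) < 2:
        raise DataError("need at least 2 sensor positions with >= 2 subjects")
    m = min(len(s) for s in usable.values())
    rng = np.random.default_rng(seed)
    groups: dict[str, object] = {}
    counts: dict[str, int] = {}
    for p in sorted(usable):
        subj = np.asarray(usable[p])
        keep = subj[np.sort(rng.choice(len(subj), size=m, replace=False))]
        sub = df[df["subject_id"].isin(keep)]
        train, test = split_dataset(sub, train_fraction, by_subject=True, seed=seed)
        if task == "sex":
            kind = model_kind or "stacking"
            if kind == "stacking":
                pred = train_stacking(train, columns=columns, seed=seed)
            else:
                pred = train_predictor(train, ModelConfig(kind, "sex", seed=seed),
                                       columns=columns)
            labels, scores = predict(pred, test)
            from .models import encode_sex
            groups[p] = classification_metrics(encode_sex(test["sex"]), labels, scores)
        else:
            kind = model_kind or "knn"
            pred = train_predictor(train, ModelConfig(kind, "age", seed=seed),
                                   columns=columns)
            yhat = predict(pred, test)
            groups[p] = regression_metrics(test["age"].to_numpy(float), yhat)
        counts[p] = m
    return GroupReport(key="position", groups=groups, counts=counts)


def plot_group_metric(report: GroupReport, metric: str, path) -> None:
    """Bar chart of one metric across groups (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(report.groups)
    values = [getattr(report.groups[k], metric) for k in labels]
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.bar(labels, values, color="#4878d0")
    ax.set_xlabel(report.key)
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
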