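"""Cross-validated prediction of cognitive change from baseline DLPFC activity.

For each hemisphere, a linear model ``change ~ activity + pre + age + sex``
is fit on 80% of the training-arm participants and evaluated on the held-out
20%, over a shuffled 5-fold split.  The outcome is z-scored with the
training fold's mean/SD before fitting, so RMSE is in SD units and
comparable across outcomes and sides.  Left and right models share the
same fold assignment, making the side contrast a paired comparison.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

from .types import CVResult, SideComparison

logger = logging.getLogger(__name__)

__all__ = ["kfold_split", "cv_rmse", "compare_sides", "build_analysis_frame"]


def kfold_split(ids: Sequence[str], k: int = 5,
                seed: int | None = None) -> dict[str, int]:
    """Shuffled balanced partition of ids into folds 1..k, deterministic in seed."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds the number of ids ({len(ids)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(kf.split(ids), start=1):
        for i in test_idx:
            assignment[ids[i]] = fold
    return assignment


def build_analysis_frame(participants_df: pd.DataFrame,
                         activity_df: pd.DataFrame) -> pd.DataFrame:
    """Merge a participant table with the long activity table (wide by side)."""
    wide = activity_df.pivot(index="id", columns="side", values="activity")
    wide.columns = [f"activity_{c}" for c in wide.columns]
    merged = participants_df.merge(wide.reset_index(), on="id", how="inner")
    if len(merged) != len(participants_df):
        missing = set(participants_df["id"]) - set(merged["id"])
        raise ValueError(f"activity missing for participants: {sorted(missing)}")
    return merged


def cv_rmse(
    data: pd.DataFrame,
    side: str,
    outcome: str,
    k: int = 5,
    seed: int | None = None,
    folds: Mapping[str, int] | None = None,
    group: str | None = "BT",
    covariates: bool = True,
) -> CVResult:
    """k-fold cross-validated RMSE of the activity-based prediction model.

    ``data`` must hold columns ``id, group, age, sex, activity_<side>,
    <outcome>_pre, <outcome>_post``.  Rows are restricted to ``group``
    (``None`` keeps all).  Pass ``folds`` to reuse an assignment across
    sides; otherwise one is drawn from ``seed``.

    The per-fold RMSE is computed on the outcome z-scored with the training
    fold's mean/SD.  A training fold with zero outcome variance is flagged,
    reported as NaN and excluded from the mean.
    """
    df = data if group is None else data[data["group"] == group]
    df = df.reset_index(drop=True)
    cols = ["id", "age", "sex", f"activity_{side}",
            f"{outcome}_pre", f"{outcome}_post"]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing columns: {missing_cols}")
    if df[cols].isna().any().any():
        raise ValueError("missing values in analysis columns")

    if folds is None:
        folds = kfold_split(df["id"].tolist(), k=k, seed=seed)
    fold_of = df["id"].map(folds)
    if fold_of.isna().any():
        raise ValueError("fold assignment does not cover all participants")
    fold_labels = sorted(set(folds[i] for i in df["id"]))

    y = (df[f"{outcome}_post"] - df[f"{outcome}_pre"]).to_numpy(float)
    X_cols = [df[f"activity_{side}"].to_numpy(float)]
    if covariates:
        X_cols += [df[f"{outcome}_pre"].to_numpy(float),
                   df["age"].to_numpy(float),
                   (df["sex"] == "M").to_numpy(float)]
    X = np.column_stack(X_cols)

    rmses, stats = [], []
    for fold in fold_labels:
        test = (fold_of == fold).to_numpy()
        train = ~test
        mu, sd = y[train].mean(), y[train].std(ddof=1)
        if sd == 0:
            logger.warning("fold %s: zero outcome variance in training data; "
                           "fold excluded from the mean", fold)
            rmses.append(float("nan"))
            stats.append((float(mu), 0.0))
            continue
        model = LinearRegression().fit(X[train], (y[train] - mu) / sd)
        pred = model.predict(X[test])
        err = (y[test] - mu) / sd - pred
        rmses.append(float(np.sqrt(np.mean(err**2))))
        stats.append((float(mu), float(sd)))
    valid = [r for r in rmses if not math.isnan(r)]
    if not valid:
        raise ValueError("no fold had positive outcome variance")
    return CVResult(side, outcome, tuple(rmses), float(np.mean(valid)),
                    dict(folds), tuple(stats))


def compare_sides(cv_a: CVResult, cv_b: CVResult) -> SideComparison:
    """Paired summary of two CV models sharing outcome and folds.

    ``difference = rmse_b - rmse_a`` (positive when the first argument wins);
    the winner is the side with the smaller mean RMSE, and is invariant
    under exchanging the arguments.
    """
    if cv_a.outcome != cv_b.outcome:
        raise ValueError("results compare different outcomes")
    if dict(cv_a.folds) != dict(cv_b.folds):
        raise ValueError("results were computed on different fold assignments")
    diff = cv_b.mean_rmse - cv_a.mean_rmse
    winner = cv_a.side if cv_a.mean_rmse <= cv_b.mean_rmse else cv_b.side
    return SideComparison(cv_a.outcome, cv_a.side, cv_b.side,
                          cv_a.mean_rmse, cv_b.mean_rmse, diff, winner)
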