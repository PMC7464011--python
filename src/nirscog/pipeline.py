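"""End-to-end orchestration: generate -> preprocess -> analyze -> cross-validate.

One :func:`run_pipeline` call performs the whole study on a synthetic
cohort and emits the three analysis tables:

1. baseline brain activity ANCOVA per hemisphere
   (``activity ~ group + age + sex``, permutation p, one FDR family);
2. change-score ANCOVAs for the eleven cognitive outcomes
   (``change ~ group + pre + age + sex``, with per-arm mean/SD change,
   eta^2, permutation and FDR-adjusted p; one FDR family);
3. permutation regressions linking each change score to left/right baseline
   activity in the training arm (one pooled FDR family), plus the 5-fold
   cross-validated RMSE comparison of the left- vs right-activity models
   on shared folds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossval import build_analysis_frame, compare_sides, cv_rmse, kfold_split
from .inference import ancova_permutation, attach_fdr, perm_regression
from .io import participants_to_frame, write_activity_csv, write_participants_csv, write_recordings
from .preprocess import preprocess_recordings
from .synthetic import (
    DEFAULT_FS,
    default_effect_config,
    make_cohort,
    simulate_cohort_recordings,
)
from .types import OUTCOMES, SIDES, BlockSchedule, EffectConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "baseline_brain_table", "change_ancova_table",
           "regression_table", "crossval_table"]


@dataclass
class RunConfig:
    """Reproducible configuration for one full pipeline run."""

    seed: int = 0
    n_per_group: int = 36
    effect: EffectConfig = field(default_factory=default_effect_config)
    fs: float = DEFAULT_FS
    block_duration: float = 30.0
    n_game_blocks: int = 2
    cutoff: float = 0.1
    filter_order: int = 4
    n_perm: int = 10_000
    k: int = 5
    direction: str = "change_on_brain"
    outdir: str | None = None

    def schedule(self) -> BlockSchedule:
        return BlockSchedule.alternating(self.block_duration, self.n_game_blocks)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effect"] = self.effect.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "effect" in d and isinstance(d["effect"], dict):
            d["effect"] = EffectConfig.from_dict(d["effect"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    participants: pd.DataFrame
    activity: pd.DataFrame
    baseline_brain: pd.DataFrame
    change_ancova: pd.DataFrame
    regression: pd.DataFrame
    crossval: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "participants": self.participants,
            "activity": self.activity,
            "baseline_brain_ancova": self.baseline_brain,
            "change_ancova": self.change_ancova,
            "regression": self.regression,
            "crossval": self.crossval,
        }


# --------------------------------------------------------------------------
# analysis-stage builders (shared by the CLI verbs and run_pipeline)
# --------------------------------------------------------------------------

def baseline_brain_table(data: pd.DataFrame, n_perm: int,
                         seed: int | None) -> pd.DataFrame:
    """Per-side group ANCOVA on baseline activity, covariates age + sex."""
    results = []
    for i, side in enumerate(SIDES):
        cov = pd.DataFrame({"age": data["age"],
                            "sex": (data["sex"] == "M").astype(float)})
        res = ancova_permutation(data[f"activity_{side}"].to_numpy(float),
                                 data["group"].to_numpy(), cov,
                                 n_perm=n_perm,
                                 seed=None if seed is None else seed + i,
                                 outcome=side)
        results.append(res)
    attach_fdr(results)
    return pd.DataFrame([{
        "side": r.outcome, "F": r.F, "df_effect": r.df_effect,
        "df_resid": r.df_resid, "eta2": r.eta2, "p_perm": r.p_perm,
        "p_adjusted": r.p_adjusted, "n_perm": r.n_perm, "method": r.method,
    } for r in results])


def change_ancova_table(data: pd.DataFrame, n_perm: int,
                        seed: int | None) -> pd.DataFrame:
    """Change-score ANCOVAs with per-arm descriptive change statistics."""
    results, rows = [], []
    for i, name in enumerate(OUTCOMES):
        change = (data[f"{name}_post"] - data[f"{name}_pre"]).to_numpy(float)
        cov = pd.DataFrame({"pre": data[f"{name}_pre"], "age": data["age"],
                            "sex": (data["sex"] == "M").astype(float)})
        res = ancova_permutation(change, data["group"].to_numpy(), cov,
                                 n_perm=n_perm,
                                 seed=None if seed is None else seed + i,
                                 outcome=name)
        results.append(res)
        bt = change[(data["group"] == "BT").to_numpy()]
        act = change[(data["group"] == "ACT").to_numpy()]
        rows.append({
            "outcome": name,
            "bt_mean_change": float(bt.mean()), "bt_sd_change": float(bt.std(ddof=1)),
            "act_mean_change": float(act.mean()), "act_sd_change": float(act.std(ddof=1)),
            "F": res.F, "df_effect": res.df_effect, "df_resid": res.df_resid,
            "eta2": res.eta2, "p_perm": res.p_perm,
        })
    attach_fdr(results)
    for row, res in zip(rows, results):
        row["p_adjusted"] = res.p_adjusted
    return pd.DataFrame(rows, columns=[
        "outcome", "bt_mean_change", "bt_sd_change", "act_mean_change",
        "act_sd_change", "eta2", "p_adjusted", "p_perm", "F",
        "df_effect", "df_resid"])


def regression_table(data: pd.DataFrame, n_perm: int, seed: int | None,
                     direction: str = "change_on_brain",
                     group: str = "BT") -> pd.DataFrame:
    """Permutation regressions for every (outcome, side) in one arm."""
    sub = data[data["group"] == group].reset_index(drop=True)
    results = []
    counter = 0
    for name in OUTCOMES:
        change = (sub[f"{name}_post"] - sub[f"{name}_pre"]).to_numpy(float)
        for side in SIDES:
            cov = pd.DataFrame({"pre": sub[f"{name}_pre"], "age": sub["age"],
                                "sex": (sub["sex"] == "M").astype(float)})
            res = perm_regression(change, sub[f"activity_{side}"].to_numpy(float),
                                  cov, n_perm=n_perm,
                                  seed=None if seed is None else seed + counter,
                                  direction=direction, outcome=name, side=side)
            results.append(res)
            counter += 1
    attach_fdr(results)
    return pd.DataFrame([{
        "outcome": r.outcome, "side": r.side, "beta_std": r.beta_std,
        "t": r.t, "p_perm": r.p_perm, "p_adjusted": r.p_adjusted,
        "n": r.n, "direction": r.direction,
    } for r in results])


def crossval_table(data: pd.DataFrame, k: int, seed: int | None,
                   group: str = "BT") -> pd.DataFrame:
    """Per-outcome left/right CV RMSE on shared folds, plus pooled summary.

    Prediction always runs change-on-brain: predicting baseline activity
    from a change score has no prospective use.
    """
    sub = data[data["group"] == group].reset_index(drop=True)
    folds = kfold_split(sub["id"].tolist(), k=k, seed=seed)
    rows = []
    per_side = {side: [] for side in SIDES}
    for name in OUTCOMES:
        cvs = {side: cv_rmse(sub, side, name, k=k, folds=folds, group=None)
               for side in SIDES}
        comp = compare_sides(cvs["left"], cvs["right"])
        for side in SIDES:
            per_side[side].append(cvs[side].mean_rmse)
        rows.append({
            "outcome": name,
            "rmse_left": cvs["left"].mean_rmse,
            "rmse_right": cvs["right"].mean_rmse,
            "difference": comp.difference,
            "winner": comp.winner,
            **{f"fold{j + 1}_left": cvs["left"].fold_rmse[j] for j in range(k)},
            **{f"fold{j + 1}_right": cvs["right"].fold_rmse[j] for j in range(k)},
        })
    pooled = {
        "outcome": "POOLED",
        "rmse_left": float(np.mean(per_side["left"])),
        "rmse_right": float(np.mean(per_side["right"])),
    }
    pooled["difference"] = pooled["rmse_right"] - pooled["rmse_left"]
    pooled["winner"] = "left" if pooled["rmse_left"] <= pooled["rmse_right"] else "right"
    rows.append(pooled)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, write: bool | None = None) -> PipelineResult:
    """Run the full synthetic study; optionally write all tables to disk.

    Any stage failure is re-raised with the stage named.  The manifest
    records the seed, the full configuration and library versions, and is
    sufficient to re-run the pipeline bit-identically.
    """
    if write is None:
        write = config.outdir is not None
    outdir = Path(config.outdir) if config.outdir else None
    if write and outdir is None:
        raise ValueError("write=True requires config.outdir")

    stage = "simulate-cohort"
    try:
        participants, amplitudes = make_cohort(
            config.n_per_group, config.effect, seed=config.seed)
        logger.info("stage %s: %d participants", stage, len(participants))
        pdf = participants_to_frame(participants)

        stage = "simulate-recordings"
        recordings = simulate_cohort_recordings(
            participants, amplitudes, fs=config.fs, schedule=config.schedule(),
            noise=config.effect.noise, seed=config.seed + 1)
        logger.info("stage %s: %d recordings", stage, len(recordings))

        stage = "preprocess"
        activity = preprocess_recordings(recordings, cutoff=config.cutoff,
                                         order=config.filter_order)
        logger.info("stage %s: %d activity estimates", stage, len(activity))

        stage = "analyze"
        data = build_analysis_frame(pdf, activity)
        if data.isna().any().any():
            raise ValueError("missing values in merged analysis table")
        baseline = baseline_brain_table(data, config.n_perm, config.seed + 100)
        change = change_ancova_table(data, config.n_perm, config.seed + 200)
        regression = regression_table(data, config.n_perm, config.seed + 300,
                                      direction=config.direction)
        logger.info("stage %s: %d baseline, %d change, %d regression rows",
                    stage, len(baseline), len(change), len(regression))

        stage = "crossval"
        crossval = crossval_table(data, config.k, config.seed + 400)
        logger.info("stage %s: %d rows", stage, len(crossval))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "package_version": __version__,
        "python": platform.python_version(),
        "versions": {mod.__name__: mod.__version__
                     for mod in _version_mods()},
        "row_counts": {"participants": len(pdf), "recordings": len(recordings),
                       "activity": len(activity)},
    }
    result = PipelineResult(pdf, activity, baseline, change, regression,
                            crossval, manifest)

    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        write_participants_csv(participants, outdir / "participants.csv")
        write_recordings(recordings, outdir / "recordings.csv",
                         outdir / "recordings.json")
        write_activity_csv(activity, outdir / "activity.csv")
        result.baseline_brain.to_csv(outdir / "baseline_brain_ancova.csv", index=False)
        result.change_ancova.to_csv(outdir / "change_ancova.csv", index=False)
        result.regression.to_csv(outdir / "regression_results.csv", index=False)
        result.crossval.to_csv(outdir / "crossval_results.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                         sort_keys=True))
    return result


def _version_mods():
    import numpy
    import pandas
    import scipy
    import sklearn
    return (numpy, scipy, pandas, sklearn)
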