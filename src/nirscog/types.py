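"""Domain types for the trial-simulation and fNIRS-analysis pipeline.

The pipeline models a two-arm randomized controlled trial (a brain-training
arm, ``BT``, against an active-control arm, ``ACT``) in which every
participant contributes eleven pre/post cognitive test scores and two
dual source-detector fNIRS recordings (left and right dorsolateral
prefrontal cortex).  Each recording holds a *shallow* (1 cm source-detector
separation, scalp haemodynamics) and a *deep* (3 cm, scalp + cortex)
total-haemoglobin series over an alternating rest / game block design.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Cognitive outcomes measured pre and post intervention.
#: Cd, SS — processing speed; rST, ST — inhibition; DS-F, DS-B — short-term
#: memory; LNS, WMU — working memory; D-CAT — attention; LM — episodic memory.
OUTCOMES: tuple[str, ...] = (
    "Cd", "SS", "rST", "ST", "DS-F", "DS-B",
    "LNS", "WMU", "D-CAT", "LM-immediate", "LM-delay",
)

GROUPS: tuple[str, str] = ("BT", "ACT")
SIDES: tuple[str, str] = ("left", "right")
SEXES: tuple[str, str] = ("M", "F")


# --------------------------------------------------------------------------
# trial-side types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantRecord:
    """One trial participant with pre/post scores for all outcomes."""

    id: str
    group: str
    sex: str
    age: float
    scores: Mapping[str, tuple[float, float]]  # outcome -> (pre, post)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        missing = set(OUTCOMES) - set(self.scores)
        if missing:
            raise ValueError(f"missing outcome scores: {sorted(missing)}")
        for name, (pre, post) in self.scores.items():
            if not (math.isfinite(pre) and math.isfinite(post)):
                raise ValueError(f"non-finite score for {name!r}")
        if not math.isfinite(self.age):
            raise ValueError("age must be finite")

    def change(self, outcome: str) -> float:
        pre, post = self.scores[outcome]
        return post - pre


@dataclass(frozen=True)
class OutcomeEffect:
    """Generative parameters for one cognitive outcome.

    ``control_change`` is the mean change in the active-control arm;
    ``training_effect`` the additional mean change in the training arm
    (BT − ACT difference).  ``rho_left`` / ``rho_right`` are the latent
    correlations between the change score and the standardized baseline
    neural amplitude on each side; their squares must sum to ≤ 1 so the
    residual change variance stays non-negative.
    """

    pre_mean: float
    pre_sd: float
    control_change: float
    training_effect: float
    change_sd: float
    rho_left: float = 0.0
    rho_right: float = 0.0

    def __post_init__(self) -> None:
        if self.pre_sd < 0 or self.change_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for rho in (self.rho_left, self.rho_right):
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
        if self.rho_left**2 + self.rho_right**2 > 1 + 1e-12:
            raise ValueError("rho_left**2 + rho_right**2 must be <= 1")


@dataclass(frozen=True)
class AmplitudeModel:
    """Log-normal model of latent baseline neural amplitude (a.u.) per arm."""

    bt_mean: float = 1.1
    act_mean: float = 0.95
    sd: float = 0.4

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.bt_mean <= 0 or self.act_mean <= 0:
            raise ValueError("amplitude means must be > 0")


@dataclass(frozen=True)
class RecordingNoise:
    """Noise model for one dual source-detector recording.

    The systemic component (shared by shallow and deep channels) is a sum
    of a slow vasomotion sinusoid, a Mayer-wave sinusoid, a cardiac-band
    sinusoid — each with a random phase — and AR(1) coloured noise.
    ``systemic_coupling`` scales how strongly the systemic component leaks
    into the deep channel.  Linear drifts and white measurement noise are
    channel-specific.  All amplitudes are in the same arbitrary
    total-haemoglobin units as the neural amplitude.
    """

    systemic_coupling: float = 0.6
    slow_amp: float = 0.3
    slow_freq: float = 0.02
    mayer_amp: float = 0.4
    mayer_freq: float = 0.08
    cardiac_amp: float = 0.25
    cardiac_freq: float = 1.1
    ar_phi: float = 0.99
    ar_sd: float = 0.02
    drift_slope_sd: float = 0.003
    shallow_noise_sd: float = 0.05
    deep_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        for name in ("slow_amp", "mayer_amp", "cardiac_amp", "ar_sd",
                     "drift_slope_sd", "shallow_noise_sd", "deep_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not abs(self.ar_phi) < 1:
            raise ValueError("ar_phi must satisfy |phi| < 1")

    def is_silent(self) -> bool:
        """True when every stochastic component has zero amplitude."""
        return all(getattr(self, n) == 0 for n in
                   ("slow_amp", "mayer_amp", "cardiac_amp", "ar_sd",
                    "drift_slope_sd", "shallow_noise_sd", "deep_noise_sd"))


@dataclass(frozen=True)
class EffectConfig:
    """Full generative configuration for a synthetic trial."""

    outcomes: Mapping[str, OutcomeEffect]
    amplitude: AmplitudeModel = field(default_factory=AmplitudeModel)
    noise: RecordingNoise = field(default_factory=RecordingNoise)
    male_fraction: float = 2.0 / 3.0
    age_mean: float = 21.63
    age_sd: float = 1.26
    age_range: tuple[float, float] = (20.0, 30.0)

    def __post_init__(self) -> None:
        missing = set(OUTCOMES) - set(self.outcomes)
        if missing:
            raise ValueError(f"missing outcome configs: {sorted(missing)}")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        if self.age_sd < 0:
            raise ValueError("age_sd must be >= 0")

    # round-tripping for YAML/JSON configs ---------------------------------
    def to_dict(self) -> dict:
        return {
            "outcomes": {k: dataclasses.asdict(v) for k, v in self.outcomes.items()},
            "amplitude": dataclasses.asdict(self.amplitude),
            "noise": dataclasses.asdict(self.noise),
            "male_fraction": self.male_fraction,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_range": list(self.age_range),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectConfig":
        return cls(
            outcomes={k: OutcomeEffect(**v) for k, v in d["outcomes"].items()},
            amplitude=AmplitudeModel(**d.get("amplitude", {})),
            noise=RecordingNoise(**d.get("noise", {})),
            male_fraction=d.get("male_fraction", 2.0 / 3.0),
            age_mean=d.get("age_mean", 21.63),
            age_sd=d.get("age_sd", 1.26),
            age_range=tuple(d.get("age_range", (20.0, 30.0))),
        )


# --------------------------------------------------------------------------
# recording-side types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    label: str  # "rest" | "game"
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in ("rest", "game"):
            raise ValueError(f"block label must be 'rest' or 'game', got {self.label!r}")
        if not self.start < self.end:
            raise ValueError("block must have start < end")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class BlockSchedule:
    """Contiguous alternating rest/game blocks, starting and ending with rest."""

    blocks: tuple[Block, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.blocks[0].label != "rest" or self.blocks[-1].label != "rest":
            raise ValueError("schedule must start and end with a rest block")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if not math.isclose(prev.end, nxt.start, abs_tol=1e-9):
                raise ValueError("blocks must be contiguous and non-overlapping")
            if prev.label == nxt.label:
                raise ValueError("rest and game blocks must alternate")

    @property
    def duration(self) -> float:
        return self.blocks[-1].end - self.blocks[0].start

    def n_samples(self, fs: float) -> int:
        return int(round(self.duration * fs))

    def sample_slice(self, block: Block, fs: float) -> slice:
        return slice(int(round(block.start * fs)), int(round(block.end * fs)))

    def game_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.label == "game")

    def rest_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.label == "rest")

    @classmethod
    def alternating(cls, block_duration: float = 30.0, n_game: int = 2) -> "BlockSchedule":
        """R-V-R-...-V-R schedule of equal-length blocks (default R-V-R-V-R, 150 s)."""
        labels = ["rest"]
        for _ in range(n_game):
            labels += ["game", "rest"]
        blocks = [Block(lab, i * block_duration, (i + 1) * block_duration)
                  for i, lab in enumerate(labels)]
        return cls(tuple(blocks))

    def to_dict(self) -> list[dict]:
        return [dataclasses.asdict(b) for b in self.blocks]

    @classmethod
    def from_dict(cls, blocks: Sequence[Mapping]) -> "BlockSchedule":
        return cls(tuple(Block(**b) for b in blocks))


@dataclass(frozen=True)
class Recording:
    """One hemisphere's shallow + deep total-Hb series for one participant."""

    participant_id: str
    side: str
    fs: float
    shallow: np.ndarray
    deep: np.ndarray
    schedule: BlockSchedule
    true_neural_amplitude: float | None = None  # simulation ground truth

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        shallow = np.asarray(self.shallow, dtype=float)
        deep = np.asarray(self.deep, dtype=float)
        object.__setattr__(self, "shallow", shallow)
        object.__setattr__(self, "deep", deep)
        n = self.schedule.n_samples(self.fs)
        if len(shallow) != n or len(deep) != n:
            raise ValueError(
                f"series length ({len(shallow)}, {len(deep)}) must equal "
                f"round(duration * fs) = {n}")


@dataclass(frozen=True)
class NeuralSeries:
    """Deep-channel series after removal of the shallow (systemic) component."""

    values: np.ndarray
    fs: float
    schedule: BlockSchedule
    coef: tuple[float, float] | None = None  # (intercept, slope) of the regression
    fallback: bool = False  # True when shallow was constant and only centering applied

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class ActivityEstimate:
    """Per-participant, per-side scalar baseline activity.

    ``activity`` is the mean of the baseline-corrected neural signal over
    all game-block samples; ``block_means`` are the per-game-block means.
    """

    participant_id: str
    side: str
    activity: float
    block_means: tuple[float, ...]
    block_sizes: tuple[int, ...]


# --------------------------------------------------------------------------
# inference-side result types
# --------------------------------------------------------------------------

@dataclass
class PermTestResult:
    """Permutation-ANCOVA result for one dependent variable."""

    outcome: str
    F: float
    df_effect: int
    df_resid: int
    eta2: float
    p_perm: float
    n_perm: int
    method: str  # "exact" | "monte-carlo"
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ValueError("F must be >= 0")
        if not 0 <= self.eta2 <= 1 + 1e-12:
            raise ValueError("eta2 must lie in [0, 1]")
        if not 0 < self.p_perm <= 1:
            raise ValueError("p_perm must lie in (0, 1]")


@dataclass
class RegressionResult:
    """Permutation multiple-regression result for one (outcome, side) pair."""

    outcome: str
    side: str
    beta_std: float
    t: float
    p_perm: float
    n: int
    direction: str  # "change_on_brain" | "brain_on_change"
    df_resid: int = 0
    p_adjusted: float = float("nan")

    def __post_init__(self) -> None:
        if self.t != 0 and np.sign(self.beta_std) != np.sign(self.t):
            raise ValueError("beta_std and t must agree in sign")


@dataclass
class CVResult:
    """k-fold cross-validation RMSEs for one predictor-side/outcome model."""

    side: str
    outcome: str
    fold_rmse: tuple[float, ...]
    mean_rmse: float
    folds: Mapping[str, int]  # participant id -> fold index (1..k)
    standardization: tuple[tuple[float, float], ...]  # per-fold (mean, sd) of outcome

    def __post_init__(self) -> None:
        valid = [r for r in self.fold_rmse if not math.isnan(r)]
        if any(r < 0 for r in valid):
            raise ValueError("RMSE must be >= 0")


@dataclass
class SideComparison:
    """Paired comparison of two CV models sharing the same folds."""

    outcome: str
    side_a: str
    side_b: str
    rmse_a: float
    rmse_b: float
    difference: float  # rmse_b - rmse_a
    winner: str
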