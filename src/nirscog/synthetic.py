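"""Synthetic two-arm trial and dual source-detector fNIRS generator.

Everything downstream (preprocessing, permutation inference, cross-validated
prediction) is tested against cohorts produced here, because the generator
records its own ground truth: each participant carries latent left/right
baseline neural amplitudes, and every simulated recording stores the
amplitude that produced it.

The default study conditions emulate a 72-participant, two-arm,
sex-stratified block-randomized trial (48 male / 24 female, block size 4,
1:1 allocation) with eleven pre/post cognitive outcomes, and single-
wavelength total-haemoglobin recordings with shallow (1 cm) and deep (3 cm)
source-detector pairs over an R-V-R-V-R block design of 30 s blocks.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .types import (
    OUTCOMES,
    AmplitudeModel,
    BlockSchedule,
    EffectConfig,
    OutcomeEffect,
    ParticipantRecord,
    Recording,
    RecordingNoise,
)

__all__ = [
    "hrf",
    "stratified_block_randomize",
    "make_cohort",
    "simulate_recording",
    "simulate_cohort_recordings",
    "default_effect_config",
    "null_effect_config",
    "silent_noise",
]

DEFAULT_FS = 10.0  # Hz; device rate is configurable, 10 Hz is the shipped default


# --------------------------------------------------------------------------
# configurations
# --------------------------------------------------------------------------

# Per-outcome generative parameters: baseline score distribution, the
# active-control mean change, the training-arm additional change, the change
# SD, and latent brain-change correlations.  Calibrated loosely to published
# normative values for these test batteries in young adults; the left-side
# correlations are concentrated on processing-speed (Cd, SS) and working-
# memory (LNS, WMU) outcomes, with a weaker right-side association, so the
# left-hemisphere predictor genuinely carries more signal.
_DEFAULT_OUTCOMES: dict[str, OutcomeEffect] = {
    "Cd":           OutcomeEffect(59.8, 10.5, 0.68, 3.80, 5.10, rho_left=0.42, rho_right=0.20),
    "SS":           OutcomeEffect(30.0, 4.00, 0.79, 2.36, 3.40, rho_left=0.41, rho_right=0.20),
    "rST":          OutcomeEffect(37.5, 5.60, 0.89, 3.11, 4.95),
    "ST":           OutcomeEffect(25.7, 7.80, 0.29, 2.41, 3.85),
    "DS-F":         OutcomeEffect(5.24, 1.08, 0.29, -0.29, 1.20),
    "DS-B":         OutcomeEffect(3.97, 0.98, 0.21, 0.12, 0.98),
    "LNS":          OutcomeEffect(6.29, 1.31, 0.78, 2.43, 1.87, rho_left=0.36, rho_right=0.20),
    "WMU":          OutcomeEffect(7.27, 1.22, 0.66, 1.51, 0.91, rho_left=0.44, rho_right=0.20),
    "D-CAT":        OutcomeEffect(3.97, 0.98, 11.14, 1.23, 21.5),
    "LM-immediate": OutcomeEffect(8.90, 3.80, -0.18, 3.39, 3.08),
    "LM-delay":     OutcomeEffect(8.40, 3.80, -0.32, 4.63, 3.19),
}


def default_effect_config() -> EffectConfig:
    """Shipped study conditions for the synthetic trial."""
    return EffectConfig(outcomes=dict(_DEFAULT_OUTCOMES))


def null_effect_config() -> EffectConfig:
    """Same noise structure but zero training effects and zero brain-change
    correlations — the complete null for type-I-error and FDR calibration."""
    outcomes = {
        name: OutcomeEffect(oe.pre_mean, oe.pre_sd, oe.control_change,
                            0.0, oe.change_sd, 0.0, 0.0)
        for name, oe in _DEFAULT_OUTCOMES.items()
    }
    return EffectConfig(
        outcomes=outcomes,
        amplitude=AmplitudeModel(bt_mean=1.0, act_mean=1.0, sd=0.4),
    )


def silent_noise() -> RecordingNoise:
    """A noise configuration with every stochastic component set to zero."""
    return RecordingNoise(
        systemic_coupling=0.0, slow_amp=0.0, mayer_amp=0.0, cardiac_amp=0.0,
        ar_sd=0.0, drift_slope_sd=0.0, shallow_noise_sd=0.0, deep_noise_sd=0.0,
    )


# --------------------------------------------------------------------------
# haemodynamic response
# --------------------------------------------------------------------------

def hrf(t, peak_delay: float = 6.0, undershoot_delay: float = 16.0,
        dispersion: float = 1.0, undershoot_ratio: float = 1.0 / 6.0):
    """Canonical double-gamma haemodynamic response, peak-normalized to 1.

    ``h(t) = g(t; peak_delay, dispersion) - undershoot_ratio *
    g(t; undershoot_delay, dispersion)`` with gamma-density components, so
    ``h(0) = 0`` and the response peaks near 5 s with the defaults.

    Parameters are in seconds; accepts scalars or arrays (t >= 0).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf is defined for t >= 0")
    main = _gamma_dist.pdf(t, peak_delay, scale=dispersion)
    under = _gamma_dist.pdf(t, undershoot_delay, scale=dispersion)
    raw = main - undershoot_ratio * under
    # normalize against the peak on a dense grid so amplitude has unit meaning
    grid = np.linspace(0, 32.0, 3201)
    ref = (_gamma_dist.pdf(grid, peak_delay, scale=dispersion)
           - undershoot_ratio * _gamma_dist.pdf(grid, undershoot_delay, scale=dispersion))
    out = raw / ref.max()
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# randomization
# --------------------------------------------------------------------------

def stratified_block_randomize(
    participants: Sequence[tuple[str, str]],
    block_size: int = 4,
    seed: int | np.random.SeedSequence | None = None,
    groups: tuple[str, str] = ("BT", "ACT"),
) -> dict[str, str]:
    """Sex-stratified blocked randomization with 1:1 allocation.

    Within each sex stratum, participants are taken in entry order and
    assigned in blocks of ``block_size``; every complete block contains
    exactly ``block_size/2`` per arm.  A final incomplete block is a random
    truncation of a balanced block, so stratum arm counts differ by at most
    one (and overall by at most one per stratum).

    Parameters
    ----------
    participants : sequence of (id, sex) pairs, in order of entry.
    block_size : even int, number of assignments per randomization block.
    seed : int or SeedSequence; the assignment is a deterministic function of it.
    """
    if block_size % 2 != 0 or block_size <= 0:
        raise ValueError("block_size must be a positive even number for 1:1 allocation")
    if seed is None:
        raise ValueError("a seed is required: assignments must be reproducible")
    ids = [pid for pid, _ in participants]
    if len(set(ids)) != len(ids):
        raise ValueError("participant ids must be unique")
    rng = np.random.default_rng(seed)

    strata: dict[str, list[str]] = {}
    for pid, sex in participants:
        strata.setdefault(sex, []).append(pid)

    half = block_size // 2
    template = np.array([groups[0]] * half + [groups[1]] * half)
    assignment: dict[str, str] = {}
    for sex in strata:  # insertion order: deterministic given input order
        members = strata[sex]
        for start in range(0, len(members), block_size):
            chunk = members[start:start + block_size]
            labels = rng.permutation(template)[: len(chunk)]
            assignment.update(zip(chunk, labels))
    return assignment


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Underlying normal (mu, sigma) for a log-normal with given mean and SD."""
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def make_cohort(
    n_per_group: int = 36,
    config: EffectConfig | None = None,
    seed: int | None = 0,
    block_size: int = 4,
) -> tuple[list[ParticipantRecord], dict[str, dict[str, float]]]:
    """Generate a randomized cohort with latent per-side neural amplitudes.

    The change score for outcome *o* of participant *i* is

    ``post - pre = control_change + training_effect*[BT]
                   + change_sd * (rho_L * z_L + rho_R * z_R
                                  + sqrt(1 - rho_L^2 - rho_R^2) * eps)``

    where ``z_L``, ``z_R`` are the participant's latent left/right neural
    amplitudes standardized by the analytic log-normal mean/SD, so the latent
    brain-change correlation is exactly ``rho`` in the noiseless limit.

    Returns the participant records and a map
    ``id -> {"left": amplitude, "right": amplitude}`` of the simulation
    ground truth.  Arm sizes are exactly ``n_per_group`` whenever each sex
    stratum size is a multiple of ``block_size`` (true for the default
    48 M / 24 F composition).

    Notes
    -----
    Each participant draws from an independent child stream of the master
    seed, so records are reproducible independent of generation order.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    config = config or default_effect_config()
    n = 2 * n_per_group
    n_male = int(round(n * config.male_fraction))
    sexes = ["M"] * n_male + ["F"] * (n - n_male)
    ids = [f"P{i + 1:03d}" for i in range(n)]

    master = np.random.SeedSequence(seed)
    rand_ss, *child_ss = master.spawn(n + 1)
    assignment = stratified_block_randomize(
        list(zip(ids, sexes)), block_size=block_size, seed=rand_ss)

    lo, hi = config.age_range
    participants: list[ParticipantRecord] = []
    amplitudes: dict[str, dict[str, float]] = {}
    for pid, sex, ss in zip(ids, sexes, child_ss):
        rng = np.random.default_rng(ss)
        group = assignment[pid]
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), lo, hi))

        amp_mean = (config.amplitude.bt_mean if group == "BT"
                    else config.amplitude.act_mean)
        mu, sigma = _lognormal_params(amp_mean, config.amplitude.sd)
        amp = {side: float(rng.lognormal(mu, sigma)) for side in ("left", "right")}
        if config.amplitude.sd > 0:
            z = {side: (amp[side] - amp_mean) / config.amplitude.sd
                 for side in ("left", "right")}
        else:
            z = {"left": 0.0, "right": 0.0}

        scores: dict[str, tuple[float, float]] = {}
        for name in OUTCOMES:
            oe = config.outcomes[name]
            pre = float(rng.normal(oe.pre_mean, oe.pre_sd))
            resid_scale = math.sqrt(max(0.0, 1.0 - oe.rho_left**2 - oe.rho_right**2))
            delta = (oe.control_change
                     + (oe.training_effect if group == "BT" else 0.0)
                     + oe.change_sd * (oe.rho_left * z["left"]
                                       + oe.rho_right * z["right"]
                                       + resid_scale * rng.standard_normal()))
            scores[name] = (pre, pre + delta)

        participants.append(ParticipantRecord(pid, group, sex, age, scores))
        amplitudes[pid] = amp
    return participants, amplitudes


# --------------------------------------------------------------------------
# recording simulation
# --------------------------------------------------------------------------

def _game_boxcar(schedule: BlockSchedule, fs: float) -> np.ndarray:
    n = schedule.n_samples(fs)
    box = np.zeros(n)
    for block in schedule.game_blocks():
        box[schedule.sample_slice(block, fs)] = 1.0
    return box


def neural_response(amplitude: float, fs: float, schedule: BlockSchedule,
                    kernel_duration: float = 30.0) -> np.ndarray:
    """Game boxcar convolved with the HRF, scaled to plateau ``amplitude``.

    The discrete HRF kernel is normalized to unit sum, so a sustained block
    drives the response toward ``amplitude`` (the asymptotic plateau).
    """
    n = schedule.n_samples(fs)
    tk = np.arange(0.0, kernel_duration, 1.0 / fs)
    kernel = hrf(tk)
    ksum = kernel.sum()
    if ksum <= 0:
        raise ValueError("HRF kernel must have positive area")
    kernel = kernel / ksum
    return amplitude * np.convolve(_game_boxcar(schedule, fs), kernel)[:n]


def simulate_recording(
    amplitude: float,
    fs: float = DEFAULT_FS,
    schedule: BlockSchedule | None = None,
    noise: RecordingNoise | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    participant_id: str = "sim",
    side: str = "left",
) -> Recording:
    """Simulate one dual source-detector recording.

    ``deep = amplitude * (boxcar (*) HRF) + coupling * systemic + drift + eps``
    and ``shallow = systemic + drift' + eps'``, where the systemic term
    (slow vasomotion + Mayer wave + cardiac sinusoids with random phases,
    plus AR(1) noise) is shared between channels — which is exactly what the
    short-separation regression downstream exploits.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    schedule = schedule or BlockSchedule.alternating()
    noise = noise or RecordingNoise()
    rng = np.random.default_rng(seed)
    n = schedule.n_samples(fs)
    t = np.arange(n) / fs

    systemic = np.zeros(n)
    for amp, freq in ((noise.slow_amp, noise.slow_freq),
                      (noise.mayer_amp, noise.mayer_freq),
                      (noise.cardiac_amp, noise.cardiac_freq)):
        phase = rng.uniform(0, 2 * np.pi)
        systemic += amp * np.sin(2 * np.pi * freq * t + phase)
    if noise.ar_sd > 0:
        innov = rng.normal(0.0, noise.ar_sd, size=n)
        ar = np.empty(n)
        ar[0] = innov[0] / math.sqrt(1 - noise.ar_phi**2)
        for i in range(1, n):
            ar[i] = noise.ar_phi * ar[i - 1] + innov[i]
        systemic += ar

    def drift() -> np.ndarray:
        slope = rng.normal(0.0, noise.drift_slope_sd)
        return slope * t

    shallow = systemic + drift() + rng.normal(0.0, noise.shallow_noise_sd, size=n)
    deep = (neural_response(amplitude, fs, schedule)
            + noise.systemic_coupling * systemic
            + drift()
            + rng.normal(0.0, noise.deep_noise_sd, size=n))
    return Recording(participant_id, side, fs, shallow, deep, schedule,
                     true_neural_amplitude=float(amplitude))


def simulate_cohort_recordings(
    participants: Iterable[ParticipantRecord],
    amplitudes: Mapping[str, Mapping[str, float]],
    fs: float = DEFAULT_FS,
    schedule: BlockSchedule | None = None,
    noise: RecordingNoise | None = None,
    seed: int | None = 0,
) -> list[Recording]:
    """Two recordings (left, right) per participant, one child seed stream each."""
    schedule = schedule or BlockSchedule.alternating()
    participants = list(participants)
    streams = np.random.SeedSequence(seed).spawn(2 * len(participants))
    recordings = []
    for i, p in enumerate(participants):
        for j, side in enumerate(("left", "right")):
            recordings.append(simulate_recording(
                amplitudes[p.id][side], fs=fs, schedule=schedule, noise=noise,
                seed=streams[2 * i + j], participant_id=p.id, side=side))
    return recordings
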