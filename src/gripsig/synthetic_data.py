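"""Study-shaped synthetic cohorts with known ground truth.

Generates per-subject, per-task pressure recordings whose grip-force profile,
region contribution weights, amplitude scaling, execution pace (time warp),
noise, spikes and saturation are all controlled, so every downstream stage can
be validated as a parameter-recovery problem without any external data.

GF profiles are parametric sums of raised-cosine bumps vanishing at both ends
of normalized time; region forces split the GF according to fixed weights, so
the ground-truth CGF is the weight vector itself.  Injected spikes are a
single frame wide by design, which a width-3 running median removes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core_io import PressureRecording, SensorLayout, ValidationError
from .preprocessing import KPA_TO_N
from .synchronization import T1_BOUNDS, T2_BOUNDS, WarpParams

__all__ = [
    "TaskTemplate",
    "SubjectEffects",
    "SyntheticConfig",
    "GroundTruth",
    "StudyData",
    "bump_profile",
    "default_templates",
    "generate_subject_recording",
    "generate_study",
]

SAMPLE_RATE_HZ = 50.0
PRESSURE_MAX_KPA = 517.0


def bump_profile(bumps: list[tuple[float, float, float]]) -> Callable[[np.ndarray], np.ndarray]:
    """Sum of raised-cosine bumps (center, width, height) on normalized time.

    Each bump is ``h * cos^2(pi (tau - c) / w)`` on |tau - c| < w/2 and zero
    outside, so the profile is smooth and vanishes wherever no bump reaches —
    in particular at tau = 0 and tau = 1 if every bump support lies inside.
    """
    for c, w, h in bumps:
        if c - w / 2 < 0 or c + w / 2 > 1:
            raise ValueError(f"bump (c={c}, w={w}) support must lie inside [0, 1]")
        if h < 0 or w <= 0:
            raise ValueError("bump width must be positive and height non-negative")

    def profile(tau: np.ndarray) -> np.ndarray:
        tau = np.asarray(tau, dtype=float)
        out = np.zeros_like(tau)
        for c, w, h in bumps:
            inside = np.abs(tau - c) < w / 2
            out[inside] += h * np.cos(np.pi * (tau[inside] - c) / w) ** 2
        return out

    return profile


@dataclass
class TaskTemplate:
    """Ground truth for one task: the GF profile and the region force split."""

    gf_profile: Callable[[np.ndarray], np.ndarray]
    region_weights: np.ndarray  # (18,), non-negative, sums to 1
    active_fraction: float = 0.5  # fraction of each region's sensels under load

    def __post_init__(self) -> None:
        self.region_weights = np.asarray(self.region_weights, dtype=float)
        if self.region_weights.shape != (18,):
            raise ValidationError("region_weights must have length 18")
        if np.any(self.region_weights < 0):
            raise ValidationError("region_weights must be non-negative")
        if abs(self.region_weights.sum() - 1.0) > 1e-9:
            raise ValidationError("region_weights must sum to 1")
        ends = self.gf_profile(np.array([0.0, 1.0]))
        if np.any(np.abs(ends) > 1e-12):
            raise ValidationError("gf_profile must vanish at tau = 0 and tau = 1")
        if not 0 < self.active_fraction <= 1:
            raise ValidationError("active_fraction must be in (0, 1]")


@dataclass
class SubjectEffects:
    """How one subject executes a task: amplitude, pace, and sensor nuisances."""

    amplitude_factor: float = 1.0
    warp: WarpParams = field(default_factory=WarpParams.identity)
    duration_s: float = 14.0
    noise_sd_kPa: float = 0.0
    spike_rate: float = 0.0  # expected spikes per sensel-second
    saturate: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_factor <= 0:
            raise ValidationError("amplitude_factor must be positive")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.noise_sd_kPa < 0 or self.spike_rate < 0:
            raise ValidationError("noise_sd_kPa and spike_rate must be non-negative")


@dataclass
class SyntheticConfig:
    n_subjects: int = 22
    n_tasks: int = 21
    templates: list[TaskTemplate] | None = None
    amplitude_sigma: float = 0.2  # lognormal sigma of the amplitude factor
    duration_mean_s: float = 14.0
    duration_sigma: float = 0.15  # lognormal sigma of task duration
    noise_sd_kPa: float = 0.0
    spike_rate: float = 0.0
    saturate: bool = False
    randomize_warps: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("need at least 2 subjects")
        if self.n_tasks < 1:
            raise ValidationError("need at least 1 task")


@dataclass
class GroundTruth:
    """Per-recording generating parameters, keyed by (subject_id, task_id)."""

    warps: dict[tuple[str, int], WarpParams]
    amplitudes: dict[tuple[str, int], float]
    durations: dict[tuple[str, int], float]
    region_weights: dict[int, np.ndarray]  # per task
    clipped_sensels: dict[tuple[str, int], list[int]]


@dataclass
class StudyData:
    recordings: dict[tuple[str, int], PressureRecording]
    ground_truth: GroundTruth


def _active_sensels(layout: SensorLayout, fraction: float) -> dict[int, np.ndarray]:
    out = {}
    for r in layout.regions:
        k = max(1, int(round(fraction * r.sensel_count)))
        out[r.id] = layout.sensel_index(r.id)[:k]
    return out


def generate_subject_recording_with_truth(
    template: TaskTemplate,
    effects: SubjectEffects,
    layout: SensorLayout,
    seed: int,
    subject_id: str = "S01",
    task_id: int = 1,
    sex: str | None = None,
) -> tuple[PressureRecording, dict]:
    """Generate one recording plus its generation record (clipped sensels etc.).

    The noiseless GF at subject time tau is
    ``amplitude_factor * gf_profile(warp.map(tau))``: the subject plays the
    canonical profile through their personal pace map, so applying the stored
    warp during synchronization recovers the template exactly.
    """
    rng = np.random.default_rng(seed)
    n = max(3, int(round(effects.duration_s * SAMPLE_RATE_HZ)) + 1)
    t = np.arange(n) / SAMPLE_RATE_HZ
    tau = t / t[-1]
    gf = effects.amplitude_factor * template.gf_profile(effects.warp.map(tau))  # (T,) N

    active = _active_sensels(layout, template.active_fraction)
    pressures = np.zeros((n, layout.n_sensels_total))
    for r_id, cols in active.items():
        w = template.region_weights[r_id - 1]
        if w == 0:
            continue
        per_sensel_force = w * gf / cols.size  # N per active sensel
        pressures[:, cols] = (per_sensel_force / KPA_TO_N)[:, None]

    if effects.noise_sd_kPa > 0:
        pressures += rng.normal(0.0, effects.noise_sd_kPa, size=pressures.shape)

    if effects.spike_rate > 0:
        lam = effects.spike_rate * layout.n_sensels_total * t[-1]
        n_spikes = rng.poisson(lam)
        occupied: set[tuple[int, int]] = set()
        placed = 0
        for _ in range(5 * n_spikes + 10):
            if placed >= n_spikes:
                break
            frame = int(rng.integers(1, n - 1))
            sensel = int(rng.integers(0, layout.n_sensels_total))
            # keep spikes single-frame and isolated in time on each sensel
            if any((frame + d, sensel) in occupied for d in (-1, 0, 1)):
                continue
            occupied.add((frame, sensel))
            pressures[frame, sensel] += rng.uniform(100.0, 400.0)
            placed += 1

    pressures = np.maximum(pressures, 0.0)
    clipped: list[int] = []
    if effects.saturate:
        over = pressures > PRESSURE_MAX_KPA
        clipped = sorted(int(c) + 1 for c in np.unique(np.where(over)[1]))
        pressures = np.minimum(pressures, PRESSURE_MAX_KPA)

    rec = PressureRecording(
        subject_id=subject_id,
        task_id=task_id,
        sample_rate_hz=SAMPLE_RATE_HZ,
        pressures=pressures,
        timestamps_s=t,
        sex=sex,
    )
    info = {
        "clipped_sensels": clipped,
        "noiseless_gf_n": gf,
        "active_sensels": {r: cols + 1 for r, cols in active.items()},
    }
    return rec, info


def generate_subject_recording(
    template: TaskTemplate,
    effects: SubjectEffects,
    layout: SensorLayout,
    seed: int,
    **kwargs,
) -> PressureRecording:
    rec, _ = generate_subject_recording_with_truth(template, effects, layout, seed, **kwargs)
    return rec


def default_templates(n_tasks: int, peak_range_n: tuple[float, float] = (5.0, 100.0),
                      seed: int = 12345) -> list[TaskTemplate]:
    """Deterministic family of task templates spanning the peak-force range.

    Each task gets one or two raised-cosine GF bumps and a distinct sparse
    region-weight pattern: a dominant thumb/palm opposition region plus a few
    finger regions, echoing the structure of real grasp signatures.
    """
    rng = np.random.default_rng(seed)
    templates = []
    for k in range(n_tasks):
        peak = peak_range_n[0] + (peak_range_n[1] - peak_range_n[0]) * (
            (k + 0.5) / n_tasks
        )
        if k % 3 == 2:
            bumps = [(0.32, 0.42, peak), (0.68, 0.42, 0.6 * peak)]
        else:
            bumps = [(0.5, 0.72, peak)]
        weights = np.full(18, 0.01)
        fingers = rng.choice(np.arange(2, 14), size=3, replace=False)
        opposer = rng.choice([0, 1, 14, 15, 16, 17])
        weights[fingers] += rng.dirichlet(np.ones(3)) * 0.5
        weights[opposer] += 0.32
        weights /= weights.sum()
        templates.append(TaskTemplate(gf_profile=bump_profile(bumps), region_weights=weights))
    return templates


def generate_study(config: SyntheticConfig, layout: SensorLayout) -> StudyData:
    """Generate the full cohort plus the ground-truth bundle.

    Reproducible bit-for-bit for a fixed ``config.rng_seed``; every recording
    gets an independent child seed.
    """
    templates = config.templates or default_templates(config.n_tasks)
    if len(templates) != config.n_tasks:
        raise ValidationError("need one template per task")

    root = np.random.SeedSequence(config.rng_seed)
    subj_ids = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    if len(set(subj_ids)) != len(subj_ids):
        raise ValidationError("duplicate subject ids")

    recordings: dict[tuple[str, int], PressureRecording] = {}
    warps: dict[tuple[str, int], WarpParams] = {}
    amplitudes: dict[tuple[str, int], float] = {}
    durations: dict[tuple[str, int], float] = {}
    clipped: dict[tuple[str, int], list[int]] = {}

    children = root.spawn(config.n_subjects * config.n_tasks)
    idx = 0
    for si, subject in enumerate(subj_ids):
        sex = "F" if si % 2 else "M"
        for task in range(1, config.n_tasks + 1):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            if config.randomize_warps:
                warp = WarpParams(
                    t1=float(rng.uniform(*T1_BOUNDS)),
                    t2=float(rng.uniform(*T2_BOUNDS)),
                    t1ref=float(rng.uniform(*T1_BOUNDS)),
                    t2ref=float(rng.uniform(*T2_BOUNDS)),
                )
            else:
                warp = WarpParams.identity()
            sigma_a = config.amplitude_sigma
            amplitude = float(rng.lognormal(-0.5 * sigma_a**2, sigma_a))
            sigma_d = config.duration_sigma
            duration = float(
                config.duration_mean_s * rng.lognormal(-0.5 * sigma_d**2, sigma_d)
            )
            effects = SubjectEffects(
                amplitude_factor=amplitude,
                warp=warp,
                duration_s=duration,
                noise_sd_kPa=config.noise_sd_kPa,
                spike_rate=config.spike_rate,
                saturate=config.saturate,
            )
            rec, info = generate_subject_recording_with_truth(
                templates[task - 1],
                effects,
                layout,
                seed=int(rng.integers(0, 2**31)),
                subject_id=subject,
                task_id=task,
                sex=sex,
            )
            key = (subject, task)
            recordings[key] = rec
            warps[key] = warp
            amplitudes[key] = amplitude
            durations[key] = duration
            clipped[key] = info["clipped_sensels"]

    truth = GroundTruth(
        warps=warps,
        amplitudes=amplitudes,
        durations=durations,
        region_weights={
            k + 1: templates[k].region_weights.copy() for k in range(config.n_tasks)
        },
        clipped_sensels=clipped,
    )
    return StudyData(recordings=recordings, ground_truth=truth)
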