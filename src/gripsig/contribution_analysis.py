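"""Post-synchronization statistics on grip-force sharing across hand regions.

The contribution to grip force (CGF) of a region at an instant is its force
divided by the total GF.  A subject x task mean CGF averages the instantaneous
ratios over the analysis window: the instants where GF exceeds its mean over
the task.  Pipeline order is fixed as synchronize -> scale to the reference
subject's mean GF -> discard outliers -> average.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ForceSeries, NormalizedCurve

__all__ = [
    "CGFMatrix",
    "PeakTable",
    "scale_to_reference",
    "discard_outliers",
    "mean_task_curve",
    "mean_cgf",
    "task_correlations",
    "region_correlations",
    "peak_table",
    "task_duration_stats",
]

log = logging.getLogger(__name__)

#: GF floor (N) guarding instantaneous CGF ratios against 0/0.
DEFAULT_EPSILON_N = 0.1


@dataclass
class CGFMatrix:
    """Subject x task x region mean-CGF fractions plus task-level averages."""

    subjects: list[str]
    tasks: list[int]
    mean_cgf: np.ndarray  # (S, K, 18), NaN where missing
    retained_subjects: dict[int, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        S, K = len(self.subjects), len(self.tasks)
        if self.mean_cgf.shape != (S, K, 18):
            raise ValueError("mean_cgf must be S x K x 18")

    @property
    def task_region_mean(self) -> np.ndarray:
        """(K, 18) region means over retained subjects per task."""
        out = np.full((len(self.tasks), 18), np.nan)
        for k, task in enumerate(self.tasks):
            keep = self.retained_subjects.get(task, self.subjects)
            rows = [self.subjects.index(s) for s in keep]
            out[k] = np.nanmean(self.mean_cgf[rows, k, :], axis=0)
        return out


@dataclass
class PeakTable:
    """Per-region peak force/pressure maxima (subject-averaged, max over tasks)."""

    region_ids: list[int]
    peak_force_n: np.ndarray  # (18,)
    peak_force_task: np.ndarray  # (18,) task ids
    peak_pressure_kpa: np.ndarray  # (18,)
    peak_pressure_task: np.ndarray  # (18,)


def scale_to_reference(
    gf_curves: dict[str, NormalizedCurve],
    region_curves: dict[str, np.ndarray],
    reference: str,
) -> tuple[dict[str, NormalizedCurve], dict[str, np.ndarray], dict[str, float]]:
    """Scale every subject's forces so each mean GF equals the reference's.

    The per-subject factor is meanGF(reference) / meanGF(subject) and is
    applied to all force channels; subjects with zero mean GF are dropped
    with a warning.
    """
    if reference not in gf_curves:
        raise ValueError(f"reference subject {reference!r} not in cohort")
    ref_mean = float(gf_curves[reference].values.mean())
    scaled_gf: dict[str, NormalizedCurve] = {}
    scaled_region: dict[str, np.ndarray] = {}
    factors: dict[str, float] = {}
    for s, curve in gf_curves.items():
        m = float(curve.values.mean())
        if m <= 0:
            log.warning("subject %s has zero mean GF; excluded from scaling", s)
            continue
        f = ref_mean / m
        factors[s] = f
        scaled_gf[s] = NormalizedCurve(curve.values * f)
        scaled_region[s] = region_curves[s] * f
    return scaled_gf, scaled_region, factors


def discard_outliers(gf_curves: dict[str, NormalizedCurve], n_discard: int = 4) -> list[str]:
    """Retain all but the ``n_discard`` subjects farthest from the mean curve.

    Distances are Euclidean over the 101-point grid to the pointwise mean over
    all subjects; ties break by subject id.  Returns the sorted retained list.
    """
    subjects = sorted(gf_curves)
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= len(subjects):
        raise ValueError(f"cannot discard {n_discard} of {len(subjects)} subjects")
    if n_discard == 0:
        return subjects
    stack = np.stack([gf_curves[s].values for s in subjects])
    mean = stack.mean(axis=0)
    dists = np.linalg.norm(stack - mean, axis=1)
    # stable sort on (-distance, id): the n_discard largest go, ids break ties
    order = sorted(range(len(subjects)), key=lambda i: (-dists[i], subjects[i]))
    dropped = {subjects[i] for i in order[:n_discard]}
    return [s for s in subjects if s not in dropped]


def mean_task_curve(
    gf_curves: dict[str, NormalizedCurve], retained: list[str] | None = None
) -> tuple[NormalizedCurve, NormalizedCurve]:
    """Pointwise mean and sample SD of the retained subjects' GF curves."""
    keep = sorted(gf_curves) if retained is None else list(retained)
    if len(keep) < 2:
        raise ValueError("need at least 2 retained subjects")
    stack = np.stack([gf_curves[s].values for s in keep])
    return NormalizedCurve(stack.mean(axis=0)), NormalizedCurve(stack.std(axis=0, ddof=1))


def mean_cgf(
    gf: np.ndarray, region_force: np.ndarray, epsilon_n: float = DEFAULT_EPSILON_N
) -> np.ndarray:
    """Mean per-region contribution over the above-mean-GF analysis window.

    The window is {t : GF(t) > mean_t GF}; instantaneous ratios are averaged
    over it, guarded by GF > epsilon to avoid 0/0.  If the window is empty
    (constant GF) all instants with GF > epsilon are used instead, flagged in
    the log.  The output 18-vector sums to 1 whenever the window is non-empty.
    """
    gf = np.asarray(gf, dtype=float)
    region_force = np.asarray(region_force, dtype=float)
    if not np.any(gf > 0):
        raise ValueError("GF is identically zero; CGF undefined")
    window = gf > gf.mean()
    window &= gf > epsilon_n
    if not np.any(window):
        log.warning("empty analysis window (constant GF?); falling back to GF > 0")
        window = gf > 0
    ratios = region_force[window] / gf[window, None]
    return ratios.mean(axis=0)


def mean_cgf_series(fs: ForceSeries, epsilon_n: float = DEFAULT_EPSILON_N) -> np.ndarray:
    """Convenience wrapper of :func:`mean_cgf` for a ForceSeries."""
    return mean_cgf(fs.gf_n, fs.region_force_n, epsilon_n=epsilon_n)


def _pearson_matrix(obs: np.ndarray) -> np.ndarray:
    """Pearson r between columns of obs; zero-variance columns give NaN."""
    obs = np.asarray(obs, dtype=float)
    centered = obs - obs.mean(axis=0)
    sd = centered.std(axis=0)
    n = obs.shape[1]
    out = np.full((n, n), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered
        denom = np.outer(sd, sd) * obs.shape[0]
        valid = denom > 0
        out[valid] = cov[valid] / denom[valid]
    np.fill_diagonal(out, np.where(sd > 0, 1.0, np.nan))
    if np.any(sd == 0):
        log.warning("%d zero-variance columns in correlation input", int(np.sum(sd == 0)))
    return out


def task_correlations(cgf: CGFMatrix) -> np.ndarray:
    """Pearson r between tasks' subject-averaged 18-region CGF patterns."""
    if len(cgf.tasks) < 2:
        raise ValueError("need at least 2 tasks")
    patterns = cgf.task_region_mean  # (K, 18)
    return _pearson_matrix(patterns.T)  # correlate tasks over the 18 regions


def region_correlations(cgf: CGFMatrix) -> np.ndarray:
    """Pearson r between region columns over all subject x task observations."""
    obs = cgf.mean_cgf.reshape(-1, 18)
    obs = obs[~np.isnan(obs).any(axis=1)]
    if obs.shape[0] < 2:
        raise ValueError("need at least 2 subject x task observations")
    return _pearson_matrix(obs)


def peak_table(
    region_peaks: dict[tuple[str, int], np.ndarray],
    pressure_peaks: dict[tuple[str, int], np.ndarray],
    retained_subjects: dict[int, list[str]],
    tasks: list[int],
) -> PeakTable:
    """Build the per-region peak force/pressure table.

    Inputs are per (subject, task): the 18-vector of per-region maxima over
    time of region force (N) and of within-region sensel pressure (kPa).
    Peaks are averaged over the retained subjects per task; each region then
    reports the maximum of these averages across tasks and the argmax task.
    """
    n_tasks = len(tasks)
    force_avg = np.full((n_tasks, 18), np.nan)
    press_avg = np.full((n_tasks, 18), np.nan)
    for k, task in enumerate(tasks):
        keep = retained_subjects.get(task, [])
        f_rows = [region_peaks[(s, task)] for s in keep if (s, task) in region_peaks]
        p_rows = [pressure_peaks[(s, task)] for s in keep if (s, task) in pressure_peaks]
        if f_rows:
            force_avg[k] = np.mean(f_rows, axis=0)
        if p_rows:
            press_avg[k] = np.mean(p_rows, axis=0)
    kf = np.nanargmax(force_avg, axis=0)
    kp = np.nanargmax(press_avg, axis=0)
    r = np.arange(18)
    return PeakTable(
        region_ids=list(range(1, 19)),
        peak_force_n=force_avg[kf, r],
        peak_force_task=np.asarray([tasks[i] for i in kf]),
        peak_pressure_kpa=press_avg[kp, r],
        peak_pressure_task=np.asarray([tasks[i] for i in kp]),
    )


def task_duration_stats(durations: dict[int, list[float]]) -> dict[int, dict]:
    """Five-number summary plus 1.5 x IQR outliers, per task."""
    out: dict[int, dict] = {}
    for task, vals in sorted(durations.items()):
        arr = np.asarray(sorted(vals), dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inliers = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
        out[task] = {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inliers.min()),
            "whisker_high": float(inliers.max()),
            "outliers": [float(v) for v in outliers],
            "n_outliers": int(outliers.size),
        }
    return out
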