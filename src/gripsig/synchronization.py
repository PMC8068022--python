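"""Cross-subject alignment with a bounded three-segment piecewise-linear warp.

Each subject's normalized GF curve is warped toward a reference subject (the
one closest to the cohort mean).  The warp maps normalized time through a
continuous, strictly increasing piecewise-linear function fixing 0 and 1, with
two interior knots (t1 -> t1ref, t2 -> t2ref) constrained to
t1, t1ref in [0.15, 0.35] and t2, t2ref in [0.65, 0.85].  The optimization
cost is the Euclidean distance between first derivatives of the warped
subject curve and the reference curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import differential_evolution

from .core_io import SensorLayout, ValidationError
from .preprocessing import TAU_GRID, ForceSeries, NormalizedCurve, lowpass_gf, normalize_time

__all__ = [
    "WarpParams",
    "SyncResult",
    "T1_BOUNDS",
    "T2_BOUNDS",
    "select_reference",
    "apply_warp",
    "sync_cost",
    "optimize_warp",
    "synchronize_task",
]

log = logging.getLogger(__name__)

T1_BOUNDS = (0.15, 0.35)
T2_BOUNDS = (0.65, 0.85)


@dataclass(frozen=True)
class WarpParams:
    """Knots of the three-segment warp: subject (t1, t2) -> reference (t1ref, t2ref)."""

    t1: float
    t2: float
    t1ref: float
    t2ref: float

    def __post_init__(self) -> None:
        for name, v, (lo, hi) in (
            ("t1", self.t1, T1_BOUNDS),
            ("t1ref", self.t1ref, T1_BOUNDS),
            ("t2", self.t2, T2_BOUNDS),
            ("t2ref", self.t2ref, T2_BOUNDS),
        ):
            if not lo - 1e-12 <= v <= hi + 1e-12:
                raise ValidationError(f"{name}={v} outside bounds [{lo}, {hi}]")

    @classmethod
    def identity(cls, t1: float = 0.25, t2: float = 0.75) -> "WarpParams":
        return cls(t1=t1, t2=t2, t1ref=t1, t2ref=t2)

    @property
    def is_identity(self) -> bool:
        return self.t1 == self.t1ref and self.t2 == self.t2ref

    def inverse(self) -> "WarpParams":
        """The warp with subject/reference roles swapped."""
        return WarpParams(t1=self.t1ref, t2=self.t2ref, t1ref=self.t1, t2ref=self.t2)

    def map(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate the forward map (subject time -> reference time)."""
        return np.interp(tau, [0.0, self.t1, self.t2, 1.0], [0.0, self.t1ref, self.t2ref, 1.0])

    def inverse_map(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate the inverse map (reference time -> subject time)."""
        return np.interp(tau, [0.0, self.t1ref, self.t2ref, 1.0], [0.0, self.t1, self.t2, 1.0])

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.t1, self.t2, self.t1ref, self.t2ref)


@dataclass
class SyncResult:
    """Outcome of synchronizing one task across subjects."""

    reference_subject: str
    warps: dict[str, WarpParams]
    costs: dict[str, float]
    warped_gf: dict[str, NormalizedCurve]
    warped_region: dict[str, np.ndarray]  # (101, 18) per subject
    warped_sensel: dict[str, np.ndarray] | None  # (101, 361) per subject
    pre_distance: dict[str, float] = field(default_factory=dict)
    post_distance: dict[str, float] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)


def select_reference(curves: dict[str, NormalizedCurve]) -> str:
    """Pick the subject whose curve is Euclidean-closest to the pointwise mean.

    Ties are broken by the lowest subject identifier, so the choice is
    deterministic.
    """
    if not curves:
        raise ValueError("cannot select a reference from an empty set")
    subjects = sorted(curves)
    stack = np.stack([curves[s].values for s in subjects])
    mean = stack.mean(axis=0)
    dists = np.linalg.norm(stack - mean, axis=1)
    return subjects[int(np.argmin(dists))]


def _resample(values: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Linear interpolation of grid-sampled values at points x in [0, 1]."""
    return np.interp(x, TAU_GRID, values)


def apply_warp(curve: NormalizedCurve, params: WarpParams) -> NormalizedCurve:
    """Warp a subject curve onto the reference time axis.

    With phi the piecewise-linear map taking (0, t1, t2, 1) to
    (0, t1ref, t2ref, 1), the output is curve(phi^-1(tau)) resampled on the
    101-point grid: a feature at subject time t1 lands at reference time t1ref.
    """
    x = params.inverse_map(TAU_GRID)
    return NormalizedCurve(_resample(curve.values, x))


def _derivative(values: np.ndarray) -> np.ndarray:
    # central differences inside, one-sided at the endpoints
    return np.gradient(values, TAU_GRID)


def sync_cost(
    subject_curve: NormalizedCurve, ref_curve: NormalizedCurve, params: WarpParams
) -> float:
    """Euclidean distance between first derivatives after warping the subject."""
    warped = apply_warp(subject_curve, params)
    return float(np.linalg.norm(_derivative(warped.values) - _derivative(ref_curve.values)))


def _lattice(resolution: float) -> np.ndarray:
    lo, hi = T1_BOUNDS
    n = int(round((hi - lo) / resolution))
    return lo + resolution * np.arange(n + 1)


def _grid_search(subject: np.ndarray, ref: np.ndarray, resolution: float) -> WarpParams:
    """Exhaustive search over the bound-respecting parameter lattice.

    Deterministic global lattice minimizer; ties resolve to the
    lexicographically smallest (t1, t2, t1ref, t2ref) tuple.
    """
    t1s = _lattice(resolution)
    t2s = T2_BOUNDS[0] + (t1s - T1_BOUNDS[0])
    dref = _derivative(ref)
    best_cost = np.inf
    best: tuple[float, float, float, float] | None = None
    # vectorize over (t1, t2) for each (t1ref, t2ref) pair
    t1g, t2g = np.meshgrid(t1s, t2s, indexing="ij")
    t1f, t2f = t1g.ravel(), t2g.ravel()  # (K,)
    for t1ref in t1s:
        for t2ref in t2s:
            # inverse map of the grid for all (t1, t2) at once
            x = np.empty((t1f.size, TAU_GRID.size))
            g = TAU_GRID
            seg1 = g <= t1ref
            seg3 = g >= t2ref
            seg2 = ~(seg1 | seg3)
            x[:, seg1] = np.outer(t1f / t1ref, g[seg1])
            x[:, seg2] = t1f[:, None] + np.outer(
                (t2f - t1f) / (t2ref - t1ref), g[seg2] - t1ref
            )
            x[:, seg3] = t2f[:, None] + np.outer(
                (1.0 - t2f) / (1.0 - t2ref), g[seg3] - t2ref
            )
            warped = np.interp(x, TAU_GRID, subject).reshape(x.shape)
            dw = np.gradient(warped, TAU_GRID, axis=1)
            costs = np.linalg.norm(dw - dref, axis=1)
            k = int(np.argmin(costs))
            if costs[k] < best_cost - 1e-15:
                best_cost = costs[k]
                best = (float(t1f[k]), float(t2f[k]), float(t1ref), float(t2ref))
            elif best is not None and abs(costs[k] - best_cost) <= 1e-15:
                cand = (float(t1f[k]), float(t2f[k]), float(t1ref), float(t2ref))
                if cand < best:
                    best = cand
    assert best is not None
    return WarpParams(t1=best[0], t2=best[1], t1ref=best[2], t2ref=best[3])


def _stochastic_search(subject: np.ndarray, ref: np.ndarray, seed: int) -> WarpParams:
    """Seeded population-based global search over the continuous box."""
    dref = _derivative(ref)

    def cost(v: np.ndarray) -> float:
        x = np.interp(TAU_GRID, [0.0, v[2], v[3], 1.0], [0.0, v[0], v[1], 1.0])
        warped = np.interp(x, TAU_GRID, subject)
        return float(np.linalg.norm(_derivative(warped) - dref))

    res = differential_evolution(
        cost,
        bounds=[T1_BOUNDS, T2_BOUNDS, T1_BOUNDS, T2_BOUNDS],
        seed=seed,
        maxiter=200,
        popsize=30,
        tol=1e-10,
        polish=True,
    )
    return WarpParams(
        t1=float(np.clip(res.x[0], *T1_BOUNDS)),
        t2=float(np.clip(res.x[1], *T2_BOUNDS)),
        t1ref=float(np.clip(res.x[2], *T1_BOUNDS)),
        t2ref=float(np.clip(res.x[3], *T2_BOUNDS)),
    )


def optimize_warp(
    subject_curve: NormalizedCurve,
    ref_curve: NormalizedCurve,
    resolution: float = 0.01,
    strategy: str = "grid",
    seed: int = 0,
) -> WarpParams:
    """Find warp knots minimizing the derivative distance to the reference.

    strategy="grid" (default) searches the full 21^4 bound-respecting lattice
    at the given resolution and is deterministic; strategy="stochastic" runs a
    seeded differential-evolution search over the continuous box.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if strategy == "grid":
        return _grid_search(subject_curve.values, ref_curve.values, resolution)
    if strategy == "stochastic":
        return _stochastic_search(subject_curve.values, ref_curve.values, seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def _warp_columns(matrix: np.ndarray, params: WarpParams) -> np.ndarray:
    """Apply the same warp to every column of a (101, k) matrix."""
    x = params.inverse_map(TAU_GRID)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        out[:, j] = np.interp(x, TAU_GRID, matrix[:, j])
    return out


def synchronize_task(
    force_series: dict[str, ForceSeries],
    layout: SensorLayout,
    sensel_pressures: dict[str, np.ndarray] | None = None,
    strategy: str = "grid",
    resolution: float = 0.01,
    seed: int = 0,
) -> SyncResult:
    """Run the full three-step synchronization for one task.

    1. Normalize each subject's GF to the 101-point grid (and low-pass filter
       a copy at the native rate for the optimization cost).
    2. Average the filtered curves and pick the reference subject.
    3. Optimize each remaining subject's warp and apply it to the unfiltered
       GF, the 18 region-force series and (optionally) every sensel series.

    Subjects whose GF is identically zero are excluded with a warning: the
    derivative cost carries no information for a flat-zero curve.
    """
    if len(force_series) < 2:
        raise ValueError("synchronization needs at least 2 subjects")

    excluded = [s for s, fs in force_series.items() if not np.any(fs.gf_n > 0)]
    for s in excluded:
        log.warning("subject %s has identically-zero GF; excluded from synchronization", s)
    cohort = {s: fs for s, fs in force_series.items() if s not in excluded}
    if len(cohort) < 2:
        raise ValueError("fewer than 2 subjects with nonzero GF")

    raw_gf: dict[str, NormalizedCurve] = {}
    filt_gf: dict[str, NormalizedCurve] = {}
    region_curves: dict[str, np.ndarray] = {}
    for s, fs in cohort.items():
        raw_gf[s] = normalize_time(fs.gf_n, fs.timestamps_s)
        rate = 1.0 / float(np.median(np.diff(fs.timestamps_s)))
        filtered = lowpass_gf(fs.gf_n, sample_rate_hz=rate)
        filt_gf[s] = normalize_time(filtered, fs.timestamps_s)
        region_curves[s] = np.column_stack(
            [normalize_time(fs.region_force_n[:, r], fs.timestamps_s).values for r in range(18)]
        )

    ref = select_reference(filt_gf)

    warps: dict[str, WarpParams] = {}
    costs: dict[str, float] = {}
    warped_gf: dict[str, NormalizedCurve] = {}
    warped_region: dict[str, np.ndarray] = {}
    warped_sensel: dict[str, np.ndarray] | None = {} if sensel_pressures is not None else None
    pre_d: dict[str, float] = {}
    post_d: dict[str, float] = {}
    ref_vals = filt_gf[ref].values

    for s in sorted(cohort):
        if s == ref:
            params = WarpParams.identity()
        else:
            params = optimize_warp(
                filt_gf[s], filt_gf[ref], resolution=resolution, strategy=strategy, seed=seed
            )
        warps[s] = params
        costs[s] = sync_cost(filt_gf[s], filt_gf[ref], params)
        warped_gf[s] = apply_warp(raw_gf[s], params)
        warped_region[s] = _warp_columns(region_curves[s], params)
        pre_d[s] = float(np.linalg.norm(filt_gf[s].values - ref_vals))
        post_d[s] = float(
            np.linalg.norm(apply_warp(filt_gf[s], params).values - ref_vals)
        )
        if warped_sensel is not None:
            fs = cohort[s]
            press = sensel_pressures[s]
            norm = np.column_stack(
                [
                    np.interp(
                        TAU_GRID,
                        (fs.timestamps_s - fs.timestamps_s[0])
                        / (fs.timestamps_s[-1] - fs.timestamps_s[0]),
                        press[:, j],
                    )
                    for j in range(press.shape[1])
                ]
            )
            warped_sensel[s] = _warp_columns(norm, params)

    return SyncResult(
        reference_subject=ref,
        warps=warps,
        costs=costs,
        warped_gf=warped_gf,
        warped_region=warped_region,
        warped_sensel=warped_sensel,
        pre_distance=pre_d,
        post_distance=post_d,
        excluded=excluded,
    )
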