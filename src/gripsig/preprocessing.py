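"""Sensel-level cleaning and conversion of pressures into force time series.

Order of the standard pipeline: running-median despike per sensel, discard of
saturated sensels, then conversion of pressures to per-sensel forces
(pressure x 16 mm^2) aggregated into 18 region forces and the total grip
force (GF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .core_io import PressureRecording, SensorLayout, ValidationError

__all__ = [
    "ForceSeries",
    "NormalizedCurve",
    "TAU_GRID",
    "median_filter_sensels",
    "mask_saturated_sensels",
    "compute_forces",
    "normalize_time",
    "lowpass_gf",
    "preprocess_recording",
]

log = logging.getLogger(__name__)

#: The shared normalized-time grid: 101 points, 0.00 .. 1.00 in steps of 0.01.
TAU_GRID = np.linspace(0.0, 1.0, 101)

#: kPa -> N conversion for one sensel: 1 kPa x 16 mm^2 = 1000 Pa x 16e-6 m^2.
KPA_TO_N = 1000.0 * 16e-6


@dataclass
class ForceSeries:
    """GF and per-region force time series derived from one recording."""

    subject_id: str
    task_id: int
    timestamps_s: np.ndarray
    gf_n: np.ndarray  # (T,)
    region_force_n: np.ndarray  # (T, 18)
    discarded_sensels: frozenset[int]

    def __post_init__(self) -> None:
        self.gf_n = np.asarray(self.gf_n, dtype=float)
        self.region_force_n = np.asarray(self.region_force_n, dtype=float)
        if self.region_force_n.shape != (self.gf_n.shape[0], 18):
            raise ValidationError("region_force_n must be T x 18")
        if np.any(self.gf_n < -1e-12) or np.any(self.region_force_n < -1e-12):
            raise ValidationError("forces must be non-negative")
        resid = np.abs(self.gf_n - self.region_force_n.sum(axis=1))
        if np.any(resid > 1e-9):
            raise ValidationError(
                f"GF must equal the sum of region forces (max residual {resid.max():.3g} N)"
            )


@dataclass(frozen=True)
class NormalizedCurve:
    """A curve resampled onto the shared 101-point normalized-time grid."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (101,):
            raise ValidationError("NormalizedCurve values must have length 101")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("NormalizedCurve values must be finite")

    @property
    def grid(self) -> np.ndarray:
        return TAU_GRID


def median_filter_sensels(rec: PressureRecording, window: int = 3) -> PressureRecording:
    """Running median along time for every sensel, replicate-padded at edges."""
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be an odd integer >= 3, got {window}")
    if rec.n_frames < window:
        raise ValueError("recording shorter than the filter window")
    filtered = ndimage.median_filter(rec.pressures, size=(window, 1), mode="nearest")
    out = rec.copy()
    out.pressures = filtered
    return out


def mask_saturated_sensels(
    rec: PressureRecording, threshold_kPa: float = 517.0
) -> tuple[PressureRecording, frozenset[int]]:
    """Zero every sensel that reaches the saturation threshold at any frame.

    A cell that clipped is untrustworthy for the whole grasp, so the discard is
    per sensel, not per frame.  Returns the cleaned recording and the set of
    discarded 1-based sensel ids.
    """
    if threshold_kPa <= 0:
        raise ValueError("threshold must be positive")
    saturated_cols = np.where(np.any(rec.pressures >= threshold_kPa, axis=0))[0]
    discarded = frozenset(int(c) + 1 for c in saturated_cols)
    out = rec.copy()
    if discarded:
        sat_frames = int(np.sum(rec.pressures >= threshold_kPa))
        frac_sensels = len(discarded) / rec.pressures.shape[1]
        frac_frames = sat_frames / rec.pressures.size
        log.info(
            "recording %s/task %d: discarding %d saturated sensels "
            "(%.2f%% of sensels, %.4f%% of frames saturated)",
            rec.subject_id, rec.task_id, len(discarded),
            100 * frac_sensels, 100 * frac_frames,
        )
        out.pressures = rec.pressures.copy()
        out.pressures[:, saturated_cols] = 0.0
        if len(discarded) == rec.pressures.shape[1]:
            log.warning("all sensels saturated; grip force will be identically zero")
    out.discarded_sensels = rec.discarded_sensels | discarded
    return out, discarded


def compute_forces(rec: PressureRecording, layout: SensorLayout) -> ForceSeries:
    """Convert sensel pressures to forces and aggregate per region and in total.

    Force per sensel is pressure (kPa) times the sensel contact area
    (16 mm^2); region forces sum the region's sensels and GF sums everything.
    """
    if rec.pressures.shape[1] != layout.n_sensels_total:
        raise ValidationError("recording and layout disagree on sensel count")
    sensel_force = rec.pressures * KPA_TO_N  # (T, 361) in N
    region_force = np.empty((rec.n_frames, 18))
    for r in sorted(layout.regions, key=lambda r: r.id):
        region_force[:, r.id - 1] = sensel_force[:, layout.sensel_index(r.id)].sum(axis=1)
    gf = region_force.sum(axis=1)
    return ForceSeries(
        subject_id=rec.subject_id,
        task_id=rec.task_id,
        timestamps_s=rec.timestamps_s.copy(),
        gf_n=gf,
        region_force_n=region_force,
        discarded_sensels=rec.discarded_sensels,
    )


def normalize_time(values: np.ndarray, timestamps_s: np.ndarray) -> NormalizedCurve:
    """Map a time series onto normalized time and resample on the 101 grid.

    Timestamps are rescaled to [0, 1] and values are linearly interpolated at
    increments of 0.01; endpoints are preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(timestamps_s, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to normalize time")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    tau = (t - t[0]) / (t[-1] - t[0])
    out = np.interp(TAU_GRID, tau, values)
    out[0], out[-1] = values[0], values[-1]
    return NormalizedCurve(out)


def lowpass_gf(
    series: np.ndarray, sample_rate_hz: float = 50.0, cutoff_hz: float = 10.0, order: int = 3
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter of the GF series.

    Applied forward-backward (no phase lag) at the native sample rate, where
    the cutoff frequency is physically meaningful.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= 3 * order:
        raise ValueError(f"series too short for order-{order} zero-phase filtering")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=sample_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, series)


def preprocess_recording(
    rec: PressureRecording,
    layout: SensorLayout,
    window: int = 3,
    saturation_kPa: float = 517.0,
) -> ForceSeries:
    """Standard cleaning chain: median despike, saturation discard, forces."""
    filtered = median_filter_sensels(rec, window=window)
    masked, _ = mask_saturated_sensels(filtered, threshold_kPa=saturation_kPa)
    return compute_forces(masked, layout)
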