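"""Data model and on-disk formats for sensor layouts and pressure recordings.

The on-disk dialect is deliberately plain: a wide CSV with one row per frame
(``time_s,s001..s361``) plus a small JSON sidecar holding the metadata, and a
JSON document for the sensor layout.  Everything is validated on load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Region",
    "SensorLayout",
    "PressureRecording",
    "load_layout",
    "default_layout",
    "read_recording",
    "write_recording",
    "read_study_dir",
    "write_study_dir",
    "PSI_TO_KPA",
]

#: 75 psi full scale corresponds to 517 kPa.
PSI_TO_KPA = 517.0 / 75.0

N_SENSELS = 361
N_REGIONS = 18

_TABLE_COUNTS = (16, 12, 16, 12, 12, 16, 12, 12, 16, 12, 12, 16, 12, 12, 16, 60, 45, 52)


class FormatError(ValueError):
    """A document does not match the expected on-disk format."""


class ValidationError(ValueError):
    """A document parsed fine but violates a domain invariant."""


@dataclass(frozen=True)
class Region:
    id: int
    label: str
    region_class: str  # one of {"thumb", "finger", "palm"}
    sensel_ids: tuple[int, ...]
    render_xy: tuple[float, float]

    @property
    def sensel_count(self) -> int:
        return len(self.sensel_ids)


@dataclass(frozen=True)
class SensorLayout:
    """The 18-region / 361-sensel map with geometry constants."""

    regions: tuple[Region, ...]
    pitch_mm: float = 4.0
    sensel_area_mm2: float = 16.0
    pressure_max_kPa: float = 517.0
    n_sensels_total: int = N_SENSELS

    def __post_init__(self) -> None:
        ids = sorted(r.id for r in self.regions)
        if ids != list(range(1, N_REGIONS + 1)):
            raise ValidationError(f"region ids must be exactly 1..{N_REGIONS}, got {ids}")
        total = sum(r.sensel_count for r in self.regions)
        if total != self.n_sensels_total:
            raise ValidationError(
                f"sensel counts sum to {total}, expected {self.n_sensels_total}"
            )
        counts = tuple(r.sensel_count for r in sorted(self.regions, key=lambda r: r.id))
        if counts != _TABLE_COUNTS:
            raise ValidationError(
                f"per-region sensel counts {counts} do not match the reference layout"
            )
        all_ids = sorted(s for r in self.regions for s in r.sensel_ids)
        if all_ids != list(range(1, self.n_sensels_total + 1)):
            raise ValidationError("sensel_ids must partition 1..361 with no overlap")
        if abs(self.sensel_area_mm2 - self.pitch_mm**2) > 1e-9:
            raise ValidationError("sensel_area_mm2 must equal pitch_mm squared")
        for r in self.regions:
            expected = "thumb" if r.id <= 2 else ("finger" if r.id <= 14 else "palm")
            if r.region_class != expected:
                raise ValidationError(
                    f"region {r.id} has class {r.region_class!r}, expected {expected!r}"
                )

    def region(self, region_id: int) -> Region:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(region_id)

    @property
    def region_ids(self) -> tuple[int, ...]:
        return tuple(r.id for r in sorted(self.regions, key=lambda r: r.id))

    def sensel_index(self, region_id: int) -> np.ndarray:
        """0-based column indices of a region's sensels in a pressure matrix."""
        return np.asarray(self.region(region_id).sensel_ids, dtype=int) - 1

    @property
    def sensel_region(self) -> np.ndarray:
        """Length-361 vector mapping each 0-based sensel index to its region id."""
        out = np.zeros(self.n_sensels_total, dtype=int)
        for r in self.regions:
            out[np.asarray(r.sensel_ids) - 1] = r.id
        return out


@dataclass
class PressureRecording:
    """One subject x task pressure matrix (T frames x 361 sensels, kPa)."""

    subject_id: str
    task_id: int
    sample_rate_hz: float
    pressures: np.ndarray
    timestamps_s: np.ndarray
    sex: str | None = None
    notes: str | None = None
    discarded_sensels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.pressures.ndim != 2 or self.pressures.shape[1] != N_SENSELS:
            raise ValidationError(
                f"pressures must be T x {N_SENSELS}, got shape {self.pressures.shape}"
            )
        T = self.pressures.shape[0]
        if T < 3:
            raise ValidationError("recording must have at least 3 frames")
        if self.timestamps_s.shape != (T,):
            raise ValidationError("timestamps length must match number of frames")
        if not np.all(np.isfinite(self.pressures)):
            raise ValidationError("pressures must be finite")
        if np.any(self.pressures < 0):
            raise ValidationError("pressures must be non-negative")
        if np.any(np.diff(self.timestamps_s) < 0):
            raise ValidationError("timestamps must be nondecreasing")
        if not 1 <= int(self.task_id) <= 21:
            raise ValidationError(f"task_id must be in 1..21, got {self.task_id}")
        dt = np.diff(self.timestamps_s)
        if dt.size and self.sample_rate_hz > 0:
            expected = 1.0 / self.sample_rate_hz
            if np.any(np.abs(dt - expected) > 0.01 * expected + 1e-9):
                raise ValidationError("timestamps not uniform at the stated sample rate")

    @property
    def n_frames(self) -> int:
        return self.pressures.shape[0]

    def copy(self) -> "PressureRecording":
        return PressureRecording(
            subject_id=self.subject_id,
            task_id=self.task_id,
            sample_rate_hz=self.sample_rate_hz,
            pressures=self.pressures.copy(),
            timestamps_s=self.timestamps_s.copy(),
            sex=self.sex,
            notes=self.notes,
            discarded_sensels=self.discarded_sensels,
        )


def _parse_layout_doc(doc: dict) -> SensorLayout:
    if not isinstance(doc, dict) or "regions" not in doc:
        raise FormatError("layout document missing 'regions' field")
    regions = []
    for entry in doc["regions"]:
        for key in ("id", "label", "class", "sensel_ids", "render_xy"):
            if key not in entry:
                raise FormatError(f"layout region entry missing field {key!r}")
        regions.append(
            Region(
                id=int(entry["id"]),
                label=str(entry["label"]),
                region_class=str(entry["class"]),
                sensel_ids=tuple(int(s) for s in entry["sensel_ids"]),
                render_xy=(float(entry["render_xy"][0]), float(entry["render_xy"][1])),
            )
        )
    kwargs = {}
    for key, attr in (
        ("pitch_mm", "pitch_mm"),
        ("sensel_area_mm2", "sensel_area_mm2"),
        ("pressure_max_kPa", "pressure_max_kPa"),
        ("n_sensels_total", "n_sensels_total"),
    ):
        if key in doc:
            kwargs[attr] = type(SensorLayout.__dataclass_fields__[attr].default)(doc[key])
    return SensorLayout(regions=tuple(regions), **kwargs)


def load_layout(path: str | Path) -> SensorLayout:
    """Load and validate a sensor layout from a JSON document."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"layout file is not valid JSON: {exc}") from exc
    return _parse_layout_doc(doc)


def default_layout() -> SensorLayout:
    """The packaged 18-region / 361-sensel layout."""
    text = resources.files("gripsig").joinpath("data/layout_default.json").read_text()
    return _parse_layout_doc(json.loads(text))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(path: str | Path, layout: SensorLayout | None = None) -> PressureRecording:
    """Read a recording CSV plus its JSON sidecar.

    The CSV has header ``time_s,s001..s361`` and one row per frame; the sidecar
    (same stem, ``.json``) carries subject/task/sample-rate metadata.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("subject_id", "task_id", "sample_rate_hz"):
        if key not in meta:
            raise FormatError(f"sidecar missing key {key!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    expected_cols = ["time_s"] + [f"s{i:03d}" for i in range(1, N_SENSELS + 1)]
    if list(df.columns) != expected_cols:
        raise FormatError(
            f"CSV columns do not match expected header "
            f"(got {len(df.columns)} columns, expected {len(expected_cols)})"
        )
    return PressureRecording(
        subject_id=str(meta["subject_id"]),
        task_id=int(meta["task_id"]),
        sample_rate_hz=float(meta["sample_rate_hz"]),
        pressures=df[expected_cols[1:]].to_numpy(dtype=float),
        timestamps_s=df["time_s"].to_numpy(dtype=float),
        sex=meta.get("sex"),
        notes=meta.get("notes"),
    )


def write_recording(rec: PressureRecording, path: str | Path) -> None:
    """Write a recording as CSV + JSON sidecar, losslessly round-trippable."""
    path = Path(path)
    cols = ["time_s"] + [f"s{i:03d}" for i in range(1, N_SENSELS + 1)]
    df = pd.DataFrame(
        np.column_stack([rec.timestamps_s, rec.pressures]), columns=cols
    )
    # repr-precision floats so read_recording reproduces bit-identical values
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "subject_id": rec.subject_id,
        "task_id": rec.task_id,
        "sample_rate_hz": rec.sample_rate_hz,
    }
    if rec.sex is not None:
        meta["sex"] = rec.sex
    if rec.notes is not None:
        meta["notes"] = rec.notes
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def _recording_stem(subject_id: str, task_id: int) -> str:
    return f"sub_{subject_id}_task_{task_id:02d}"


def write_study_dir(
    recordings: dict[tuple[str, int], PressureRecording], out_dir: str | Path
) -> None:
    """Write a study's recordings as one CSV+sidecar pair each."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for (subject, task), rec in sorted(recordings.items()):
        write_recording(rec, out_dir / f"{_recording_stem(subject, task)}.csv")


def read_study_dir(
    in_dir: str | Path, layout: SensorLayout | None = None
) -> dict[tuple[str, int], PressureRecording]:
    """Read every recording CSV (with sidecar) found in a directory."""
    in_dir = Path(in_dir)
    out: dict[tuple[str, int], PressureRecording] = {}
    for csv_path in sorted(in_dir.glob("*.csv")):
        if not _sidecar_path(csv_path).exists():
            continue  # not a recording (e.g. an output table)
        rec = read_recording(csv_path, layout)
        key = (rec.subject_id, rec.task_id)
        if key in out:
            raise FormatError(f"duplicate recording for subject {key[0]}, task {key[1]}")
        out[key] = rec
    if not out:
        raise FormatError(f"no recordings found in {in_dir}")
    return out
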