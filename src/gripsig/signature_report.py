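"""Tactile-signature opposition graphs and the end-to-end report bundle.

A task's signature is its 18 mean region CGF values drawn as circles on a
schematic hand, with lines connecting finger regions to thumb or palm regions
whenever both exceed a contribution threshold (default 5%) — the grasp's
opposition pattern.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import contribution_analysis as ca
from . import stats as st
from .core_io import SensorLayout, ValidationError
from .preprocessing import TAU_GRID, median_filter_sensels, mask_saturated_sensels, compute_forces
from .synchronization import synchronize_task
from .synthetic_data import StudyData

__all__ = ["SignatureGraph", "build_signature", "render_signature", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureGraph:
    """Thresholded opposition graph for one task's mean CGF pattern."""

    cgf: np.ndarray  # (18,)
    edges: tuple[tuple[int, int], ...]  # (finger_region, opposing_region), 1-based
    threshold: float
    render_xy: tuple[tuple[float, float], ...]


def build_signature(
    mean_cgf: np.ndarray, layout: SensorLayout, threshold: float = 0.05
) -> SignatureGraph:
    """Build the opposition graph from an 18-vector of mean CGF fractions.

    An edge (f, o) exists iff f is a finger-class region, o is a thumb- or
    palm-class region, and both CGFs exceed the threshold.  Finger-finger,
    palm-palm and thumb-palm pairs are never connected.
    """
    cgf = np.asarray(mean_cgf, dtype=float)
    if cgf.shape != (18,):
        raise ValidationError("mean_cgf must have length 18")
    if abs(cgf.sum() - 1.0) > 1e-6:
        raise ValidationError(f"mean_cgf must sum to 1 (got {cgf.sum():.8f})")
    classes = {r.id: r.region_class for r in layout.regions}
    fingers = sorted(r for r, c in classes.items() if c == "finger")
    opposers = sorted(r for r, c in classes.items() if c in ("thumb", "palm"))
    edges = tuple(
        (f, o)
        for f in fingers
        for o in opposers
        if cgf[f - 1] > threshold and cgf[o - 1] > threshold
    )
    xy = tuple(layout.region(r).render_xy for r in range(1, 19))
    return SignatureGraph(cgf=cgf, edges=edges, threshold=threshold, render_xy=xy)


def render_signature(
    graph: SignatureGraph, layout: SensorLayout, path: str | Path, max_radius: float = 0.45
) -> None:
    """Write the graph as a deterministic standalone SVG.

    Circle radii are linearly proportional to CGF (the largest contribution
    gets ``max_radius`` in hand-frame units); edges are straight segments.
    Byte-identical output for identical input.
    """
    xs = [p[0] for p in graph.render_xy]
    ys = [p[1] for p in graph.render_xy]
    pad = 1.0
    x0, x1 = min(xs) - pad, max(xs) + pad
    y0, y1 = min(ys) - pad, max(ys) + pad
    scale = 60.0  # px per hand-frame unit
    width, height = (x1 - x0) * scale, (y1 - y0) * scale

    def px(x: float, y: float) -> tuple[float, float]:
        # y axis flipped: SVG grows downward, the hand frame grows upward
        return ((x - x0) * scale, (y1 - y) * scale)

    peak = float(graph.cgf.max())
    radii = graph.cgf / peak * max_radius * scale if peak > 0 else np.zeros(18)

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.1f}" '
        f'height="{height:.1f}" viewBox="0 0 {width:.1f} {height:.1f}">',
        f'<!-- opposition threshold: {graph.threshold:.4f} -->',
    ]
    for f, o in graph.edges:
        ax, ay = px(*graph.render_xy[f - 1])
        bx, by = px(*graph.render_xy[o - 1])
        parts.append(
            f'<line x1="{ax:.2f}" y1="{ay:.2f}" x2="{bx:.2f}" y2="{by:.2f}" '
            'stroke="#555555" stroke-width="2"/>'
        )
    for rid in range(1, 19):
        cx, cy = px(*graph.render_xy[rid - 1])
        parts.append(
            f'<circle cx="{cx:.2f}" cy="{cy:.2f}" r="{radii[rid - 1]:.3f}" '
            'fill="#1f77b4" fill-opacity="0.75" stroke="#10405f" stroke-width="1"/>'
        )
        parts.append(
            f'<text x="{cx:.2f}" y="{cy:.2f}" font-size="10" text-anchor="middle" '
            f'dy="3">{rid}</text>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")


def run_pipeline(
    study: StudyData,
    layout: SensorLayout,
    out_dir: str | Path,
    n_discard: int = 4,
    epsilon_n: float = ca.DEFAULT_EPSILON_N,
    threshold: float = 0.05,
    strategy: str = "grid",
    resolution: float = 0.01,
    seed: int = 0,
    warp_sensels: bool = True,
) -> dict:
    """Run preprocess -> sync -> analyze -> stats -> signatures for every task.

    Writes per-task signature SVG/JSON and sync_result.json, plus the CSV
    tables (mean curves, CGF matrix, correlations, peaks, durations, ANOVA)
    and a summary log.  Returns the in-memory results dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    recs = study.recordings
    if not recs:
        raise ValueError("empty study")
    subjects = sorted({s for s, _ in recs})
    tasks = sorted({t for _, t in recs})

    # --- preprocessing -----------------------------------------------------
    force = {}
    clean_press = {}
    discarded_sensels = {}
    for key, rec in recs.items():
        filtered = median_filter_sensels(rec)
        masked, disc = mask_saturated_sensels(filtered, threshold_kPa=layout.pressure_max_kPa)
        force[key] = compute_forces(masked, layout)
        clean_press[key] = masked.pressures
        discarded_sensels[key] = sorted(disc)

    results: dict = {"tasks": {}, "subjects": subjects}
    S, K = len(subjects), len(tasks)
    cgf_cube = np.full((S, K, 18), np.nan)
    retained_map: dict[int, list[str]] = {}
    region_peaks = {}
    pressure_peaks = {}
    mean_rows = []

    for k, task in enumerate(tasks):
        cohort = {s: force[(s, task)] for s in subjects if (s, task) in force}
        if len(cohort) < 2:
            log.warning("task %d has fewer than 2 subjects; skipped", task)
            continue
        press = {s: clean_press[(s, task)] for s in cohort}
        sync = synchronize_task(
            cohort, layout,
            sensel_pressures=press if warp_sensels else None,
            strategy=strategy, resolution=resolution, seed=seed,
        )
        scaled_gf, scaled_region, factors = ca.scale_to_reference(
            sync.warped_gf, sync.warped_region, sync.reference_subject
        )
        # never discard below 2 subjects (mean/SD need at least 2)
        n_eff = min(n_discard, max(len(scaled_gf) - 2, 0))
        retained = ca.discard_outliers(scaled_gf, n_discard=n_eff)
        retained_map[task] = retained
        mean_curve, sd_curve = ca.mean_task_curve(scaled_gf, retained)

        for s in sync.warped_gf:
            si = subjects.index(s)
            gf = sync.warped_gf[s].values
            if np.any(gf > 0):
                cgf_cube[si, k] = ca.mean_cgf(gf, sync.warped_region[s], epsilon_n=epsilon_n)

        for s in cohort:
            fs = force[(s, task)]
            region_peaks[(s, task)] = fs.region_force_n.max(axis=0)
            pmax = np.empty(18)
            for r in layout.regions:
                pmax[r.id - 1] = clean_press[(s, task)][:, layout.sensel_index(r.id)].max()
            pressure_peaks[(s, task)] = pmax

        sync_doc = {
            "task_id": task,
            "reference_subject": sync.reference_subject,
            "warps": {s: dict(zip(("t1", "t2", "t1ref", "t2ref"), w.as_tuple()))
                      for s, w in sync.warps.items()},
            "costs": sync.costs,
            "pre_distance": sync.pre_distance,
            "post_distance": sync.post_distance,
            "excluded": sync.excluded,
            "scale_factors": factors,
            "retained_subjects": retained,
        }
        (out_dir / f"sync_task{task:02d}.json").write_text(json.dumps(sync_doc, indent=1))

        for tau, m, sd in zip(TAU_GRID, mean_curve.values, sd_curve.values):
            mean_rows.append({"task_id": task, "tau": tau, "mean_gf_n": m, "sd_gf_n": sd})
        results["tasks"][task] = {"sync": sync, "retained": retained, "mean_curve": mean_curve}

    cgf = ca.CGFMatrix(subjects=subjects, tasks=tasks, mean_cgf=cgf_cube,
                       retained_subjects=retained_map)

    # --- signatures --------------------------------------------------------
    task_mean = cgf.task_region_mean
    for k, task in enumerate(tasks):
        if np.any(np.isnan(task_mean[k])):
            continue
        graph = build_signature(task_mean[k], layout, threshold=threshold)
        render_signature(graph, layout, out_dir / f"signature_task{task:02d}.svg")
        (out_dir / f"signature_task{task:02d}.json").write_text(
            json.dumps(
                {
                    "task_id": task,
                    "threshold": threshold,
                    "cgf": [float(v) for v in graph.cgf],
                    "edges": [list(e) for e in graph.edges],
                },
                indent=1,
            )
        )
        results["tasks"][task]["signature"] = graph

    # --- tables ------------------------------------------------------------
    pd.DataFrame(mean_rows).to_csv(out_dir / "mean_curves.csv", index=False)

    cgf_rows = []
    for si, s in enumerate(subjects):
        for k, task in enumerate(tasks):
            row = cgf_cube[si, k]
            if np.any(np.isnan(row)):
                continue
            cgf_rows.append(
                {"subject_id": s, "task_id": task,
                 **{f"region_{r:02d}": row[r - 1] for r in range(1, 19)}}
            )
    pd.DataFrame(cgf_rows).to_csv(out_dir / "cgf_matrix.csv", index=False)

    if len(tasks) >= 2:
        tc = ca.task_correlations(cgf)
        pd.DataFrame(tc, index=tasks, columns=tasks).to_csv(out_dir / "task_corr.csv")
        rc = ca.region_correlations(cgf)
        rids = list(range(1, 19))
        pd.DataFrame(rc, index=rids, columns=rids).to_csv(out_dir / "region_corr.csv")

    peaks = ca.peak_table(region_peaks, pressure_peaks, retained_map, tasks)
    pd.DataFrame(
        {
            "region_id": peaks.region_ids,
            "peak_force_n": peaks.peak_force_n,
            "peak_force_task": peaks.peak_force_task,
            "peak_pressure_kpa": peaks.peak_pressure_kpa,
            "peak_pressure_task": peaks.peak_pressure_task,
        }
    ).to_csv(out_dir / "peak_table.csv", index=False)

    durations = {
        t: [recs[(s, t)].timestamps_s[-1] for s in subjects if (s, t) in recs]
        for t in tasks
    }
    dur_stats = ca.task_duration_stats(durations)
    pd.DataFrame(
        [{"task_id": t, **{k: v for k, v in d.items() if k != "outliers"}}
         for t, d in dur_stats.items()]
    ).to_csv(out_dir / "durations.csv", index=False)

    # --- ANOVA on unscaled GF and per-region CGF ---------------------------
    anova_rows = []
    gf_table = np.full((K, S), np.nan)
    for si, s in enumerate(subjects):
        for k, task in enumerate(tasks):
            key = (s, task)
            if key in force:
                fs = force[key]
                window = fs.gf_n > fs.gf_n.mean()
                gf_table[k, si] = fs.gf_n[window].mean() if np.any(window) else fs.gf_n.mean()
    if K >= 2 and S >= 2 and not np.any(np.isnan(gf_table)):
        res = st.two_way_anova(gf_table)
        for eff in ("task", "subject"):
            e = res[eff]
            anova_rows.append({"dv": "gf", "region": "", "effect": eff,
                               "ss": e.ss, "df": e.df, "f": e.f, "p": e.p})
        for r in range(1, 19):
            table = cgf_cube[:, :, r - 1].T  # (K, S)
            if np.any(np.isnan(table)):
                continue
            res = st.two_way_anova(table)
            for eff in ("task", "subject"):
                e = res[eff]
                anova_rows.append({"dv": "cgf", "region": r, "effect": eff,
                                   "ss": e.ss, "df": e.df, "f": e.f, "p": e.p})
    if anova_rows:
        pd.DataFrame(anova_rows).to_csv(out_dir / "anova.csv", index=False)

    summary = {
        "n_subjects": S,
        "n_tasks": K,
        "n_discard": n_discard,
        "epsilon_n": epsilon_n,
        "threshold": threshold,
        "strategy": strategy,
        "resolution": resolution,
        "seed": seed,
        "discarded_sensels": {f"{s}/{t}": d for (s, t), d in discarded_sensels.items() if d},
        "retained_subjects": retained_map,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")

    results["cgf"] = cgf
    results["peaks"] = peaks
    results["durations"] = dur_stats
    return results
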