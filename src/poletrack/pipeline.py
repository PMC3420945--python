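"""End-to-end pipeline: scene -> profiles/histogram -> tracks -> Rxy.

run_pipeline executes the full chain (simulate if a scene is configured,
otherwise read a movie), writes every intermediate table as UTF-8 CSV with
unit-suffixed columns (_px, _au, _s), a machine-readable manifest
(config + version + seed + collected warnings) and a plain-text summary.
Rerunning with the same config and seed reproduces all CSVs and the
manifest bit-identically; per-stage timings go to the log only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .scenes import (
    SceneConfig,
    generate_movie,
    read_stack,
    read_truth,
    scene_config_to_dict,
    write_stack,
    write_truth,
)
from . import quant
from .quant import (
    axial_profile,
    build_histogram,
    classify_pattern,
    detect_clusters,
    estimate_background,
    resolve_cluster_threshold,
    segment_cells,
    splice_segments,
)
from .tracking import (
    ShortTrackError,
    detections_from_masks,
    link_tracks,
    score_reversals,
    traveled_distance,
)
from .dynamics import (
    EventSeries,
    aggregate_rxy,
    binarize_events,
    pole_series,
    rxy_curve,
    score_switching,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_against_truth"]

log = logging.getLogger("poletrack")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and entity."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run. Exactly one of scene / input_path."""

    scene: SceneConfig | None = None
    input_path: str | None = None
    frame_interval_s: float = 30.0
    seg_method: str = "halfmax"
    seg_level: float | None = None
    min_area: int = 50
    cluster_rule: str | float = "robust:5"
    sym_cutoff: float = 1.5
    max_step: float = 15.0
    max_gap: int = 1
    min_move: float = 1.0
    window_min: float = 10.0
    r_pole_px: float | None = None
    max_delay_frames: int = 4
    rxy_threshold: float = 0.4
    out_dir: str = "poletrack_run"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.scene is None) == (self.input_path is None):
            raise ValueError(
                "exactly one of scene / input_path must be configured"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scene is not None:
            d["scene"] = scene_config_to_dict(self.scene)
        d.pop("out_dir", None)  # run location is not part of the run's identity
        return d


def _stage(name: str):
    def deco(fn):
        def wrapper(ctx, *a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(ctx, *a, **kw)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
            ctx["manifest"]["stages"].append(name)
            return out
        return wrapper
    return deco


@_stage("acquire")
def _acquire(ctx, config: PipelineConfig):
    if config.scene is not None:
        scene = dataclasses.replace(config.scene, seed=config.seed)
        stack, truths = generate_movie(scene)
        out = ctx["out"]
        write_stack(stack, out / "movie.tif")
        write_truth(truths, out / "truth.csv")
        ctx["manifest"]["clipping_fraction"] = generate_movie.last_clipping_fraction
        if generate_movie.last_clipping_fraction > 0:
            ctx["warn"](
                f"{generate_movie.last_clipping_fraction:.2e} of pixels clipped"
            )
        ctx["frame_interval_s"] = scene.frame_interval_s
        ctx["scene"] = scene
        return stack, truths
    stack = read_stack(config.input_path)
    ctx["frame_interval_s"] = config.frame_interval_s
    return stack, None


@_stage("segment")
def _segment(ctx, config: PipelineConfig, stack):
    masks_by_frame: dict[int, list] = {}
    backgrounds = []
    for f in range(len(stack)):
        masks = segment_cells(
            stack[f],
            method=config.seg_method,
            level=config.seg_level,
            min_area=config.min_area,
            frame=f,
        )
        if not masks:
            ctx["warn"](f"frame {f}: no cells segmented")
        masks_by_frame[f] = masks
        backgrounds.append(estimate_background(stack[f], masks))
    rows = []
    for f, masks in masks_by_frame.items():
        for m in masks:
            rows.append(
                {
                    "frame": f,
                    "det_id": m.cell_id,
                    "x_px": m.centroid_xy[0],
                    "y_px": m.centroid_xy[1],
                    "area_px": m.area,
                    "axis_length_px": float(
                        np.sum(np.linalg.norm(np.diff(m.axis, axis=0), axis=1))
                    ),
                }
            )
    pd.DataFrame(
        rows,
        columns=["frame", "det_id", "x_px", "y_px", "area_px", "axis_length_px"],
    ).to_csv(ctx["out"] / "masks_summary.csv", index=False)
    return masks_by_frame, np.array(backgrounds)


@_stage("profile")
def _profile(ctx, config: PipelineConfig, stack, masks_by_frame, backgrounds):
    """Snapshot quantification on frame 0 (one snapshot per cell)."""
    out = ctx["out"]
    masks = masks_by_frame[0]
    if not masks:
        ctx["warn"]("frame 0 empty; skipping snapshot quantification")
        return [], [], None
    profiles, segments = [], []
    for m in masks:
        try:
            p = axial_profile(stack[0], m, background=backgrounds[0])
        except quant.ProfileError as exc:
            ctx["warn"](f"profile skipped: {exc}")
            continue
        profiles.append(p)
        segments.append(splice_segments(p))
    threshold = resolve_cluster_threshold(segments, config.cluster_rule)
    calls = [detect_clusters(s, threshold) for s in segments]
    patterns = [
        classify_pattern(c, s, config.sym_cutoff)
        for c, s in zip(calls, segments)
    ]
    hist = build_histogram(calls)

    pd.DataFrame(
        [
            {"cell_id": p.cell_id, "position_px": pos, "intensity_au": v}
            for p in profiles
            for pos, v in zip(p.positions, p.intensities)
        ]
    ).to_csv(out / "profiles.csv", index=False)
    seg_tbl = pd.DataFrame(
        [s.values for s in segments],
        columns=[f"segment_{i + 1}_au" for i in range(quant.N_SEGMENTS)],
    )
    seg_tbl.insert(0, "cell_id", [s.cell_id for s in segments])
    seg_tbl.to_csv(out / "segments.csv", index=False)
    pd.DataFrame(
        {
            "segment": np.arange(1, quant.N_SEGMENTS + 1),
            "count": hist.counts,
            "frequency": hist.frequencies,
        }
    ).to_csv(out / "histogram.csv", index=False)
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "pattern": p.category,
                "asymmetry_ratio": p.asymmetry_ratio,
                "cluster_threshold_au": threshold,
            }
            for c, p in zip(calls, patterns)
        ]
    ).to_csv(out / "patterns.csv", index=False)
    return segments, patterns, hist


@_stage("track")
def _track(ctx, config: PipelineConfig, masks_by_frame):
    out = ctx["out"]
    detections = detections_from_masks(masks_by_frame)
    tracks = link_tracks(
        detections,
        max_step=config.max_step,
        max_gap=config.max_gap,
        frame_interval_s=ctx["frame_interval_s"],
    )
    rows = [
        {
            "cell_id": t.cell_id,
            "frame": int(f),
            "x_px": float(x),
            "y_px": float(y),
        }
        for t in tracks
        for f, (x, y) in zip(t.frame_indices, t.centroids)
    ]
    pd.DataFrame(rows, columns=["cell_id", "frame", "x_px", "y_px"]).to_csv(
        out / "tracks.csv", index=False
    )

    dist_rows, reversal_records = [], {}
    for t in tracks:
        try:
            d = traveled_distance(t, window_min=config.window_min)
        except ShortTrackError as exc:
            ctx["warn"](f"distance skipped: {exc}")
            d = {"path_length_px": np.nan, "net_displacement_px": np.nan}
        rec = score_reversals(t, min_move=config.min_move)
        if rec.non_motile:
            ctx["warn"](f"track {t.cell_id}: non-motile")
        reversal_records[t.cell_id] = rec
        dist_rows.append(
            {
                "cell_id": t.cell_id,
                "path_length_px": d["path_length_px"],
                "net_displacement_px": d["net_displacement_px"],
                "n_reversals": rec.n_reversals,
                "non_motile": rec.non_motile,
            }
        )
    pd.DataFrame(
        dist_rows,
        columns=[
            "cell_id", "path_length_px", "net_displacement_px",
            "n_reversals", "non_motile",
        ],
    ).to_csv(out / "motility.csv", index=False)
    pd.DataFrame(
        [
            {"cell_id": cid, "frame": f}
            for cid, rec in sorted(reversal_records.items())
            for f in rec.reversal_frames
        ],
        columns=["cell_id", "frame"],
    ).to_csv(out / "reversals.csv", index=False)
    return tracks, reversal_records


@_stage("dynamics")
def _dynamics(ctx, config: PipelineConfig, stack, masks_by_frame, backgrounds,
              tracks, reversal_records):
    out = ctx["out"]
    scene = ctx.get("scene")
    if config.r_pole_px is not None:
        r_pole = config.r_pole_px
    elif scene is not None:
        r_pole = scene.cell_width_px / 2.0
    else:
        r_pole = 3.5
    n_frames = len(stack)

    pole_rows, switch_rows, curves = [], [], []
    per_cell_used = 0
    for t in tracks:
        cell_masks = {}
        ok = True
        for f, det in zip(t.frame_indices, t.det_ids):
            if det < 0 or det >= len(masks_by_frame[int(f)]):
                ok = False
                break
            cell_masks[int(f)] = masks_by_frame[int(f)][int(det)]
        if not ok:
            ctx["warn"](f"track {t.cell_id}: mask lookup failed; skipped")
            continue
        series = pole_series(
            t, cell_masks, stack,
            r_pole=r_pole,
            background=backgrounds[t.frame_indices],
            min_move=config.min_move,
        )
        for i, f in enumerate(series.frames):
            pole_rows.append(
                {
                    "cell_id": series.cell_id,
                    "frame": int(f),
                    "time_s": float(f) * ctx["frame_interval_s"],
                    "intensity_initial_leading_au": float(
                        series.initial_leading()[i]
                    ),
                    "intensity_initial_lagging_au": float(
                        series.initial_lagging()[i]
                    ),
                }
            )
        rec = reversal_records[t.cell_id]
        switches = score_switching(series, rec)
        for f, lc in zip(switches.switch_frames, switches.low_confidence):
            switch_rows.append(
                {"cell_id": t.cell_id, "frame": int(f), "low_confidence": lc}
            )
            if lc:
                ctx["warn"](f"track {t.cell_id}: tie at switch frame {f}")
        if not rec.reversal_frames or not switches.switch_frames:
            continue
        events = EventSeries(
            x=binarize_events(switches.switch_frames, n_frames),
            y=binarize_events(rec.reversal_frames, n_frames),
            frame_interval_s=ctx["frame_interval_s"],
        )
        curve = rxy_curve(events, max_delay_frames=config.max_delay_frames)
        if curve.defined:
            curves.append((t.cell_id, curve))
            per_cell_used += 1

    pd.DataFrame(
        pole_rows,
        columns=[
            "cell_id", "frame", "time_s",
            "intensity_initial_leading_au", "intensity_initial_lagging_au",
        ],
    ).to_csv(out / "pole_series.csv", index=False)
    pd.DataFrame(
        switch_rows, columns=["cell_id", "frame", "low_confidence"]
    ).to_csv(out / "switches.csv", index=False)
    pd.DataFrame(
        [
            {
                "cell_id": cid,
                "delay_frames": int(m),
                "delay_s": float(m) * ctx["frame_interval_s"],
                "rxy": float(r),
            }
            for cid, c in curves
            for m, r in zip(c.delays, c.rxy)
        ],
        columns=["cell_id", "delay_frames", "delay_s", "rxy"],
    ).to_csv(out / "rxy_per_cell.csv", index=False)

    if not curves:
        ctx["warn"]("no cell produced a defined Rxy curve")
        return None, False
    agg, flag = aggregate_rxy(
        [c for _, c in curves],
        threshold=config.rxy_threshold,
        window_frames=(0, max(1, int(round(60.0 / ctx["frame_interval_s"])))),
    )
    pd.DataFrame(
        {
            "delay_frames": agg.delays,
            "delay_s": agg.delays * ctx["frame_interval_s"],
            "rxy": agg.rxy,
            "n": np.full(len(agg.delays), agg.n_cells),
        }
    ).to_csv(out / "rxy_aggregate.csv", index=False)
    return agg, flag


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    def warn(msg: str) -> None:
        log.warning("%s", msg)
        warnings.append(msg)

    ctx = {
        "out": out,
        "warn": warn,
        "manifest": {
            "tool": "poletrack",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": [],
        },
    }
    stack, _truths = _acquire(ctx, config)
    masks_by_frame, backgrounds = _segment(ctx, config, stack)
    segments, patterns, hist = _profile(
        ctx, config, stack, masks_by_frame, backgrounds
    )
    tracks, reversal_records = _track(ctx, config, masks_by_frame)
    agg, flag = _dynamics(
        ctx, config, stack, masks_by_frame, backgrounds, tracks, reversal_records
    )

    manifest = ctx["manifest"]
    manifest["warnings"] = warnings
    manifest["rxy_significant"] = bool(flag)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    lines = [
        f"poletrack {__version__} run (seed {config.seed})",
        f"cells in frame 0: {len(masks_by_frame.get(0, []))}",
        f"tracks: {len(tracks)}",
    ]
    if hist is not None:
        lines.append(
            "histogram terminal counts: "
            f"first={int(hist.counts[0])} last={int(hist.counts[-1])} "
            f"of n={hist.n_cells}"
        )
    if agg is not None:
        sel = (agg.delays >= 0) & (agg.delays <= 2)
        lines.append(
            f"aggregate Rxy (n={agg.n_cells} cells), max over 0-1 min delays: "
            f"{np.nanmax(agg.rxy[sel]):.3f} "
            f"({'significant' if flag else 'not significant'} at "
            f">{config.rxy_threshold})"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# validation against generator truth
# ---------------------------------------------------------------------------


def _match_tracks_to_truth(tracks_df: pd.DataFrame, truths) -> dict[int, int]:
    """Map scored track id -> truth cell id via first-frame centroid."""
    mapping: dict[int, int] = {}
    for cid, grp in tracks_df.groupby("cell_id"):
        first = grp.sort_values("frame").iloc[0]
        best, best_d = None, np.inf
        for tr in truths:
            f = int(first["frame"])
            if f >= tr.n_frames():
                continue
            d = np.hypot(
                tr.centroids[f, 0] - first["x_px"],
                tr.centroids[f, 1] - first["y_px"],
            )
            if d < best_d:
                best, best_d = tr.cell_id, d
        if best is not None and best_d <= 10.0:
            mapping[int(cid)] = int(best)
    return mapping


def validate_against_truth(run_dir: str | Path, truth_path: str | Path) -> dict:
    """Compare a synthetic run with its ground truth.

    Reports reversal precision/recall at +/-1 frame tolerance, the
    switching-lag error distribution (scored minus truth switch frame),
    the localization-pattern confusion table, and the terminal-bin error
    of the occurrence histogram. Writes metrics.json into the run dir.
    """
    run_dir = Path(run_dir)
    truth_path = Path(truth_path)
    if not truth_path.exists():
        raise FileNotFoundError(f"truth table not found: {truth_path}")
    truths = read_truth(truth_path)
    truth_by_id = {t.cell_id: t for t in truths}
    tracks_df = pd.read_csv(run_dir / "tracks.csv")
    reversals_df = pd.read_csv(run_dir / "reversals.csv")
    switches_df = pd.read_csv(run_dir / "switches.csv")
    mapping = _match_tracks_to_truth(tracks_df, truths)

    tp = fp = fn = 0
    lag_errors: list[int] = []
    for tid, cid in mapping.items():
        tr = truth_by_id[cid]
        scored = sorted(reversals_df.loc[reversals_df.cell_id == tid, "frame"])
        true = list(tr.reversal_frames)
        # scored reversal = first frame moving the new way = truth frame + 1
        unmatched = list(true)
        for s in scored:
            hit = next((u for u in unmatched if abs(s - (u + 1)) <= 1), None)
            if hit is None:
                fp += 1
            else:
                tp += 1
                unmatched.remove(hit)
        fn += len(unmatched)
        sw_scored = sorted(switches_df.loc[switches_df.cell_id == tid, "frame"])
        sw_true = list(tr.switch_frames)
        for s in sw_scored:
            if sw_true:
                nearest = min(sw_true, key=lambda u: abs(s - u))
                lag_errors.append(int(s - nearest))

    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")

    confusion: dict[str, dict[str, int]] = {}
    pattern_acc = float("nan")
    patterns_path = run_dir / "patterns.csv"
    masks_path = run_dir / "masks_summary.csv"
    if patterns_path.exists() and masks_path.exists():
        patterns_df = pd.read_csv(patterns_path)
        masks_df = pd.read_csv(masks_path)
        frame0 = masks_df[masks_df.frame == 0]
        n_ok = n_tot = 0
        for _, row in patterns_df.iterrows():
            det = frame0[frame0.det_id == row["cell_id"]]
            if det.empty:
                continue
            x, y = float(det.iloc[0]["x_px"]), float(det.iloc[0]["y_px"])
            best, best_d = None, np.inf
            for tr in truths:
                d = np.hypot(tr.centroids[0, 0] - x, tr.centroids[0, 1] - y)
                if d < best_d:
                    best, best_d = tr, d
            if best is None or best_d > 10.0:
                continue
            confusion.setdefault(best.pattern, {})
            confusion[best.pattern][row["pattern"]] = (
                confusion[best.pattern].get(row["pattern"], 0) + 1
            )
            n_tot += 1
            n_ok += int(best.pattern == row["pattern"])
        if n_tot:
            pattern_acc = n_ok / n_tot

    hist_metrics: dict[str, float] = {}
    hist_path = run_dir / "histogram.csv"
    if hist_path.exists():
        hist_df = pd.read_csv(hist_path)
        counts = hist_df["count"].to_numpy()
        expected = sum(
            int(t.amp_pole_neg[0] > 0) + int(t.amp_pole_pos[0] > 0)
            for t in truths
        )
        hist_metrics = {
            "terminal_count_measured": int(counts[0] + counts[-1]),
            "terminal_count_expected": int(expected),
            "terminal_count_error": int(abs(counts[0] + counts[-1] - expected)),
        }

    metrics = {
        "n_tracks_matched": len(mapping),
        "reversal_precision": precision,
        "reversal_recall": recall,
        "reversal_tp": tp,
        "reversal_fp": fp,
        "reversal_fn": fn,
        "switch_lag_errors_frames": lag_errors,
        "pattern_accuracy": pattern_acc,
        "pattern_confusion": confusion,
        "histogram": hist_metrics,
    }
    with open(run_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    return metrics
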