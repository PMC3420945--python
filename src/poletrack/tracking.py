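"""Centroid tracking, traveled-distance statistics and reversal scoring.

Tracks are built by deterministic greedy nearest-neighbor linking of
per-frame detections. Two motility statistics are computed over a 10-min
reference window: the cumulated path length and the net start-to-end
displacement (the paper's Methods describe both readings; net displacement
is the default reported one, path length is always available). A reversal
is scored at the first frame whose supra-threshold displacement along the
cell axis opposes the previously established direction of movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Detection",
    "Track",
    "ReversalRecord",
    "ShortTrackError",
    "link_tracks",
    "detections_from_masks",
    "traveled_distance",
    "score_reversals",
]


class ShortTrackError(ValueError):
    """Track does not span the requested reference window."""


@dataclass(frozen=True)
class Detection:
    frame: int
    x: float
    y: float
    axis_x: float = 1.0
    axis_y: float = 0.0
    det_id: int = -1  # index into the frame's mask list, if any


@dataclass
class Track:
    """One cell's centroid trajectory on the fixed frame grid.

    axes holds one unit vector per frame, sign-aligned for continuity
    (each flipped, if needed, to have nonnegative dot product with its
    predecessor) so displacement projections carry a consistent sign.
    """

    cell_id: int
    frame_indices: np.ndarray
    centroids: np.ndarray  # (n, 2) as (x, y) px
    axes: np.ndarray  # (n, 2) unit vectors, (x, y)
    frame_interval_s: float = 30.0
    det_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if len(self.frame_indices) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_indices)


@dataclass
class ReversalRecord:
    cell_id: int
    reversal_frames: list[int]
    non_motile: bool = False

    @property
    def n_reversals(self) -> int:
        return len(self.reversal_frames)


def detections_from_masks(masks_by_frame: dict[int, list]) -> pd.DataFrame:
    """Flatten cell_quant masks into a detections table for linking."""
    rows = []
    for frame, masks in sorted(masks_by_frame.items()):
        for i, m in enumerate(masks):
            ax = m.axis_unit_vector()
            x, y = m.centroid_xy
            rows.append(
                {"frame": frame, "x": x, "y": y,
                 "axis_x": ax[0], "axis_y": ax[1], "det_id": i}
            )
    return pd.DataFrame(
        rows, columns=["frame", "x", "y", "axis_x", "axis_y", "det_id"]
    )


def link_tracks(
    detections: pd.DataFrame,
    max_step: float = 15.0,
    max_gap: int = 1,
    frame_interval_s: float = 30.0,
) -> list[Track]:
    """Greedy nearest-neighbor frame-to-frame linking.

    Candidate links are sorted by (distance, track id, detection position)
    and assigned greedily, so the result is deterministic. A link over g
    missing frames is allowed up to distance max_step * (g + 1); tracks
    unmatched for more than max_gap frames are closed. Unlinked detections
    start new tracks. Tracks with fewer than 2 points are dropped.
    """
    req = {"frame", "x", "y"}
    if not req.issubset(detections.columns):
        raise ValueError(f"detections need columns {sorted(req)}")
    df = detections.copy()
    if "axis_x" not in df.columns:
        df["axis_x"], df["axis_y"] = 1.0, 0.0
    if "det_id" not in df.columns:
        df["det_id"] = -1
    frames = sorted(df["frame"].unique())
    if len(frames) < 2:
        raise ValueError("need detections in at least 2 frames")

    next_id = 0
    open_tracks: list[dict] = []
    done: list[dict] = []
    for f in frames:
        dets = df[df.frame == f].sort_values(["x", "y"]).to_dict("records")
        used = [False] * len(dets)
        candidates = []
        for tr in open_tracks:
            gap = f - tr["frames"][-1]
            if gap > max_gap + 1:
                continue
            allowed = max_step * gap
            lx, ly = tr["xy"][-1]
            for di, d in enumerate(dets):
                dist = np.hypot(d["x"] - lx, d["y"] - ly)
                if dist <= allowed:
                    candidates.append((dist, tr["id"], d["x"], d["y"], tr, di))
        matched_tracks = set()
        for dist, tid, _, _, tr, di in sorted(
            candidates, key=lambda c: (c[0], c[1], c[2], c[3])
        ):
            if used[di] or tid in matched_tracks:
                continue
            used[di] = True
            matched_tracks.add(tid)
            d = dets[di]
            ax = np.array([d["axis_x"], d["axis_y"]])
            if np.dot(ax, tr["axes"][-1]) < 0:
                ax = -ax
            tr["frames"].append(f)
            tr["xy"].append((d["x"], d["y"]))
            tr["axes"].append(ax)
            tr["dets"].append(int(d["det_id"]))
        # close stale tracks
        still_open = []
        for tr in open_tracks:
            if f - tr["frames"][-1] > max_gap:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        for di, d in enumerate(dets):
            if used[di]:
                continue
            open_tracks.append(
                {
                    "id": next_id,
                    "frames": [f],
                    "xy": [(d["x"], d["y"])],
                    "axes": [np.array([d["axis_x"], d["axis_y"]])],
                    "dets": [int(d["det_id"])],
                }
            )
            next_id += 1
    done.extend(open_tracks)

    tracks = []
    for tr in sorted(done, key=lambda t: t["id"]):
        if len(tr["frames"]) < 2:
            continue
        axes = np.array(tr["axes"])
        norms = np.linalg.norm(axes, axis=1, keepdims=True)
        axes = np.divide(axes, norms, out=np.zeros_like(axes), where=norms > 0)
        tracks.append(
            Track(
                cell_id=tr["id"],
                frame_indices=np.array(tr["frames"]),
                centroids=np.array(tr["xy"]),
                axes=axes,
                frame_interval_s=frame_interval_s,
                det_ids=np.array(tr["dets"], dtype=int),
            )
        )
    return tracks


def traveled_distance(track: Track, window_min: float = 10.0) -> dict[str, float]:
    """Distance statistics over the first full reference window.

    path_length_px sums frame-to-frame centroid distances; the
    net_displacement_px is the straight start-to-end distance. The window
    is anchored at the track start and spans window_min minutes.
    """
    n_intervals = int(round(window_min * 60.0 / track.frame_interval_s))
    f0 = track.frame_indices[0]
    in_win = track.frame_indices <= f0 + n_intervals
    if track.frame_indices[-1] - f0 < n_intervals:
        raise ShortTrackError(
            f"track {track.cell_id} spans "
            f"{track.frame_indices[-1] - f0} intervals < {n_intervals}"
        )
    pts = track.centroids[in_win]
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return {
        "path_length_px": float(steps.sum()),
        "net_displacement_px": float(np.linalg.norm(pts[-1] - pts[0])),
    }


def score_reversals(track: Track, min_move: float = 1.0) -> ReversalRecord:
    """Score reversals from axial displacement sign changes.

    Each inter-frame displacement is projected on the (continuity-aligned)
    cell axis; intervals with |projection| below min_move px per frame step
    are treated as noise and do not establish or change direction. The
    direction is established at the first supra-threshold interval; a
    reversal is scored at the first frame whose displacement opposes the
    established direction. A track with no supra-threshold interval is
    flagged non-motile.
    """
    disp = np.diff(track.centroids, axis=0)
    gaps = np.diff(track.frame_indices)
    proj = np.einsum("ij,ij->i", disp, track.axes[:-1])
    supra = np.abs(proj) >= min_move * gaps
    direction = 0
    reversals: list[int] = []
    for i in np.flatnonzero(supra):
        s = 1 if proj[i] > 0 else -1
        if direction == 0:
            direction = s
        elif s != direction:
            reversals.append(int(track.frame_indices[i + 1]))
            direction = s
    return ReversalRecord(
        cell_id=track.cell_id,
        reversal_frames=reversals,
        non_motile=(direction == 0),
    )
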