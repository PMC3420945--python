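"""Pole-intensity time series, switching scoring and the Rxy correlation.

The two physical cell ends are followed over time by geometric continuity;
their leading/lagging ROLES swap at every reversal while the labels (initial
leading / initial lagging) stay fixed. Pole-to-pole switching of a polar
cluster is scored, per reversal, at the frame where fluorescence at the new
leading pole reaches its maximum within the inter-reversal interval. Scored
reversals and switchings are binarized on the frame grid and compared with
the normalized cross-correlation coefficient Rxy as a function of delay;
Rxy = 1 marks perfect correlation, and an aggregate curve over a cell
population is called significant when it exceeds 0.4 within the 0-1 min
delay window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quant import CellMask
from .tracking import ReversalRecord, Track

__all__ = [
    "PoleSeries",
    "SwitchRecord",
    "EventSeries",
    "RxyCurve",
    "pole_series",
    "score_switching",
    "binarize_events",
    "cross_correlation",
    "rxy_curve",
    "aggregate_rxy",
]


@dataclass
class PoleSeries:
    """Background-subtracted intensity at the two physical poles over time.

    Pole A is the pole whose tip is lexicographically smaller at the first
    frame; a_is_initial_leading records which physical pole was leading
    (pointing along the first supra-threshold movement) at track start.
    """

    cell_id: int
    frames: np.ndarray
    intensity_a: np.ndarray
    intensity_b: np.ndarray
    a_is_initial_leading: bool

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.intensity_a = np.asarray(self.intensity_a, dtype=float)
        self.intensity_b = np.asarray(self.intensity_b, dtype=float)
        if not (len(self.frames) == len(self.intensity_a) == len(self.intensity_b)):
            raise ValueError("pole series arrays must have equal length")

    def initial_leading(self) -> np.ndarray:
        return self.intensity_a if self.a_is_initial_leading else self.intensity_b

    def initial_lagging(self) -> np.ndarray:
        return self.intensity_b if self.a_is_initial_leading else self.intensity_a


@dataclass
class SwitchRecord:
    cell_id: int
    switch_frames: list[int]
    low_confidence: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.switch_frames, self.switch_frames[1:])
        ):
            raise ValueError("switch frames must be strictly increasing")


@dataclass
class EventSeries:
    """Binary event indicators on the frame grid: x = fluorescence polar
    inversions (switching), y = cellular reversals."""

    x: np.ndarray
    y: np.ndarray
    frame_interval_s: float = 30.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y):
            raise ValueError("x and y must have equal length")
        for v in (self.x, self.y):
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError("event series must be binary")


@dataclass
class RxyCurve:
    """Rxy per signed delay (in frames). defined=False flags the undefined
    result obtained from a constant series (not coerced to 0)."""

    delays: np.ndarray
    rxy: np.ndarray
    n_cells: int = 1
    defined: bool = True

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=int)
        self.rxy = np.asarray(self.rxy, dtype=float)
        if len(self.delays) != len(self.rxy):
            raise ValueError("delays and rxy must match in length")

    def at(self, m: int) -> float:
        idx = np.flatnonzero(self.delays == m)
        if len(idx) == 0:
            raise KeyError(f"delay {m} not on the grid")
        return float(self.rxy[idx[0]])


# ---------------------------------------------------------------------------
# pole intensity series
# ---------------------------------------------------------------------------


def _pole_measure_points(mask: CellMask, r_pole: float) -> np.ndarray:
    """Centres of the two pole disks: axis points r_pole inside each tip."""
    axis = mask.axis
    arc = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(axis, axis=0), axis=1))]
    )
    L = arc[-1]
    s0 = min(r_pole, L / 2.0)
    s1 = max(L - r_pole, L / 2.0)
    p0 = np.array(
        [np.interp(s0, arc, axis[:, 0]), np.interp(s0, arc, axis[:, 1])]
    )
    p1 = np.array(
        [np.interp(s1, arc, axis[:, 0]), np.interp(s1, arc, axis[:, 1])]
    )
    return np.array([p0, p1])  # (row, col)


def _disk_mean(
    image: np.ndarray, mask: CellMask, center_rc: np.ndarray, r_pole: float,
    background: float,
) -> float:
    """Mean intensity in a disk re-centred on the brightest pixel near the
    pole (within r_pole of the nominal centre), which removes the sub-pixel
    asymmetry of tip placement between the two poles."""
    rows, cols = mask.pixels
    d2 = (rows - center_rc[0]) ** 2 + (cols - center_rc[1]) ** 2
    near = d2 <= r_pole**2
    if not near.any():
        near = d2 == d2.min()
    vals_near = image[rows[near], cols[near]]
    peak = int(np.argmax(vals_near))
    cr, cc = rows[near][peak], cols[near][peak]
    d2 = (rows - cr) ** 2 + (cols - cc) ** 2
    sel = d2 <= r_pole**2
    vals = image[rows[sel], cols[sel]].astype(float) - background
    return float(max(vals.mean(), 0.0))


def pole_series(
    track: Track,
    masks: dict[int, CellMask],
    frames: np.ndarray,
    r_pole: float = 3.5,
    background: float | np.ndarray = 0.0,
    min_move: float = 1.0,
) -> PoleSeries:
    """Measure mean intensity in a disk of radius r_pole at each pole tip.

    masks maps frame index -> the cell's CellMask in that frame; frames is
    the (T, H, W) image stack. Pole correspondence across frames is kept by
    continuity (nearest tip to the previous frame's tip); if the tip pairing
    is ambiguous the previous assignment wins. background may be scalar or
    per-frame array.
    """
    bg = np.asarray(background, dtype=float)
    per_frame_bg = bg.ndim == 1

    ints_a, ints_b = [], []
    prev_a: np.ndarray | None = None
    tips_at_first = None
    for i, f in enumerate(track.frame_indices):
        mask = masks[int(f)]
        pts = _pole_measure_points(mask, r_pole)
        tips = mask.pole_tips
        if prev_a is None:
            order = (0, 1)  # tips already lexicographically ordered
            tips_at_first = tips
        else:
            d_same = np.linalg.norm(tips[0] - prev_a)
            d_swap = np.linalg.norm(tips[1] - prev_a)
            order = (0, 1) if d_same <= d_swap else (1, 0)
        prev_a = tips[order[0]]
        b = float(bg[i]) if per_frame_bg else float(bg)
        img = frames[int(f)]
        ints_a.append(_disk_mean(img, mask, pts[order[0]], r_pole, b))
        ints_b.append(_disk_mean(img, mask, pts[order[1]], r_pole, b))

    # initial leading pole: tip pointing along the first supra-threshold move
    disp = np.diff(track.centroids, axis=0)
    gaps = np.diff(track.frame_indices)
    steps = np.linalg.norm(disp, axis=1)
    supra = np.flatnonzero(steps >= min_move * gaps)
    a_leads = True
    if len(supra) > 0 and tips_at_first is not None:
        v = disp[supra[0]]
        tip_a_xy = tips_at_first[0][::-1]  # (row,col) -> (x,y)
        tip_b_xy = tips_at_first[1][::-1]
        c0 = track.centroids[0]
        a_leads = float(np.dot(tip_a_xy - c0, v)) >= float(
            np.dot(tip_b_xy - c0, v)
        )
    return PoleSeries(
        cell_id=track.cell_id,
        frames=track.frame_indices.copy(),
        intensity_a=np.array(ints_a),
        intensity_b=np.array(ints_b),
        a_is_initial_leading=bool(a_leads),
    )


# ---------------------------------------------------------------------------
# switching
# ---------------------------------------------------------------------------


def score_switching(
    series: PoleSeries, reversals: ReversalRecord
) -> SwitchRecord:
    """Score pole-to-pole switching: per reversal, the frame of maximum
    fluorescence at the new leading pole within the inter-reversal interval
    beginning at that reversal (ties -> first frame, flagged low confidence).

    The new leading pole after the k-th reversal (k = 0, 1, ...) alternates
    starting from the initial lagging pole.
    """
    if not reversals.reversal_frames:
        return SwitchRecord(series.cell_id, [], [])
    rev = list(reversals.reversal_frames)
    bounds = rev + [int(series.frames[-1]) + 1]
    switch_frames: list[int] = []
    low_conf: list[bool] = []
    for k, r in enumerate(rev):
        new_leading = (
            series.initial_leading() if k % 2 == 1 else series.initial_lagging()
        )
        window = (series.frames >= r) & (series.frames < bounds[k + 1])
        if not window.any():
            continue
        vals = new_leading[window]
        frames_w = series.frames[window]
        best = int(np.argmax(vals))  # argmax returns the first maximum
        f = int(frames_w[best])
        if switch_frames and f <= switch_frames[-1]:
            continue
        switch_frames.append(f)
        low_conf.append(bool(np.count_nonzero(vals == vals[best]) > 1))
    return SwitchRecord(series.cell_id, switch_frames, low_conf)


# ---------------------------------------------------------------------------
# event series and cross-correlation
# ---------------------------------------------------------------------------


def binarize_events(event_frames, n_frames: int) -> np.ndarray:
    """Indicator vector on the frame grid; repeated frames collapse to 1."""
    v = np.zeros(int(n_frames))
    for f in event_frames:
        f = int(f)
        if not 0 <= f < n_frames:
            raise ValueError(f"event frame {f} outside [0, {n_frames})")
        v[f] = 1.0
    return v


def cross_correlation(
    x: np.ndarray, y: np.ndarray, m_range: tuple[int, int] | None = None
) -> RxyCurve:
    """Normalized cross-correlation of x(t) against y(t + m) per delay m.

    Rxy(m) = sum_t (x_t - mean(x)) (y_{t+m} - mean(y)) / (n sx sy), where
    the sum runs over the overlap window (no zero padding) and n, sx, sy
    are the full-series length and population standard deviations. This
    normalization guarantees both calibration properties of the statistic:
    Rxy = 1 exactly for x = y at m = 0, and |Rxy(m)| <= 1 for every delay
    (by Cauchy-Schwarz on the overlap window). Values at large |m| are
    attenuated by the shrinking overlap, a factor (n-|m|)/n at most.
    A constant input yields an undefined (NaN, defined=False) curve rather
    than 0. Positive m peaks when y is a delayed copy of x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be non-empty and equal length")
    n = len(x)
    if m_range is None:
        m_range = (-(n // 4), n // 4)
    m_lo, m_hi = int(m_range[0]), int(m_range[1])
    delays = np.arange(m_lo, m_hi + 1)
    xc = x - x.mean()
    yc = y - y.mean()
    # population variances; the x = y self-correlation at m = 0 then
    # reduces to (D/n) / sqrt((D/n)^2) and evaluates to exactly 1.0
    vx = float(np.dot(xc, xc)) / n
    vy = float(np.dot(yc, yc)) / n
    if vx == 0.0 or vy == 0.0:
        return RxyCurve(delays, np.full(len(delays), np.nan), defined=False)
    norm = float(np.sqrt(vx * vy))
    out = np.empty(len(delays))
    for i, m in enumerate(delays):
        if m >= 0:
            a, b = xc[: n - m], yc[m:]
        else:
            a, b = xc[-m:], yc[: n + m]
        out[i] = np.nan if len(a) == 0 else float(np.dot(a, b)) / n / norm
    return RxyCurve(delays, out)


def rxy_curve(series: EventSeries, max_delay_frames: int = 4) -> RxyCurve:
    """Per-cell Rxy between reversals and switchings.

    Sign convention: positive delay means the fluorescence switch follows
    the reversal (the paper's 0-1 min window corresponds to delays 0-2
    frames at 30 s sampling), so the curve is the cross-correlation of the
    reversal series against the delayed switching series.
    """
    return cross_correlation(
        series.y, series.x, (-max_delay_frames, max_delay_frames)
    )


def aggregate_rxy(
    curves: list[RxyCurve],
    threshold: float = 0.4,
    window_frames: tuple[int, int] = (0, 2),
) -> tuple[RxyCurve, bool]:
    """Mean Rxy curve over cells and the >threshold significance readout.

    Curves must share one delay grid; undefined (constant-series) curves
    are excluded from the mean. The flag is true iff the mean curve
    exceeds the threshold at some delay within window_frames (inclusive),
    the 0-1 min window at 30 s frames by default.
    """
    if not curves:
        raise ValueError("need at least one per-cell curve")
    grid = curves[0].delays
    for c in curves[1:]:
        if len(c.delays) != len(grid) or np.any(c.delays != grid):
            raise ValueError("per-cell curves must share one delay grid")
    usable = [c for c in curves if c.defined]
    if not usable:
        return RxyCurve(grid, np.full(len(grid), np.nan), 0, defined=False), False
    mean = np.mean([c.rxy for c in usable], axis=0)
    agg = RxyCurve(grid, mean, n_cells=len(usable))
    sel = (grid >= window_frames[0]) & (grid <= window_frames[1])
    flag = bool(sel.any() and np.nanmax(mean[sel]) > threshold)
    return agg, flag
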