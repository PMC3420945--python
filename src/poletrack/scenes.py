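"""Synthetic time-lapse movies of gliding, reversing rod-shaped cells.

Emulates widefield fluorescence acquisitions of rod cells (~4 um x 0.7 um at
~0.1 um/px, 30 s frames) carrying diffuse cytoplasmic signal plus polar
clusters. Cells glide along their long axis in disjoint lanes, reverse
direction at programmed or Poisson-distributed times, and relocate the bright
polar cluster to the new leading pole with a programmable frame lag relative
to each reversal. Every movie comes with an exact ground-truth table so
downstream segmentation, tracking, reversal scoring and switching scoring can
be validated without any real data.

Rendering model: a spherocylinder (capsule) footprint filled with a uniform
diffuse level, two compact Gaussian spots just inside the pole tips, an
isotropic Gaussian PSF blur, a constant camera offset, then shot (Poisson)
and read (Gaussian) noise, clipped to the 16-bit range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "NoiseModel",
    "FixedSchedule",
    "PoissonReversals",
    "SceneConfig",
    "CellTruth",
    "SceneGeometryError",
    "simulate_truths",
    "render_cell",
    "render_frame",
    "generate_movie",
    "write_stack",
    "read_stack",
    "write_truth",
    "read_truth",
    "load_scene_config",
    "scene_config_to_dict",
]

U16_MAX = 65535


class SceneGeometryError(ValueError):
    """A configured cell trajectory does not fit inside the image."""


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise then additive Gaussian read noise.

    poisson_scale converts intensity counts to photon events
    (events = counts * poisson_scale); 0 disables shot noise.
    """

    poisson_scale: float = 1.0
    gaussian_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass(frozen=True)
class FixedSchedule:
    """Every cell reverses exactly at these frame indices."""

    frames: tuple[int, ...]

    def __init__(self, frames: Sequence[int]):
        object.__setattr__(self, "frames", tuple(int(f) for f in frames))


@dataclass(frozen=True)
class PoissonReversals:
    """Memoryless reversals with the given mean inter-reversal interval."""

    mean_interval_min: float = 8.0

    def __post_init__(self) -> None:
        if self.mean_interval_min <= 0:
            raise ValueError("mean_interval_min must be positive")


@dataclass
class SceneConfig:
    """Generative parameters of a synthetic movie.

    All geometry is strictly positive; image_shape=None auto-sizes the frame
    from the number of lanes. The seed fully determines the movie and truth.
    """

    n_cells: int = 10
    n_frames: int = 40
    frame_interval_s: float = 30.0
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] | None = None  # (H, W); None -> auto height
    image_width_px: int = 1024
    cell_length_um: float = 4.0
    cell_width_um: float = 0.7
    speed_um_per_min: float = 2.0
    reversal_process: FixedSchedule | PoissonReversals = field(
        default_factory=PoissonReversals
    )
    switch_lag_frames: int | tuple[int, ...] = 1
    polar_cluster_amplitudes: tuple[float, float] = (6000.0, 1800.0)  # leading, lagging
    cluster_decay_per_frame: float = 0.05
    pattern_mix: dict[str, float] | None = None
    initial_direction: int | None = None  # +1/-1 along x; None -> random per cell
    diffuse_level: float = 300.0
    camera_offset: float = 100.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    spot_sigma_px: float = 1.5
    spot_inset_px: float = 1.5
    psf_sigma_px: float = 1.5
    lane_pitch_px: int = 24
    margin_px: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in (
            "frame_interval_s",
            "pixel_size_um",
            "cell_length_um",
            "cell_width_um",
            "diffuse_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.speed_um_per_min < 0:
            raise ValueError("speed_um_per_min must be nonnegative")
        if self.cell_width_um >= self.cell_length_um:
            raise ValueError("cells must be longer than wide")
        if any(a < 0 for a in self.polar_cluster_amplitudes):
            raise ValueError("cluster amplitudes must be nonnegative")
        if self.initial_direction not in (None, 1, -1):
            raise ValueError("initial_direction must be +1, -1 or None")
        if self.pattern_mix is not None:
            total = sum(self.pattern_mix.values())
            if not np.isclose(total, 1.0):
                raise ValueError("pattern_mix fractions must sum to 1")
            bad = set(self.pattern_mix) - {
                "diffuse",
                "unipolar",
                "bipolar_symmetric",
                "bipolar_asymmetric",
            }
            if bad:
                raise ValueError(f"unknown pattern(s) in mix: {sorted(bad)}")

    # -- derived pixel-space geometry -------------------------------------
    @property
    def cell_length_px(self) -> float:
        return self.cell_length_um / self.pixel_size_um

    @property
    def cell_width_px(self) -> float:
        return self.cell_width_um / self.pixel_size_um

    @property
    def speed_px_per_frame(self) -> float:
        return (
            self.speed_um_per_min / 60.0 * self.frame_interval_s / self.pixel_size_um
        )

    def lane_margin_px(self) -> int:
        # lanes must keep every centroid >= one cell length off the border
        return max(self.margin_px, int(np.ceil(self.cell_length_px)) + 4)

    def resolved_shape(self) -> tuple[int, int]:
        if self.image_shape is not None:
            return tuple(int(v) for v in self.image_shape)
        height = self.n_cells * self.lane_pitch_px + 2 * self.lane_margin_px()
        return (height, int(self.image_width_px))


@dataclass
class CellTruth:
    """Per-frame ground truth for one synthetic cell.

    polarity_sign is the direction of the leading pole along the x axis
    (+1/-1) and flips exactly at reversal_frames. switch_frames are the
    reversal frames shifted by the cell's switching lag, clipped to the
    movie. Pole amplitudes are the pre-render Gaussian spot peaks at the
    physical pole in -x direction (amp_pole_neg) and +x (amp_pole_pos).
    """

    cell_id: int
    centroids: np.ndarray  # (n_frames, 2) as (x, y) px
    orientations: np.ndarray  # radians, (n_frames,)
    polarity_sign: np.ndarray  # (n_frames,), +1/-1
    reversal_frames: list[int]
    switch_frames: list[int]
    amp_pole_neg: np.ndarray  # (n_frames,)
    amp_pole_pos: np.ndarray  # (n_frames,)
    switch_lag_frames: int = 0
    pattern: str = "unipolar"

    def n_frames(self) -> int:
        return len(self.polarity_sign)


# ---------------------------------------------------------------------------
# trajectory / truth simulation
# ---------------------------------------------------------------------------

_PATTERN_ORDER = ("diffuse", "unipolar", "bipolar_symmetric", "bipolar_asymmetric")


def _draw_reversal_frames(
    process: FixedSchedule | PoissonReversals, config: SceneConfig, rng: np.random.Generator
) -> list[int]:
    if isinstance(process, FixedSchedule):
        frames = sorted(set(process.frames))
        if any(f < 1 or f >= config.n_frames for f in frames):
            raise ValueError("fixed reversal frames must lie in [1, n_frames)")
        return frames
    mean_frames = process.mean_interval_min * 60.0 / config.frame_interval_s
    frames: set[int] = set()
    t = 0.0
    horizon = float(config.n_frames)
    while True:
        t += rng.exponential(mean_frames)
        if t >= horizon:
            break
        f = int(round(t))
        if 1 <= f <= config.n_frames - 1:
            frames.add(f)
    return sorted(frames)


def _pattern_amplitudes(
    pattern: str, base: tuple[float, float]
) -> tuple[float, float]:
    """(leading, lagging) spot amplitudes realizing a localization pattern."""
    lead, lag = base
    if pattern == "diffuse":
        return (0.0, 0.0)
    if pattern == "unipolar":
        return (lead, 0.0)
    if pattern == "bipolar_symmetric":
        return (lead, lead)
    if pattern == "bipolar_asymmetric":
        return (lead, lag if lag > 0 else lead / 3.0)
    raise ValueError(f"unknown pattern {pattern!r}")


def simulate_truths(config: SceneConfig) -> list[CellTruth]:
    """Draw trajectories, reversal/switch schedules and pole amplitudes.

    Cheap (no rendering); generate_movie renders these truths. Raises
    SceneGeometryError naming the first cell whose trajectory leaves the
    required in-image margin (one cell length from every border).
    """
    rng = np.random.default_rng(config.seed)
    height, width = config.resolved_shape()
    length_px = config.cell_length_px
    n = config.n_frames
    truths: list[CellTruth] = []

    for i in range(config.n_cells):
        lane_y = config.lane_margin_px() + config.lane_pitch_px * (i + 0.5)
        x0 = width / 2.0 + rng.uniform(-10.0, 10.0)
        if config.initial_direction is None:
            d0 = int(rng.choice([-1, 1]))
        else:
            d0 = int(config.initial_direction)
        reversal_frames = _draw_reversal_frames(config.reversal_process, config, rng)

        lag_spec = config.switch_lag_frames
        if isinstance(lag_spec, tuple):
            lag = int(rng.choice(lag_spec))
        else:
            lag = int(lag_spec)
        switch_frames = sorted(
            {min(max(r + lag, 0), n - 1) for r in reversal_frames}
        )

        if config.pattern_mix is not None:
            pats = [p for p in _PATTERN_ORDER if p in config.pattern_mix]
            probs = [config.pattern_mix[p] for p in pats]
            pattern = str(rng.choice(pats, p=probs))
        else:
            pattern = "bipolar_asymmetric" if config.polar_cluster_amplitudes[1] > 0 else "unipolar"
        amp_lead, amp_lag = _pattern_amplitudes(
            pattern, config.polar_cluster_amplitudes
        )

        direction = np.empty(n, dtype=int)
        direction[0] = d0
        rev = set(reversal_frames)
        for t in range(1, n):
            direction[t] = -direction[t - 1] if t in rev else direction[t - 1]

        x = np.empty(n)
        x[0] = x0
        step = config.speed_px_per_frame
        for t in range(1, n):
            x[t] = x[t - 1] + direction[t - 1] * step
        centroids = np.column_stack([x, np.full(n, lane_y)])

        # fluorescence polarity: bright cluster sits at the pole in
        # direction fluo_sign; flips at switch frames (lagging reversals)
        fluo_sign = np.empty(n, dtype=int)
        sw = set(switch_frames)
        fluo_sign[0] = -d0 if 0 in sw else d0  # switch clipped onto frame 0
        for t in range(1, n):
            fluo_sign[t] = -fluo_sign[t - 1] if t in sw else fluo_sign[t - 1]

        # bright-pole amplitude peaks at the switch frame then decays
        # linearly (mimics gradual redistribution between switches)
        frames_since = np.empty(n)
        last = 0
        for t in range(n):
            if t in sw:
                last = t
            frames_since[t] = t - last
        # both poles share the post-switch decay envelope so that symmetric
        # cells stay symmetric; the roles (which pole is bright) flip at
        # switch frames
        envelope = np.maximum(
            1.0 - config.cluster_decay_per_frame * frames_since, 0.4
        )
        amp_pos = envelope * np.where(fluo_sign > 0, amp_lead, amp_lag)
        amp_neg = envelope * np.where(fluo_sign > 0, amp_lag, amp_lead)

        lo = x.min() - length_px / 2.0
        hi = x.max() + length_px / 2.0
        if lo < length_px or hi > width - 1 - length_px:
            raise SceneGeometryError(
                f"cell {i}: trajectory x-range [{lo:.1f}, {hi:.1f}] px leaves "
                f"the one-cell-length margin of a width-{width} image; "
                "enlarge image_width_px or reduce speed/n_frames"
            )
        if lane_y < length_px or lane_y > height - 1 - length_px:
            raise SceneGeometryError(
                f"cell {i}: lane row {lane_y:.1f} px too close to the border "
                f"of a height-{height} image"
            )

        truths.append(
            CellTruth(
                cell_id=i,
                centroids=centroids,
                orientations=np.zeros(n),
                polarity_sign=direction.copy(),
                reversal_frames=list(reversal_frames),
                switch_frames=list(switch_frames),
                amp_pole_neg=amp_neg.astype(float),
                amp_pole_pos=amp_pos.astype(float),
                switch_lag_frames=lag,
                pattern=pattern,
            )
        )
    return truths


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _capsule_and_spots(
    shape: tuple[int, int],
    centroid_xy: tuple[float, float],
    orientation: float,
    length_px: float,
    width_px: float,
    diffuse_level: float,
    amp_tip_neg: float,
    amp_tip_pos: float,
    spot_sigma_px: float,
    spot_inset_px: float = 1.5,
) -> np.ndarray:
    """Unblurred field: capsule footprint plus two polar Gaussian spots.

    Spot centres sit spot_inset_px inside each pole tip (the extremal axis
    point), marking a compact cluster at the pole cap. amp_tip_neg belongs
    to the tip in the -axis direction.
    """
    h, w = shape
    cx, cy = centroid_xy
    ux, uy = np.cos(orientation), np.sin(orientation)
    half = (length_px - width_px) / 2.0  # centroid -> cap centre distance
    pad = width_px / 2.0 + 4.0 * spot_sigma_px + 2.0
    r0 = max(int(np.floor(cy - abs(uy) * half - pad)), 0)
    r1 = min(int(np.ceil(cy + abs(uy) * half + pad)) + 1, h)
    c0 = max(int(np.floor(cx - abs(ux) * half - pad)), 0)
    c1 = min(int(np.ceil(cx + abs(ux) * half + pad)) + 1, w)
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    dx = cols - cx
    dy = rows - cy
    # distance from pixel centre to the axial segment between cap centres
    t = np.clip(dx * ux + dy * uy, -half, half)
    ddx = dx - t * ux
    ddy = dy - t * uy
    dist = np.hypot(ddx, ddy)
    patch = np.where(dist <= width_px / 2.0, diffuse_level, 0.0)

    tip = length_px / 2.0 - spot_inset_px
    for amp, sgn in ((amp_tip_neg, -1.0), (amp_tip_pos, 1.0)):
        if amp <= 0:
            continue
        px = cx + sgn * tip * ux
        py = cy + sgn * tip * uy
        d2 = (cols - px) ** 2 + (rows - py) ** 2
        patch = patch + amp * np.exp(-d2 / (2.0 * spot_sigma_px**2))

    out = np.zeros(shape)
    out[r0:r1, c0:c1] = patch
    return out


def render_cell(
    shape: tuple[int, int],
    centroid_xy: tuple[float, float],
    orientation: float,
    length_px: float,
    width_px: float,
    diffuse_level: float,
    amp_tip_neg: float,
    amp_tip_pos: float,
    spot_sigma_px: float = 1.5,
    psf_sigma_px: float = 1.5,
    spot_inset_px: float = 1.5,
) -> np.ndarray:
    """Render one cell as a PSF-blurred float field (no noise, no offset)."""
    from scipy.ndimage import gaussian_filter

    h, w = shape
    half_len = length_px / 2.0
    cx, cy = centroid_xy
    if not (half_len <= cx <= w - 1 - half_len and half_len <= cy <= h - 1 - half_len):
        raise SceneGeometryError(
            f"cell at ({cx:.1f}, {cy:.1f}) px does not fit a {shape} image"
        )
    field = _capsule_and_spots(
        shape, centroid_xy, orientation, length_px, width_px,
        diffuse_level, amp_tip_neg, amp_tip_pos, spot_sigma_px,
        spot_inset_px,
    )
    return gaussian_filter(field, psf_sigma_px)


def render_frame(
    config: SceneConfig, truths: list[CellTruth], frame: int
) -> np.ndarray:
    """Noiseless float frame: all cells composited, then one PSF blur."""
    from scipy.ndimage import gaussian_filter

    shape = config.resolved_shape()
    field = np.zeros(shape)
    for tr in truths:
        field += _capsule_and_spots(
            shape,
            tuple(tr.centroids[frame]),
            float(tr.orientations[frame]),
            config.cell_length_px,
            config.cell_width_px,
            config.diffuse_level,
            float(tr.amp_pole_neg[frame]),
            float(tr.amp_pole_pos[frame]),
            config.spot_sigma_px,
            config.spot_inset_px,
        )
    return gaussian_filter(field, config.psf_sigma_px)


def generate_movie(
    config: SceneConfig,
) -> tuple[np.ndarray, list[CellTruth]]:
    """Render the full movie as a uint16 stack plus per-cell ground truth.

    Deterministic under (config, seed): two calls yield bit-identical
    arrays and truth tables. Noise stream is drawn after all trajectories.
    """
    truths = simulate_truths(config)
    shape = config.resolved_shape()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0xF1])
    )
    stack = np.empty((config.n_frames, *shape), dtype=np.uint16)
    clipped = 0
    total = 0
    for f in range(config.n_frames):
        img = render_frame(config, truths, f) + config.camera_offset
        if config.noise.poisson_scale > 0:
            scale = config.noise.poisson_scale
            img = rng.poisson(img * scale).astype(float) / scale
        if config.noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, config.noise.gaussian_sd, size=img.shape)
        clipped += int(np.count_nonzero((img < 0) | (img > U16_MAX)))
        total += img.size
        stack[f] = np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)
    generate_movie.last_clipping_fraction = clipped / max(total, 1)
    return stack, truths


generate_movie.last_clipping_fraction = 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_stack(frames: np.ndarray, path: str | Path) -> None:
    """Write a (T, H, W) uint16 stack as a multi-frame grayscale TIFF."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.size == 0:
        raise ValueError("expected a non-empty (T, H, W) stack")
    tifffile.imwrite(str(path), frames.astype(np.uint16), photometric="minisblack")


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def _events_path(path: Path) -> Path:
    return path.with_name(path.stem + "_events" + path.suffix)


def write_truth(truths: list[CellTruth], path: str | Path) -> None:
    """Write truth as two CSVs: per-cell-per-frame rows at `path`, and an
    events table (reversals and switches) next to it (`*_events.csv`)."""
    if not truths:
        raise ValueError("refusing to write an empty truth table")
    path = Path(path)
    rows = []
    for tr in truths:
        for f in range(tr.n_frames()):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": f,
                    "x_px": tr.centroids[f, 0],
                    "y_px": tr.centroids[f, 1],
                    "orientation_rad": tr.orientations[f],
                    "polarity_sign": int(tr.polarity_sign[f]),
                    "amp_pole_neg_au": tr.amp_pole_neg[f],
                    "amp_pole_pos_au": tr.amp_pole_pos[f],
                    "switch_lag_frames": tr.switch_lag_frames,
                    "pattern": tr.pattern,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")

    events = []
    for tr in truths:
        for f in tr.reversal_frames:
            events.append({"cell_id": tr.cell_id, "event": "reversal", "frame": f})
        for f in tr.switch_frames:
            events.append({"cell_id": tr.cell_id, "event": "switch", "frame": f})
    pd.DataFrame(events, columns=["cell_id", "event", "frame"]).to_csv(
        _events_path(path), index=False
    )


def read_truth(path: str | Path) -> list[CellTruth]:
    path = Path(path)
    per_frame = pd.read_csv(path, float_precision="round_trip")
    events = pd.read_csv(_events_path(path))
    truths = []
    for cell_id, grp in per_frame.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        ev = events[events.cell_id == cell_id]
        truths.append(
            CellTruth(
                cell_id=int(cell_id),
                centroids=grp[["x_px", "y_px"]].to_numpy(),
                orientations=grp["orientation_rad"].to_numpy(),
                polarity_sign=grp["polarity_sign"].to_numpy(dtype=int),
                reversal_frames=sorted(
                    ev.loc[ev.event == "reversal", "frame"].astype(int)
                ),
                switch_frames=sorted(
                    ev.loc[ev.event == "switch", "frame"].astype(int)
                ),
                amp_pole_neg=grp["amp_pole_neg_au"].to_numpy(),
                amp_pole_pos=grp["amp_pole_pos_au"].to_numpy(),
                switch_lag_frames=int(grp["switch_lag_frames"].iloc[0]),
                pattern=str(grp["pattern"].iloc[0]),
            )
        )
    return truths


# ---------------------------------------------------------------------------
# YAML config round-trip (CLI support)
# ---------------------------------------------------------------------------


def scene_config_to_dict(config: SceneConfig) -> dict:
    d = dataclasses.asdict(config)
    proc = config.reversal_process
    if isinstance(proc, FixedSchedule):
        d["reversal_process"] = {"fixed_schedule": list(proc.frames)}
    else:
        d["reversal_process"] = {"poisson_mean_min": proc.mean_interval_min}
    d["switch_lag_frames"] = (
        list(config.switch_lag_frames)
        if isinstance(config.switch_lag_frames, tuple)
        else config.switch_lag_frames
    )
    d["polar_cluster_amplitudes"] = list(config.polar_cluster_amplitudes)
    if config.image_shape is not None:
        d["image_shape"] = list(config.image_shape)
    return d


def _scene_config_from_dict(d: dict) -> SceneConfig:
    d = dict(d)
    proc = d.get("reversal_process")
    if isinstance(proc, dict):
        if "fixed_schedule" in proc:
            d["reversal_process"] = FixedSchedule(proc["fixed_schedule"])
        elif "poisson_mean_min" in proc:
            d["reversal_process"] = PoissonReversals(float(proc["poisson_mean_min"]))
        else:
            raise ValueError("reversal_process needs fixed_schedule or poisson_mean_min")
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseModel(**d["noise"])
    if isinstance(d.get("switch_lag_frames"), list):
        d["switch_lag_frames"] = tuple(int(v) for v in d["switch_lag_frames"])
    if isinstance(d.get("polar_cluster_amplitudes"), list):
        d["polar_cluster_amplitudes"] = tuple(d["polar_cluster_amplitudes"])
    if isinstance(d.get("image_shape"), list):
        d["image_shape"] = tuple(d["image_shape"])
    return SceneConfig(**d)


def load_scene_config(path: str | Path) -> SceneConfig:
    with open(path) as fh:
        return _scene_config_from_dict(yaml.safe_load(fh))
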