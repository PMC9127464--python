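"""Synthetic DNA-PAINT microtubule datasets by random-walk simulation.

Filaments are simulated as smooth random walks: each trajectory starts at a
uniformly random point on the boundary of a square working field and takes
fixed-length steps (default half a pixel, so consecutive localizations
overlap into a continuous line) whose noise-free heading points at the field
center; the heading of every step is perturbed by a normally distributed
angle.  One trajectory point per frame emulates the point-accumulation
character of DNA-PAINT: overlaying all frames gives the dense ground truth,
overlaying a random ~10% frame subset gives the sparse input, and blurring
the ground truth to a coarse grid emulates the diffraction-limited widefield
channel.

The simulated filaments are single-point-wide paths; the hollow ~26 nm
cylinder geometry of real microtubules is deliberately not modelled, so
simulated filaments are thinner than real ones.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import downscale_local_mean, rescale, resize

from .errors import ConfigurationError, ContractError

__all__ = [
    "SimulationConfig",
    "TrajectorySet",
    "RenderedImage",
    "simulate_trajectories",
    "overlay_frames",
    "make_ground_truth",
    "make_widefield",
    "make_sparse",
    "generate_dataset",
    "save_triplets",
    "load_triplets",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated DNA-PAINT field.

    Defaults reproduce the published simulation protocol: ~10 boundary-seeded
    trajectories walked for 500 frames in half-pixel steps; ground truth
    blurred with sigma = 1.25 px and cropped to a 256 px tile; widefield
    derived by a sigma = 20 px blur downsampled to a 32 px grid; sparse image
    from a random 10% frame subset.
    """

    field_width: int = 512
    n_trajectories: int = 10
    n_frames: int = 500
    step_length: float = 0.5
    heading_noise_sd: float = 0.35  # radians; the paper leaves this open
    rescale_factor: float = 1.0
    gt_blur_sd: float = 1.25
    wf_blur_sd: float = 20.0
    wf_small_size: int = 32
    tile_size: int = 256
    sparse_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("field_width", "n_trajectories", "n_frames", "wf_small_size",
                     "tile_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        for name in ("step_length", "heading_noise_sd", "rescale_factor",
                     "gt_blur_sd", "wf_blur_sd"):
            if getattr(self, name) < 0 or (name in ("step_length", "rescale_factor")
                                           and getattr(self, name) == 0):
                raise ConfigurationError(f"{name} must be positive")
        if not (0.0 < self.sparse_fraction <= 1.0):
            raise ConfigurationError("sparse_fraction must lie in (0, 1]")
        if self.tile_size % self.wf_small_size != 0:
            raise ConfigurationError(
                f"wf_small_size ({self.wf_small_size}) must divide tile_size "
                f"({self.tile_size})"
            )
        if int(round(self.field_width * self.rescale_factor)) < self.tile_size:
            raise ConfigurationError(
                "field_width x rescale_factor must be at least tile_size"
            )

    @property
    def n_sparse_frames(self) -> int:
        """Round-half-up count of frames in the sparse subset (minimum 1)."""
        x = self.sparse_fraction * self.n_frames
        if x < 1.0:
            raise ConfigurationError(
                f"sparse_fraction x n_frames = {x:.3g} selects no frame"
            )
        return int(math.floor(x + 0.5))


@dataclass
class RenderedImage:
    """A 2-D nonnegative intensity grid with rendering provenance."""

    data: np.ndarray
    pixel_size_nm: float | None = None
    kind: str = ""  # ground-truth | widefield | sparse | reconstruction | overlay

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ContractError("RenderedImage expects a 2-D array")


@dataclass
class TrajectorySet:
    """Simulated filament paths.

    Each trajectory is an (n_frames, 3) float array with columns
    (frame_index, x, y); coordinates are in working-grid pixels and may exit
    the field (the renderer clips).
    """

    trajectories: list[np.ndarray]
    field_width: int

    @property
    def n_frames(self) -> int:
        return len(self.trajectories[0]) if self.trajectories else 0

    def points(self, frame_subset=None) -> np.ndarray:
        """All (frame, x, y) rows, optionally restricted to a frame subset."""
        all_pts = np.concatenate(self.trajectories, axis=0)
        if frame_subset is None:
            return all_pts
        mask = np.isin(all_pts[:, 0].astype(np.int64), np.fromiter(frame_subset, dtype=np.int64))
        return all_pts[mask]


def _boundary_point(width: float, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point on the perimeter of [0, width]^2."""
    t = rng.uniform(0.0, 4.0 * width)
    side, u = int(t // width), t % width
    if side == 0:
        return u, 0.0
    if side == 1:
        return float(width), u
    if side == 2:
        return width - u, float(width)
    return 0.0, width - u


def simulate_trajectories(config: SimulationConfig,
                          rng: np.random.Generator | None = None) -> TrajectorySet:
    """Walk ``n_trajectories`` filaments across the field.

    Every step has length exactly ``step_length``; its expected (noise-free)
    heading points from the current position toward the field center, and the
    realized heading is rotated by a N(0, heading_noise_sd) angle.
    """
    if config.step_length <= 0 or config.n_frames <= 0:
        raise ConfigurationError("step_length and n_frames must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    w = float(config.field_width)
    cx = cy = w / 2.0
    trajectories = []
    for _ in range(config.n_trajectories):
        x, y = _boundary_point(w, rng)
        pts = np.empty((config.n_frames, 3))
        pts[0] = (0, x, y)
        for f in range(1, config.n_frames):
            base = math.atan2(cy - y, cx - x)
            theta = base + rng.normal(0.0, config.heading_noise_sd)
            x += config.step_length * math.cos(theta)
            y += config.step_length * math.sin(theta)
            pts[f] = (f, x, y)
        trajectories.append(pts)
    return TrajectorySet(trajectories, config.field_width)


def overlay_frames(traj: TrajectorySet, frame_subset) -> RenderedImage:
    """Accumulate trajectory points of the selected frames into a count image.

    Each in-field point adds one count to the pixel cell containing it, under
    floor binning: cell (i, j) covers [i, i+1) x [j, j+1) in (x, y).  The
    image is indexed [y, x]; total counts equal the number of in-field
    selected points.
    """
    w = traj.field_width
    frame_subset = set(int(f) for f in frame_subset)
    if frame_subset and (min(frame_subset) < 0 or max(frame_subset) >= traj.n_frames):
        raise ContractError("frame_subset outside [0, n_frames)")
    img = np.zeros((w, w), dtype=np.float64)
    if frame_subset:
        pts = traj.points(frame_subset)
        xs, ys = pts[:, 1], pts[:, 2]
        infield = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < w)
        ix = np.floor(xs[infield]).astype(np.intp)
        iy = np.floor(ys[infield]).astype(np.intp)
        np.add.at(img, (iy, ix), 1.0)
    return RenderedImage(img, kind="overlay")


def _center_crop(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    r0, c0 = (h - size) // 2, (w - size) // 2
    return img[r0:r0 + size, c0:c0 + size]


def make_ground_truth(overlay: RenderedImage, config: SimulationConfig) -> RenderedImage:
    """Rescale, blur (sigma = gt_blur_sd), and center-crop the overlay to a tile."""
    img = overlay.data
    if config.rescale_factor != 1.0:
        img = rescale(img, config.rescale_factor, order=1, anti_aliasing=False,
                      preserve_range=True)
    if min(img.shape) < config.tile_size:
        raise ConfigurationError(
            f"overlay of shape {img.shape} smaller than tile_size {config.tile_size} "
            "after rescale"
        )
    img = gaussian_filter(img, config.gt_blur_sd, mode="reflect")
    return RenderedImage(_center_crop(img, config.tile_size), kind="ground-truth")


def make_widefield(gt: RenderedImage, config: SimulationConfig) -> RenderedImage:
    """Diffraction-limited channel: heavy blur, coarse grid, upscale back.

    The ground-truth tile is blurred with sigma = wf_blur_sd, downsampled by
    area averaging to wf_small_size (a camera-like integration), and
    bilinearly rescaled back to tile_size.
    """
    img = gt.data
    if img.shape != (config.tile_size, config.tile_size):
        raise ContractError("make_widefield expects a tile_size x tile_size image")
    img = gaussian_filter(img, config.wf_blur_sd, mode="reflect")
    factor = config.tile_size // config.wf_small_size
    small = downscale_local_mean(img, (factor, factor))
    big = resize(small, (config.tile_size, config.tile_size), order=1,
                 anti_aliasing=False, preserve_range=True)
    return RenderedImage(big, kind="widefield")


def make_sparse(traj: TrajectorySet, config: SimulationConfig,
                rng: np.random.Generator | None = None,
                mode: str = "random") -> RenderedImage:
    """Render the sparse-subset image through the ground-truth chain.

    mode="random" draws round(sparse_fraction * n_frames) distinct frames;
    mode="first" takes that many leading frames (the real-data convention of
    reconstructing from the first n acquisition frames).
    """
    k = config.n_sparse_frames
    if mode == "random":
        rng = np.random.default_rng(config.seed) if rng is None else rng
        frames = rng.choice(config.n_frames, size=k, replace=False)
    elif mode == "first":
        frames = np.arange(k)
    else:
        raise ContractError(f"unknown sparse mode {mode!r}")
    out = make_ground_truth(overlay_frames(traj, frames), config)
    out.kind = "sparse"
    return out


def generate_dataset(config: SimulationConfig, n_sets: int,
                     rng: np.random.Generator | None = None,
                     sparse_mode: str = "random") -> list:
    """Simulate ``n_sets`` aligned (widefield, sparse, dense) training triplets.

    All three channels of a triplet derive from the same trajectories.  The
    dense and sparse channels share the dense tile's maximum as
    normalization divisor (a sparse render is physically dimmer than the
    dense one); the widefield channel is normalized to its own maximum.
    Deterministic for a fixed config seed.
    """
    from .prep import TrainingTriplet  # local import to avoid a cycle

    if n_sets < 1:
        raise ContractError("n_sets must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    triplets = []
    for i in range(n_sets):
        traj = simulate_trajectories(config, rng)
        gt = make_ground_truth(overlay_frames(traj, range(config.n_frames)), config)
        wf = make_widefield(gt, config)
        sparse = make_sparse(traj, config, rng, mode=sparse_mode)
        dense_max = gt.data.max()
        wf_max = wf.data.max()
        dense = gt.data / dense_max if dense_max > 0 else gt.data
        sp = sparse.data / dense_max if dense_max > 0 else sparse.data
        wfn = wf.data / wf_max if wf_max > 0 else wf.data
        triplets.append(TrainingTriplet(
            widefield=wfn.astype(np.float32),
            sparse=np.clip(sp, 0.0, 1.0).astype(np.float32),
            dense=dense.astype(np.float32),
            grid_index=(0, 0),
            source_id=f"sim{i:05d}",
        ))
    return triplets


def save_triplets(triplets, out_dir: str, config: SimulationConfig | None = None) -> None:
    """Write triplets as 16-bit TIFFs (suffixes _wf/_sparse/_gt) + JSON sidecar."""
    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    for t in triplets:
        r, c = t.grid_index
        base = os.path.join(out_dir, f"{t.source_id}_r{r}_c{c}")
        for suffix, arr in (("wf", t.widefield), ("sparse", t.sparse), ("gt", t.dense)):
            as16 = np.clip(np.asarray(arr, dtype=np.float64) * 65535.0, 0, 65535)
            tifffile.imwrite(f"{base}_{suffix}.tif", as16.astype(np.uint16))
    sidecar = {"n_sets": len(triplets)}
    if config is not None:
        sidecar["config"] = dataclasses.asdict(config)
    with open(os.path.join(out_dir, "simulation.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_triplets(in_dir: str) -> list:
    """Read triplets written by :func:`save_triplets` (intensities back in [0,1])."""
    import tifffile

    from .prep import TrainingTriplet

    out = []
    bases = sorted(
        f[:-len("_gt.tif")] for f in os.listdir(in_dir) if f.endswith("_gt.tif")
    )
    for base in bases:
        chans = {}
        for suffix in ("wf", "sparse", "gt"):
            arr = tifffile.imread(os.path.join(in_dir, f"{base}_{suffix}.tif"))
            chans[suffix] = (arr.astype(np.float32) / 65535.0)
        source, _, rc = base.rpartition("_r")
        row, _, col = rc.partition("_c")
        out.append(TrainingTriplet(widefield=chans["wf"], sparse=chans["sparse"],
                                   dense=chans["gt"],
                                   grid_index=(int(row), int(col)),
                                   source_id=source))
    return out
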