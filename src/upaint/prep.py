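"""Training-set preparation: tile, filter, normalize, and split image fields.

Full-field (widefield, sparse, dense) image triplets are cut on a
non-overlapping 256 x 256 grid; tiles whose mean intensity falls below a
multiple of the whole-field mean are discarded (empty background regions
carry no training signal), with the keep/drop mask derived from the dense
channel and applied identically to all three channels; intensities are
normalized to [0, 1] by the maximum of the corresponding uncut field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "TrainingTriplet",
    "tile_image",
    "filter_tiles",
    "tile_keep_mask",
    "normalize_channel",
    "assemble_triplets",
    "split_dataset",
    "write_manifest",
]


@dataclass
class TrainingTriplet:
    """Aligned (widefield, sparse, dense) tiles normalized to [0, 1]."""

    widefield: np.ndarray
    sparse: np.ndarray
    dense: np.ndarray
    grid_index: tuple[int, int]
    source_id: str

    def __post_init__(self):
        shapes = {self.widefield.shape, self.sparse.shape, self.dense.shape}
        if len(shapes) != 1:
            raise ContractError(f"triplet channels differ in shape: {shapes}")


def _as_2d(image) -> np.ndarray:
    arr = np.asarray(getattr(image, "data", image), dtype=np.float64)
    if arr.ndim != 2:
        raise ContractError("expected a 2-D image")
    return arr


def tile_image(image, tile_size: int = 256) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut ``image`` into non-overlapping tile_size x tile_size grid tiles.

    Trailing partial tiles are discarded; tiles are returned row-major with
    their (row, col) grid index.
    """
    arr = _as_2d(image)
    if arr.shape[0] < tile_size or arr.shape[1] < tile_size:
        raise ContractError(
            f"image of shape {arr.shape} smaller than tile_size {tile_size}"
        )
    rows, cols = arr.shape[0] // tile_size, arr.shape[1] // tile_size
    return [
        ((r, c), arr[r * tile_size:(r + 1) * tile_size,
                     c * tile_size:(c + 1) * tile_size])
        for r in range(rows) for c in range(cols)
    ]


def tile_keep_mask(tiles, whole_image_mean: float, alpha: float = 1.0) -> dict:
    """Keep decision per grid index: mean(tile) >= alpha x whole-image mean."""
    return {gi: float(np.mean(t)) >= alpha * whole_image_mean for gi, t in tiles}


def filter_tiles(tiles, whole_image_mean: float, alpha: float = 1.0):
    """Drop tiles whose mean intensity is below alpha x the uncut-image mean."""
    mask = tile_keep_mask(tiles, whole_image_mean, alpha)
    return [(gi, t) for gi, t in tiles if mask[gi]]


def normalize_channel(tiles, uncut_max: float):
    """Divide every tile by the uncut field's maximum intensity."""
    if uncut_max <= 0:
        raise ContractError("uncut_max must be positive (blank field?)")
    return [(gi, t / uncut_max) for gi, t in tiles]


def assemble_triplets(wf_field, sparse_field, dense_field, tile_size: int = 256,
                      alpha: float = 1.0, source_id: str = "field0",
                      render_divisor: str = "dense") -> list[TrainingTriplet]:
    """Tile three pixel-aligned fields into filtered, normalized triplets.

    The keep mask comes from the dense (ground-truth) channel and is applied
    to all three.  ``render_divisor`` chooses the normalization convention
    for the localization renders: "dense" (default) divides both sparse and
    dense tiles by the dense field's maximum, preserving their relative
    intensity; "per_channel" divides each by its own field maximum.  The
    widefield channel is always normalized to its own maximum.
    """
    wf, sp, de = _as_2d(wf_field), _as_2d(sparse_field), _as_2d(dense_field)
    if not (wf.shape == sp.shape == de.shape):
        raise ContractError(
            f"channel shapes differ: wf {wf.shape}, sparse {sp.shape}, dense {de.shape}"
        )
    if render_divisor not in ("dense", "per_channel"):
        raise ContractError(f"unknown render_divisor {render_divisor!r}")

    dense_tiles = tile_image(de, tile_size)
    mask = tile_keep_mask(dense_tiles, float(de.mean()), alpha)

    de_max = float(de.max())
    sp_max = de_max if render_divisor == "dense" else float(sp.max())
    wf_max = float(wf.max())

    kept_dense = normalize_channel([(gi, t) for gi, t in dense_tiles if mask[gi]], de_max)
    kept_sparse = normalize_channel(
        [(gi, t) for gi, t in tile_image(sp, tile_size) if mask[gi]], sp_max)
    kept_wf = normalize_channel(
        [(gi, t) for gi, t in tile_image(wf, tile_size) if mask[gi]], wf_max)

    out = []
    for (gi, d), (gis, s), (giw, w) in zip(kept_dense, kept_sparse, kept_wf):
        assert gi == gis == giw
        out.append(TrainingTriplet(
            widefield=np.clip(w, 0.0, 1.0).astype(np.float32),
            sparse=np.clip(s, 0.0, 1.0).astype(np.float32),
            dense=np.clip(d, 0.0, 1.0).astype(np.float32),
            grid_index=gi,
            source_id=source_id,
        ))
    return out


def split_dataset(triplets, test_fraction: float,
                  rng: np.random.Generator | None = None):
    """Split triplets into (train, test) at the source-field level.

    All tiles from one source field land on the same side, so no spatial
    leakage between train and test.  Deterministic for a seeded ``rng``.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ContractError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    sources = sorted({t.source_id for t in triplets})
    if len(sources) < 2:
        raise ContractError("need at least 2 source fields to split")
    n_test = min(len(sources) - 1, max(1, int(round(test_fraction * len(sources)))))
    shuffled = list(rng.permutation(sources))
    test_ids = set(shuffled[:n_test])
    train = [t for t in triplets if t.source_id not in test_ids]
    test = [t for t in triplets if t.source_id in test_ids]
    return train, test


def write_manifest(triplets, path: str, kept_flags=None, divisors=None) -> None:
    """Emit a CSV manifest (source, grid index, kept flag, divisors)."""
    rows = []
    for t in triplets:
        rows.append({
            "source_id": t.source_id,
            "grid_row": t.grid_index[0],
            "grid_col": t.grid_index[1],
            "kept": True if kept_flags is None else kept_flags.get(t.grid_index, True),
            "wf_divisor": None if divisors is None else divisors.get("widefield"),
            "render_divisor": None if divisors is None else divisors.get("render"),
        })
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
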