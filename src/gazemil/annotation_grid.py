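"""Grid-cell annotations from continuous heatmaps or binary masks.

The classifier predicts one logit per cell of a coarse grid laid over
the letterboxed image (32x32 cells at the 512-px working resolution).
Supervision therefore needs, per label, the set of grid cells that
contain evidence of the finding: the heatmap (or ellipse mask, which
takes the identical path) is thresholded and max-pooled down to grid
resolution. Because ``max`` and ``> t`` commute, threshold-then-pool
and pool-then-threshold give identical cells; threshold-then-pool is
implemented and the equivalence is asserted in the tests.

Geometry: images are letterboxed — scaled so the longest side is 512
and padded with black on the short side — and annotations go through
the same transform, so grid cells and image content stay aligned and
padding cells are always negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

#: Heatmap binarization threshold (chosen from intensity histograms).
DEFAULT_THRESHOLD = 0.15

DEFAULT_TARGET = 512
DEFAULT_GRID = (32, 32)
DEFAULT_DECODER_SIZE = (256, 256)


@dataclass(frozen=True)
class LetterboxTransform:
    """Aspect-preserving resize + short-side padding to a square."""

    scale: float
    pad_x: int
    pad_y: int
    target: int

    def apply_points(self, xy: np.ndarray) -> np.ndarray:
        """Map (x, y) image coordinates into letterboxed coordinates."""
        xy = np.asarray(xy, dtype=np.float64)
        return xy * self.scale + np.array([self.pad_x, self.pad_y])


@dataclass
class GridAnnotation:
    """Binary per-label cell map; ``positive_cells`` is the evidence set."""

    label: str
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=bool)

    @property
    def positive_cells(self) -> set[int]:
        return set(np.flatnonzero(self.cells.ravel()))


def letterbox(
    array: np.ndarray, target: int = DEFAULT_TARGET, order: int = 1
) -> tuple[np.ndarray, LetterboxTransform]:
    """Scale so the longest side equals ``target``; pad the other with 0.

    ``order=1`` (bilinear) suits images and continuous heatmaps;
    ``order=0`` keeps binary masks binary. The returned transform maps
    original pixel coordinates into the letterboxed frame, and applies
    identically to an image and its annotation maps.
    """
    array = np.asarray(array, dtype=np.float64)
    h, w = array.shape
    if h <= 0 or w <= 0:
        raise ValueError(f"non-positive input shape {(h, w)}")
    scale = target / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    scaled = resize(
        array, (nh, nw), order=order, mode="edge",
        anti_aliasing=(order > 0 and scale < 1), preserve_range=True,
    )
    pad_y = (target - nh) // 2
    pad_x = (target - nw) // 2
    out = np.zeros((target, target), dtype=np.float64)
    out[pad_y : pad_y + nh, pad_x : pad_x + nw] = scaled
    return out, LetterboxTransform(scale=scale, pad_x=pad_x, pad_y=pad_y, target=target)


def block_max(array: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Max-pool ``array`` down to ``shape`` with equal blocks."""
    h, w = array.shape
    gh, gw = shape
    if h % gh or w % gw:
        raise ValueError(f"grid {shape} does not divide map shape {(h, w)}")
    return array.reshape(gh, h // gh, gw, w // gw).max(axis=(1, 3))


def to_grid(
    heatmap: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    grid: tuple[int, int] = DEFAULT_GRID,
    label: str = "",
) -> GridAnnotation:
    """Threshold a heatmap and max-pool it to grid-cell resolution.

    A cell is positive iff the maximum heatmap value over its pixel
    block exceeds ``threshold``. Binary ellipse masks (values {0, 1})
    pass through the same path, any threshold in (0, 1) reproducing the
    mask's block maxima.
    """
    heatmap = np.asarray(heatmap, dtype=np.float64)
    return GridAnnotation(label=label, cells=block_max(heatmap > threshold, grid))


def to_decoder_target(
    heatmap: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    size: tuple[int, int] = DEFAULT_DECODER_SIZE,
) -> np.ndarray:
    """Binary decoder target at half working resolution (block max)."""
    heatmap = np.asarray(heatmap, dtype=np.float64)
    return block_max(heatmap > threshold, size)


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a binary mask (row-major, runs start with 0s)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    pos = 0
    current = False
    for change in np.flatnonzero(np.diff(flat)):
        runs.append(int(change + 1 - pos))
        pos = change + 1
        current = not current
    runs.append(int(len(flat) - pos))
    if flat.size and flat[0]:
        runs.insert(0, 0)
    return {"shape": [int(s) for s in mask.shape], "runs": runs}


def rle_decode(encoded: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(encoded["shape"])), dtype=bool)
    pos = 0
    value = False
    for run in encoded["runs"]:
        if value:
            flat[pos : pos + run] = True
        pos += run
        value = not value
    return flat.reshape(encoded["shape"])


def save_grid_annotations(annotations: list[GridAnnotation], path) -> None:
    """Serialize grid annotations as RLE masks in a JSON sidecar."""
    payload = {a.label: rle_encode(a.cells) for a in annotations}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_grid_annotations(path) -> list[GridAnnotation]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        GridAnnotation(label=label, cells=rle_decode(enc))
        for label, enc in payload.items()
    ]
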