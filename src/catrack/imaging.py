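"""Rendering synthetic movies and extracting ROI mean traces.

``render_movie`` turns a synthetic dataset into a frame stack with Gaussian
cell footprints plus an integer ROI label mask; ``extract_traces`` is the
manual-ROI path that averages pixel intensity over each labelled region per
frame.  Together they form a round trip: at zero noise the extracted traces
equal the input traces up to a positive affine factor.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import tifffile

from .session import FluorescenceRecording
from .simulate import SyntheticDataset


def _grid_centers(n: int, shape: Tuple[int, int], margin: int) -> np.ndarray:
    """Deterministic grid layout of n cell centers inside the frame."""
    if n == 0:
        return np.empty((0, 2), dtype=int)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    ys = np.linspace(margin, shape[0] - 1 - margin, rows)
    xs = np.linspace(margin, shape[1] - 1 - margin, cols)
    centers = [(int(round(y)), int(round(x))) for y in ys for x in xs][:n]
    if len(set(centers)) != n:
        raise ValueError(
            f"frame_shape {shape} too small to place {n} distinct cell centers"
        )
    return np.asarray(centers, dtype=int)


def render_movie(
    dataset: SyntheticDataset,
    frame_shape: Tuple[int, int] = (64, 64),
    footprint_sd: float = 1.5,
    background: float = 10.0,
    mask_radius_sd: float = 2.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Render frames ``frame(t) = sum_n footprint_n * F_n(t) + background``.

    Footprints are unit-peak 2-D Gaussians on a deterministic grid; the label
    mask assigns pixels within ``mask_radius_sd * footprint_sd`` of a center
    the neuron's 1-based label (ascending neuron order).

    Returns
    -------
    movie : (T, H, W) float32 array
    mask : (H, W) uint16 label image
    """
    rec = dataset.recording
    n = rec.n_neurons
    margin = int(np.ceil(3 * footprint_sd)) + 1
    if 2 * margin >= min(frame_shape):
        raise ValueError(f"frame_shape {frame_shape} too small for footprint_sd {footprint_sd}")
    centers = _grid_centers(n, frame_shape, margin)

    yy, xx = np.mgrid[0: frame_shape[0], 0: frame_shape[1]]
    footprints = np.empty((n, *frame_shape), dtype=float)
    mask = np.zeros(frame_shape, dtype=np.uint16)
    for i, (cy, cx) in enumerate(centers):
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        footprints[i] = np.exp(-r2 / (2.0 * footprint_sd**2))
        disk = r2 <= (mask_radius_sd * footprint_sd) ** 2
        if np.any(mask[disk] != 0):
            raise ValueError(f"cell footprints overlap at center {(cy, cx)}")
        mask[disk] = i + 1

    if n == 0:
        movie = np.full((rec.F.shape[1], *frame_shape), background)
    else:
        flat = footprints.reshape(n, -1)
        movie = (rec.F.T @ flat).reshape(rec.F.shape[1], *frame_shape) + background
    return movie.astype(np.float32), mask


def write_movie(movie: np.ndarray, mask: np.ndarray, movie_path: str | Path,
                mask_path: str | Path) -> None:
    """Write the frame stack as a multi-page TIFF and the mask as integer TIFF."""
    tifffile.imwrite(movie_path, movie)
    tifffile.imwrite(mask_path, mask)


def extract_traces(
    movie: np.ndarray,
    mask: np.ndarray,
    sampling_rate_hz: float,
    day_starts: Sequence[int],
    neuron_ids: Sequence[str] | None = None,
) -> FluorescenceRecording:
    """Mean pixel intensity over each labelled ROI region, per frame.

    Neuron order follows ascending mask label.  A label present in the mask
    header range but covering zero pixels raises an error naming the label.
    """
    movie = np.asarray(movie)
    mask = np.asarray(mask)
    if movie.ndim != 3 or movie.shape[1:] != mask.shape:
        raise ValueError("mask spatial shape must match movie frames")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        raise ValueError("mask contains no labelled regions")
    traces = np.empty((labels.size, movie.shape[0]), dtype=float)
    flat_movie = movie.reshape(movie.shape[0], -1)
    flat_mask = mask.ravel()
    for i, lab in enumerate(labels):
        sel = flat_mask == lab
        if not np.any(sel):
            raise ValueError(f"ROI label {lab} covers no pixels")
        traces[i] = flat_movie[:, sel].mean(axis=1)
    if neuron_ids is None:
        neuron_ids = [f"roi{int(lab):04d}" for lab in labels]
    return FluorescenceRecording(
        F=traces,
        sampling_rate_hz=sampling_rate_hz,
        day_starts=day_starts,
        neuron_ids=neuron_ids,
    )


def read_movie(movie_path: str | Path, mask_path: str | Path) -> Tuple[np.ndarray, np.ndarray]:
    return tifffile.imread(movie_path), tifffile.imread(mask_path)
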