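"""IC-mask trace extraction and neuropil pixel selection.

One-photon miniscope movies are decomposed upstream (PCA/ICA, performed by
vendor software) into per-cell spatial masks ("ICs").  This module applies
those masks to ΔF/F pixel stacks to produce per-soma fluorescence traces,
and derives the diffuse *neuropil* signal from the pixels that no soma
dominates: each IC is normalized to unit maximum, the per-pixel maximum is
taken across normalized ICs within a region of interest containing all
somas, and pixels strictly below the median of that distribution form the
neuropil set.  The neuropil trace is the discrete integral (sum) of ΔF/F
over that pixel set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceMatrix",
    "IcMaskSet",
    "PixelStack",
    "NeuropilPixelSet",
    "extract_traces",
    "median_rule",
    "select_neuropil_pixels",
    "neuropil_trace",
]


@dataclass
class FluorescenceMatrix:
    """Per-cell ΔF/F (or Z-scored) time series at the imaging frame rate.

    Parameters
    ----------
    traces : ndarray, shape (n_cells, n_frames)
    frame_rate : float
        Imaging rate in Hz (20 fps for the recordings this models).
    cell_ids : sequence of int, optional
    """

    traces: np.ndarray
    frame_rate: float
    cell_ids: list[int] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be 2-D (n_cells, n_frames)")
        if not self.cell_ids:
            self.cell_ids = list(range(self.traces.shape[0]))
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length must match number of traces")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate


@dataclass
class PixelStack:
    """A ΔF/F movie: time × height × width, uniformly sampled."""

    frames: np.ndarray
    frame_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (time, height, width)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("pixel stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate


@dataclass
class IcMaskSet:
    """Per-cell nonnegative pixel weight maps sharing one field of view."""

    masks: np.ndarray  # (n_cells, height, width)
    cell_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=float)
        if self.masks.ndim != 3:
            raise ValueError("masks must be 3-D (n_cells, height, width)")
        if np.any(self.masks < 0):
            raise ValueError("mask weights must be nonnegative")
        if not self.cell_ids:
            self.cell_ids = list(range(self.masks.shape[0]))

    @property
    def n_cells(self) -> int:
        return self.masks.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]


@dataclass
class NeuropilPixelSet:
    """Pixels carrying diffuse (extra-somatic) fluorescence.

    ``roi`` is the axis-aligned bounding rectangle (row0, row1, col0, col1),
    half-open, that contains the support of every IC.  ``pixels`` are
    (row, col) coordinates of the selected pixels, all inside the ROI and
    strictly below ``threshold`` (the median of the per-pixel maxima over
    unit-normalized ICs within the ROI).
    """

    roi: tuple[int, int, int, int]
    pixels: np.ndarray  # (n_selected, 2) int coordinates
    pixel_values: np.ndarray  # per-pixel maxima at the selected pixels
    threshold: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


def extract_traces(stack: PixelStack, masks: IcMaskSet) -> FluorescenceMatrix:
    """Apply IC spatial masks to a ΔF/F stack to get per-soma traces.

    Each trace is the mask-weighted mean over pixels,
    ``trace_c(t) = Σ_p mask_c(p) · stack(t, p) / Σ_p mask_c(p)``,
    so amplitudes are comparable across masks of different area.
    """
    if stack.shape != masks.shape:
        raise ValueError(
            f"stack spatial shape {stack.shape} != mask shape {masks.shape}"
        )
    weights = masks.masks.reshape(masks.n_cells, -1)
    norms = weights.sum(axis=1)
    if np.any(norms <= 0):
        raise ValueError("every mask needs at least one strictly positive pixel")
    flat = stack.frames.reshape(stack.n_frames, -1)
    traces = (weights @ flat.T) / norms[:, None]
    return FluorescenceMatrix(
        traces=traces,
        frame_rate=stack.frame_rate,
        cell_ids=list(masks.cell_ids),
        start_time=stack.start_time,
    )


def median_rule(per_pixel_max: np.ndarray) -> tuple[float, np.ndarray]:
    """Median threshold over a distribution of per-pixel maxima.

    Returns (threshold, boolean selection) where selected values lie
    strictly below the median; ties at the median are excluded, so at most
    half of the pixels are ever selected.
    """
    values = np.asarray(per_pixel_max, dtype=float)
    threshold = float(np.median(values))
    return threshold, values < threshold


def select_neuropil_pixels(masks: IcMaskSet) -> NeuropilPixelSet:
    """Select the neuropil pixel set from the IC masks.

    Within the bounding rectangle of the union of IC supports, each IC is
    divided by its own maximum, the per-pixel maximum is taken across the
    normalized ICs, and pixels strictly below the median of that
    distribution are selected.  Strict inequality guarantees at most half
    of the ROI is selected; if all per-pixel maxima are equal the selection
    is empty and a warning is raised.
    """
    if masks.n_cells < 1:
        raise ValueError("need at least one IC mask")
    maxima = masks.masks.reshape(masks.n_cells, -1).max(axis=1)
    if np.any(maxima <= 0):
        raise ValueError("every mask needs at least one strictly positive pixel")
    normalized = masks.masks / maxima[:, None, None]
    per_pixel_max = normalized.max(axis=0)

    support = per_pixel_max > 0
    rows, cols = np.nonzero(support)
    if len(rows) == 0:
        raise ValueError("all masks are empty")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    roi_values = per_pixel_max[r0:r1, c0:c1]
    threshold, below = median_rule(roi_values)
    if not below.any():
        warnings.warn(
            "all per-pixel maxima are >= the median (degenerate distribution); "
            "neuropil pixel set is empty",
            stacklevel=2,
        )
    rr, cc = np.nonzero(below)
    pixels = np.column_stack([rr + r0, cc + c0]).astype(int)
    return NeuropilPixelSet(
        roi=(int(r0), int(r1), int(c0), int(c1)),
        pixels=pixels,
        pixel_values=roi_values[rr, cc],
        threshold=threshold,
    )


def neuropil_trace(stack: PixelStack, pixels: NeuropilPixelSet) -> np.ndarray:
    """Neuropil trace: sum of ΔF/F over the neuropil pixel set, per frame."""
    if pixels.n_pixels == 0:
        raise ValueError("neuropil pixel set is empty")
    h, w = stack.shape
    if np.any(pixels.pixels[:, 0] >= h) or np.any(pixels.pixels[:, 1] >= w):
        raise ValueError("neuropil pixels fall outside the stack")
    return stack.frames[:, pixels.pixels[:, 0], pixels.pixels[:, 1]].sum(axis=1)
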