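"""Expert-input emulation: artifact-aware slice selection and traced contours.

Two measurement arms are produced from the same corrupted scan:

* the *interpolation arm* traces contours only on a sparse set of
  low-severity slices (at most ``max_gap`` apart, endpoints of the graft
  extent always included) and fills the rest with morphological contour
  interpolation.  Its premise is that the selected input slices are
  effectively artifact-free, so they are traced at severity zero.
* the *manual arm* traces every slice of the graft extent, including the
  artifact-corrupted ones; there, tracing error grows with slice severity
  (negative radial bias by default — under-tracing near artifacts — plus
  correlated jitter).

Repeat-to-repeat variation of the interpolation arm comes from jittering
which slice is chosen inside each severity window (+/- 1 index); the
manual arm varies through its stochastic tracing field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.ndimage as ndi

from .grid import GRAFT, VoxelGrid
from .cbct_sim import SliceSeverity
from .mci_core import SparseSliceSet


@dataclass(frozen=True)
class RaterModel:
    """Stochastic model of a human tracing a contour on a corrupted slice.

    The traced boundary is the true boundary displaced radially by a smooth
    correlated random field with mean ``bias_per_severity * severity`` (mm,
    negative = under-tracing) and standard deviation
    ``jitter_sigma * severity`` (mm); ``smoothing_scale`` is the
    correlation length of the field along the boundary (mm).  A zero model
    — or a severity of zero — reproduces the truth exactly.
    """

    bias_per_severity: float = -0.5
    jitter_sigma: float = 0.4
    smoothing_scale: float = 1.0
    seed: int = 0

    def is_zero(self) -> bool:
        return self.bias_per_severity == 0.0 and self.jitter_sigma == 0.0


def _severity_array(severities, n: int | None = None) -> np.ndarray:
    """Normalize a list of SliceSeverity (or plain floats) to an array."""
    if len(severities) and isinstance(severities[0], SliceSeverity):
        if n is None:
            n = max(s.slice_index for s in severities) + 1
        arr = np.zeros(n)
        for s in severities:
            arr[s.slice_index] = s.severity
        return arr
    return np.asarray(severities, dtype=float)


def graft_extent(truth: VoxelGrid, axis: int = 0) -> tuple[int, int]:
    """First and last slice indices (inclusive) containing graft label."""
    moved = np.moveaxis(truth.data, axis, 0)
    has = np.nonzero((moved == GRAFT).any(axis=(1, 2)))[0]
    if len(has) == 0:
        raise ValueError("grid contains no graft label")
    return int(has[0]), int(has[-1])


def select_input_slices(
    severities, extent: tuple[int, int], max_gap: int = 5
) -> list[int]:
    """Greedy artifact-aware selection of interpolation input slices.

    Starting from the first slice of the graft extent, each step picks the
    minimum-severity slice within the next window of ``max_gap`` slices
    (ties resolved to the farthest candidate, so uniform severities yield a
    regular stride of ``max_gap``).  Both extent endpoints are always
    included and no gap ever exceeds ``max_gap``.  An extent shorter than
    two slices selects everything in it.
    """
    if max_gap < 1:
        raise ValueError("max_gap must be >= 1")
    lo, hi = int(extent[0]), int(extent[1])
    if hi < lo:
        raise ValueError("empty graft extent")
    if hi - lo < 1:
        return list(range(lo, hi + 1))
    sev = _severity_array(severities, n=hi + 1)
    selected = [lo]
    while selected[-1] < hi:
        start = selected[-1] + 1
        stop = min(selected[-1] + max_gap, hi)
        window = np.arange(start, stop + 1)
        vals = sev[window]
        # farthest among the minimal-severity candidates
        best = window[np.nonzero(vals == vals.min())[0][-1]]
        selected.append(int(best))
    if selected[-1] != hi:
        selected.append(hi)
    return selected


def jitter_selection(
    indices: Sequence[int],
    extent: tuple[int, int],
    max_gap: int,
    rng: np.random.Generator,
) -> list[int]:
    """Perturb interior input-slice indices by +/- 1.

    Endpoints stay fixed; a repair pass restores strict monotonicity and
    the ``max_gap`` guarantee (always possible because the unperturbed
    selection satisfies both).
    """
    idx = list(int(i) for i in indices)
    if len(idx) <= 2:
        return idx
    deltas = rng.integers(-1, 2, size=len(idx) - 2)
    new = [idx[0]] + [i + int(d) for i, d in zip(idx[1:-1], deltas)] + [idx[-1]]
    # forward pass: strictly increasing
    for k in range(1, len(new)):
        new[k] = max(new[k], new[k - 1] + 1)
    new[-1] = idx[-1]
    # backward pass: close any gap that exceeds max_gap
    for k in range(len(new) - 2, 0, -1):
        new[k] = max(new[k], new[k + 1] - max_gap)
        new[k] = min(new[k], new[k + 1] - 1)
    for k in range(1, len(new)):
        if new[k] - new[k - 1] > max_gap or new[k] <= new[k - 1]:
            return idx  # give up on pathological configurations
    return new


def trace_slice(
    truth_mask: np.ndarray,
    severity: float,
    rater: RaterModel,
    spacing: float = 0.25,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Emulate manual tracing of one slice.

    The true boundary is displaced by a smooth random field whose mean and
    spread scale with the slice's artifact severity (see
    :class:`RaterModel`).  Severity zero, an empty mask, or a zero rater
    model return the truth unchanged.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if severity == 0.0 or rater.is_zero() or not truth_mask.any():
        return truth_mask.copy()
    if rng is None:
        rng = np.random.default_rng(rater.seed)
    # signed distance to the boundary, mm (positive inside, boundary at
    # half a voxel outside the innermost out-crossing)
    sd = (
        ndi.distance_transform_edt(truth_mask)
        - ndi.distance_transform_edt(~truth_mask)
    ).astype(float)
    sd_mm = (sd - 0.5 * np.sign(sd)) * spacing
    noise = ndi.gaussian_filter(
        rng.standard_normal(truth_mask.shape), sigma=rater.smoothing_scale / spacing
    )
    std = noise.std()
    if std > 0:
        noise = noise / std
    displacement = (
        rater.bias_per_severity * severity + rater.jitter_sigma * severity * noise
    )
    return (sd_mm + displacement) > 0


def manual_segment_volume(
    intensity: VoxelGrid,
    truth: VoxelGrid,
    severities,
    rater: RaterModel,
    axis: int = 0,
) -> VoxelGrid:
    """The manual arm: trace every slice of the graft extent.

    ``intensity`` is what the emulated rater is looking at; the tracing
    model acts on the truth contours with the per-slice severities of that
    scan, which is the only part of the image that matters for the
    emulation.
    """
    lo, hi = graft_extent(truth, axis)
    sev = _severity_array(severities, n=np.moveaxis(truth.data, axis, 0).shape[0])
    rng = np.random.default_rng(rater.seed)
    out = np.zeros(truth.shape, dtype=np.uint8)
    moved_out = np.moveaxis(out, axis, 0)
    moved_truth = np.moveaxis(truth.data, axis, 0)
    for k in range(lo, hi + 1):
        moved_out[k] = trace_slice(
            moved_truth[k] == GRAFT, float(sev[k]), rater, truth.spacing, rng
        )
    return VoxelGrid(out, truth.spacing, truth.origin.copy())


def build_sparse_annotations(
    truth: VoxelGrid,
    severities,
    axis: int = 0,
    max_gap: int = 5,
    indices: Sequence[int] | None = None,
) -> SparseSliceSet:
    """The interpolation arm's input: clean traces on selected slices.

    Input slices are traced at severity zero (the method's premise is that
    slices with no or few artifacts are chosen), so the masks equal the
    truth contours on those slices.  ``indices`` overrides the automatic
    severity-greedy selection, e.g. with a jittered repeat.
    """
    lo, hi = graft_extent(truth, axis)
    sev = _severity_array(severities, n=np.moveaxis(truth.data, axis, 0).shape[0])
    if indices is None:
        indices = select_input_slices(sev, (lo, hi), max_gap)
    moved_truth = np.moveaxis(truth.data, axis, 0)
    slices = {int(k): (moved_truth[k] == GRAFT) for k in indices}
    return SparseSliceSet(
        axis=axis,
        slices=slices,
        severities={int(k): float(sev[k]) for k in indices},
        max_gap=max_gap,
    )


def repeated_measurements(
    pipeline: Callable[[int, int], float],
    n_repeats: int = 5,
    n_raters: int = 2,
    seed: int = 0,
) -> list[float]:
    """Run a measurement pipeline ``n_repeats`` times with ``n_raters``.

    ``pipeline(rater_index, seed)`` must return one volume (mm^3).  Each
    repeat runs the pipeline once per rater with a distinct derived seed
    and records the across-rater mean, mirroring a protocol where two
    observers measure and the mean value is recorded.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=(n_repeats, n_raters))
    volumes = []
    for r in range(n_repeats):
        vals = [pipeline(i, int(seeds[r, i])) for i in range(n_raters)]
        volumes.append(float(np.mean(vals)))
    return volumes
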