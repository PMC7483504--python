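"""CBCT-like intensity simulation with implant-induced metal artifacts.

Reconstructed cone-beam images around a titanium implant show bright/dark
streaks radiating from the metal plus a dark band hugging it.  This module
models that corruption *geometrically* — angular rays with radial decay and
a near-field dark band, per slice of the stack — rather than through a
polyenergetic projection/reconstruction chain: for validating a
segmentation method only the corrupting effect on boundary delineation
matters.  Scanner acquisition settings (kV, mA, FOV) are metadata only.

Each stack slice also receives an artifact-severity score: the fraction of
graft-boundary voxels whose intensity the deterministic artifact field
pushes across the nominal graft threshold.  Severities drive the
artifact-aware selection of interpolation input slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .grid import BACKGROUND, BONE, GRAFT, IMPLANT, VoxelGrid

#: Nominal reconstructed intensities per tissue label (arbitrary units,
#: ordered implant >> graft > bone > background).
INTENSITY = {BACKGROUND: 100.0, BONE: 400.0, GRAFT: 800.0, IMPLANT: 3000.0}

#: Nominal graft segmentation window: lower bound is the bone/graft
#: midpoint, upper bound the graft/implant midpoint.
GRAFT_LOW = 0.5 * (INTENSITY[BONE] + INTENSITY[GRAFT])
GRAFT_HIGH = 0.5 * (INTENSITY[GRAFT] + INTENSITY[IMPLANT])

#: Dark-band amplitude as a fraction of the streak amplitude.
_DARK_FRACTION = 0.6

#: Amplitude of the smooth trabecular texture given to bone voxels, as a
#: multiple of the white-noise sigma (so a zero model is texture-free).
_TEXTURE_GAIN = 2.0


@dataclass(frozen=True)
class ArtifactModel:
    """Parameters of the geometric metal-artifact model.

    streak_count
        number of angular streak lobes around the implant.
    streak_amplitude
        peak streak intensity (same units as :data:`INTENSITY`); the dark
        band scales with it.
    streak_decay
        radial decay rate of the streaks, 1/mm.
    dark_band_width
        extent (mm) of the dark band hugging the implant surface.
    noise_sigma
        white-noise standard deviation added to the whole volume.
    """

    streak_count: int = 9
    streak_amplitude: float = 600.0
    streak_decay: float = 0.15
    dark_band_width: float = 1.0
    noise_sigma: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if min(
            self.streak_count,
            self.streak_amplitude,
            self.streak_decay,
            self.dark_band_width,
            self.noise_sigma,
        ) < 0:
            raise ValueError("all artifact magnitudes must be non-negative")


@dataclass(frozen=True)
class SliceSeverity:
    """Artifact severity of one stack slice, in [0, 1]."""

    slice_index: int
    severity: float

    def __post_init__(self):
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError(f"severity {self.severity} outside [0, 1]")


_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_LUT = np.array([INTENSITY[i] for i in range(4)])


def _artifact_field(labels: VoxelGrid, model: ArtifactModel, axis: int) -> np.ndarray:
    """Deterministic streak + dark-band field, slice by slice along ``axis``."""
    data = np.moveaxis(labels.data, axis, 0)
    field = np.zeros(data.shape, dtype=float)
    if model.streak_amplitude == 0:
        return np.moveaxis(field, 0, axis)
    sp = labels.spacing
    in_plane = [a for a in range(3) if a != axis]
    c0 = labels.origin[in_plane[0]] + sp * np.arange(data.shape[1])
    c1 = labels.origin[in_plane[1]] + sp * np.arange(data.shape[2])
    rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), 17]))
    phases = rng.uniform(0, 2 * np.pi, size=data.shape[0])
    for k in range(data.shape[0]):
        implant = data[k] == IMPLANT
        if not implant.any():
            continue
        iy, iz = np.nonzero(implant)
        cy = c0[iy].mean()
        cz = c1[iz].mean()
        theta = np.arctan2(c1[None, :] - cz, c0[:, None] - cy)
        # distance (mm) to the implant cross-section surface
        d = ndi.distance_transform_edt(~implant) * sp
        streak = (
            model.streak_amplitude
            * np.cos(model.streak_count * theta + phases[k])
            * np.exp(-model.streak_decay * d)
        )
        band = (
            -_DARK_FRACTION
            * model.streak_amplitude
            * np.clip(1.0 - d / max(model.dark_band_width, 1e-9), 0.0, 1.0)
        )
        sl = streak + band
        sl[implant] = 0.0
        field[k] = sl
    return np.moveaxis(field, 0, axis)


def _slice_severity(label_slice: np.ndarray, field_slice: np.ndarray) -> float:
    graft = label_slice == GRAFT
    if not graft.any():
        return 0.0
    implant = label_slice == IMPLANT
    inner = graft & ~ndi.binary_erosion(graft, _CROSS)
    outer = ndi.binary_dilation(graft, _CROSS) & ~graft & ~implant
    boundary = inner | outer
    n = int(boundary.sum())
    if n == 0:
        return 0.0
    clean = _LUT[label_slice.astype(np.intp)]
    corrupted = clean + field_slice
    crossed = ((clean >= GRAFT_LOW) != (corrupted >= GRAFT_LOW)) & boundary
    return float(crossed.sum()) / n


def simulate_cbct(
    labels: VoxelGrid, model: ArtifactModel, axis: int = 0
) -> tuple[VoxelGrid, list[SliceSeverity]]:
    """Turn a label grid into a CBCT-like intensity volume.

    Base intensities are assigned per label; bone receives a smooth
    trabecular texture; streak/dark-band artifacts radiate from the implant
    cross-section in every slice (along ``axis``) that contains implant;
    Gaussian white noise is added last.  Per-slice severities are computed
    from the deterministic artifact field alone, so they are reproducible
    for a given seed.  A model with all magnitudes zero yields the pure
    label-to-intensity mapping and all-zero severities.
    """
    labels.validate_labels()
    base = _LUT[labels.data.astype(np.intp)]

    field = _artifact_field(labels, model, axis)

    moved_labels = np.moveaxis(labels.data, axis, 0)
    moved_field = np.moveaxis(field, axis, 0)
    severities = [
        SliceSeverity(k, _slice_severity(moved_labels[k], moved_field[k]))
        for k in range(moved_labels.shape[0])
    ]

    intensity = base + field
    if model.noise_sigma > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), 29]))
        texture = ndi.gaussian_filter(rng.standard_normal(labels.data.shape), sigma=3.0)
        tstd = texture.std()
        if tstd > 0:
            texture /= tstd
        intensity = intensity + np.where(
            labels.data == BONE, _TEXTURE_GAIN * model.noise_sigma * texture, 0.0
        )
        intensity = intensity + rng.normal(0.0, model.noise_sigma, labels.data.shape)

    return VoxelGrid(intensity, labels.spacing, labels.origin.copy()), severities


def threshold_segment(
    intensity: VoxelGrid, threshold: float, upper: float = GRAFT_HIGH
) -> VoxelGrid:
    """Binary graft mask by window thresholding.

    Voxels with ``threshold <= value < upper`` are graft; the default upper
    bound excludes the (much brighter) implant, so on an artifact-free
    simulation the mask equals the graft label exactly.
    """
    mask = (intensity.data >= threshold) & (intensity.data < upper)
    return VoxelGrid(mask.astype(np.uint8), intensity.spacing, intensity.origin.copy())
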