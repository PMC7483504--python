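"""Voxel-grid container and volume I/O (NRRD / NIfTI / DICOM series).

Coordinate convention, used everywhere in the package: grids are indexed
``data[x, y, z]`` with 0-based indices, isotropic spacing in millimetres,
and the *center* of voxel ``(i, j, k)`` at ``origin + index * spacing``.
Axis 0 (``x``) is the default stack axis for slice-wise operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

# Label values for segmentation grids.
BACKGROUND, BONE, IMPLANT, GRAFT = 0, 1, 2, 3
LABEL_SET = frozenset((BACKGROUND, BONE, IMPLANT, GRAFT))

AXES = ("x", "y", "z")


@dataclass
class VoxelGrid:
    """A 3-D scalar volume with isotropic spacing.

    Carries both intensity data (float) and label/binary data (integer);
    which one it is follows from context and can be checked with
    :meth:`validate_labels` / :meth:`is_binary`.
    """

    data: np.ndarray
    spacing: float = 0.25
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: tuple = AXES

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate grid shape {self.data.shape}")
        if not (self.spacing > 0):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (mm)")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(self.spacing) ** 3

    def coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along ``axis``."""
        return self.origin[axis] + self.spacing * np.arange(self.data.shape[axis])

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.spacing, self.origin.copy(), self.axes)

    def is_binary(self) -> bool:
        return bool(np.isin(self.data, (0, 1)).all())

    def validate_labels(self) -> None:
        bad = set(np.unique(self.data)) - set(LABEL_SET)
        if bad:
            raise ValueError(f"grid contains undeclared label values {sorted(bad)}")


# ---------------------------------------------------------------------------
# NRRD / NIfTI I/O via SimpleITK.  SimpleITK stores arrays (z, y, x); this
# package stores (x, y, z), hence the transposes.


def save_volume(grid: VoxelGrid, path) -> None:
    """Write a grid as NRRD or NIfTI, chosen by file extension."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.data.transpose(2, 1, 0)))
    img.SetSpacing((float(grid.spacing),) * 3)
    img.SetOrigin(tuple(float(v) for v in grid.origin))
    sitk.WriteImage(img, str(path))


def load_volume(path) -> VoxelGrid:
    """Read an NRRD / NIfTI volume written by :func:`save_volume`."""
    img = sitk.ReadImage(str(path))
    spacings = img.GetSpacing()
    if max(spacings) - min(spacings) > 1e-6:
        raise ValueError(f"anisotropic spacing {spacings} is not supported")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return VoxelGrid(data, float(spacings[0]), np.asarray(img.GetOrigin()))


# ---------------------------------------------------------------------------
# Minimal single-frame-per-slice DICOM series, for I/O round-trip testing.


def write_dicom_series(grid: VoxelGrid, directory) -> list:
    """Emit a synthetic axial DICOM series (one file per z-slice).

    Pixel data are cast to int16.  PixelSpacing / SliceThickness /
    ImagePositionPatient carry the grid geometry so a series reader can
    reassemble the volume.  Returns the written file paths.
    """
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    paths = []
    nz = grid.shape[2]
    for k in range(nz):
        sl = np.ascontiguousarray(grid.data[:, :, k].T.astype(np.int16))  # rows=y
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = pydicom.Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            float(grid.origin[0]),
            float(grid.origin[1]),
            float(grid.origin[2] + k * grid.spacing),
        ]
        ds.PixelSpacing = [float(grid.spacing), float(grid.spacing)]
        ds.SliceThickness = float(grid.spacing)
        ds.Rows, ds.Columns = sl.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        ds.PixelData = sl.tobytes()
        path = directory / f"slice_{k:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def read_dicom_series(directory) -> VoxelGrid:
    """Reassemble a volume from a DICOM series written by
    :func:`write_dicom_series`."""
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files under {directory}")
    slices = [pydicom.dcmread(f) for f in files]
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    data = np.stack([ds.pixel_array.T for ds in slices], axis=2)  # -> (x, y, z)
    first = slices[0]
    spacing = float(first.PixelSpacing[0])
    origin = np.array(
        [
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            float(first.ImagePositionPatient[2]),
        ]
    )
    return VoxelGrid(data, spacing, origin)
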