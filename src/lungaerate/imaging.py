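"""Image volumes, masks and reference-ROI statistics.

All quantitative lung-aeration measurements in this package reduce to a
handful of primitives on 3D magnitude MR images: segmented-mask volume in
mL, mean signal intensity in grey units (GU) under a mask or inside an
analytic region of interest, normalization of signal to a reference tissue
(water or muscle), and merging of breath-hold acquisition blocks into a
whole-thorax volume expressed in muscle-normalized units.

Geometry convention
-------------------
Volumes are axis-aligned grids.  World coordinates (mm) of a voxel center
are ``origin + index * spacing``.  Each grid axis carries a two-letter
anatomical label whose first character names the side at index 0 and whose
second names the side at the last index, e.g. ``"PA"`` means the axis runs
from posterior to anterior.  NIfTI files are reoriented to closest-canonical
(RAS-like) on load; DICOM series keep the scanner's LPS frame.  Masks never
carry independent geometry: they inherit spacing/origin/labels from a paired
volume so that a geometry mismatch cannot arise silently.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: grid-axis labels for canonical (RAS-like) NIfTI volumes
RAS_LABELS = ("LR", "PA", "IS")
#: grid-axis labels for DICOM volumes kept in the scanner LPS frame
LPS_LABELS = ("RL", "AP", "IS")

_SLICE_SPACING_RTOL = 0.01  # max relative deviation of inter-slice gaps


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and anatomical axis labels.

    Parameters
    ----------
    data
        3D array of non-negative intensities.  Units are raw grey units
        (``units="gu"``) or dimensionless muscle-normalized ratios
        (``units="muscle-normalized"``).
    spacing
        Per-axis voxel size in mm; all components must be positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    axis_labels
        Two-letter anatomical label per grid axis (see module docstring).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = RAS_LABELS
    units: str = "gu"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("Volume.data must be a 3D grid with >=1 voxel per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        if np.any(self.data < 0):
            n = int(np.sum(self.data < 0))
            logger.warning("clamping %d negative intensities to 0 (magnitude image)", n)
            self.data = np.clip(self.data, 0.0, None)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_for(self, anatomical_pair: str) -> int:
        """Grid axis index carrying the given anatomical pair, e.g. ``"AP"``."""
        want = frozenset(anatomical_pair.upper())
        for i, lab in enumerate(self.axis_labels):
            if frozenset(lab.upper()) == want:
                return i
        raise ValueError(
            f"no axis labelled with {anatomical_pair!r} in {self.axis_labels}"
        )

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one grid axis."""
        n = self.data.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class Mask:
    """A binary segmentation paired to a :class:`Volume`'s geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: tuple[str, str, str] = RAS_LABELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("Mask.data must be 3D")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @classmethod
    def from_volume(cls, volume: Volume, data: np.ndarray) -> "Mask":
        data = np.asarray(data)
        if data.shape != volume.data.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match volume {volume.data.shape}"
            )
        return cls(data=data, spacing=volume.spacing, origin=volume.origin,
                   axis_labels=volume.axis_labels)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def check_paired(self, volume: Volume) -> None:
        if self.data.shape != volume.data.shape:
            raise ValueError(
                f"mask grid {self.data.shape} != volume grid {volume.data.shape}"
            )
        if not np.allclose(self.spacing, volume.spacing):
            raise ValueError(
                f"mask spacing {self.spacing} != volume spacing {volume.spacing}"
            )


@dataclass
class RoiSpec:
    """Analytic region of interest placed in world coordinates.

    ``shape`` is one of ``"sphere"`` / ``"cube"`` (sized by volume in cm^3)
    or ``"disc"`` (sized by area in cm^2, confined to one slice along the
    inferior-superior axis, ``slice_index`` required).
    """

    shape: str
    center_mm: tuple[float, float, float]
    size_cm3: float | None = None
    size_cm2: float | None = None
    slice_index: int | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cube", "disc"):
            raise ValueError(f"unknown ROI shape {self.shape!r}")
        if self.shape in ("sphere", "cube"):
            if self.size_cm3 is None or self.size_cm3 <= 0:
                raise ValueError(f"{self.shape} ROI requires size_cm3 > 0")
        else:
            if self.size_cm2 is None or self.size_cm2 <= 0:
                raise ValueError("disc ROI requires size_cm2 > 0")
            if self.slice_index is None:
                raise ValueError("disc ROI requires a slice_index")
        self.center_mm = tuple(float(c) for c in self.center_mm)
        if self.size_cm3 is not None:
            self.size_cm3 = float(self.size_cm3)
        if self.size_cm2 is not None:
            self.size_cm2 = float(self.size_cm2)
        if self.slice_index is not None:
            self.slice_index = int(self.slice_index)

    @property
    def radius_mm(self) -> float:
        """Sphere/disc radius in mm derived from the configured size."""
        if self.shape == "sphere":
            v_mm3 = self.size_cm3 * 1000.0
            return (3.0 * v_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
        if self.shape == "disc":
            a_mm2 = self.size_cm2 * 100.0
            return math.sqrt(a_mm2 / math.pi)
        raise ValueError("cube ROI has no radius; use side_mm")

    @property
    def side_mm(self) -> float:
        """Cube side length in mm derived from the configured volume."""
        if self.shape != "cube":
            raise ValueError("side_mm defined for cube ROIs only")
        return (self.size_cm3 * 1000.0) ** (1.0 / 3.0)

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        """Build from a config mapping (keys: shape, center_mm, size_cm3 |
        size_cm2, slice_index)."""
        return cls(
            shape=d["shape"],
            center_mm=tuple(d["center_mm"]),
            size_cm3=d.get("size_cm3"),
            size_cm2=d.get("size_cm2"),
            slice_index=d.get("slice_index"),
        )

    def to_dict(self) -> dict:
        d: dict = {"shape": self.shape, "center_mm": list(self.center_mm)}
        if self.size_cm3 is not None:
            d["size_cm3"] = self.size_cm3
        if self.size_cm2 is not None:
            d["size_cm2"] = self.size_cm2
        if self.slice_index is not None:
            d["slice_index"] = self.slice_index
        return d


@dataclass
class ReferenceSet:
    """Mean signals (GU) of the reference materials present in a scan.

    At least one of water or muscle must be available for normalization;
    the air signal feeds the SNR and may legitimately approach zero.
    """

    water_signal: float | None = None
    muscle_signal: float | None = None
    air_signal: float | None = None

    def __post_init__(self) -> None:
        if self.water_signal is None and self.muscle_signal is None:
            raise ValueError("need water and/or muscle reference for normalization")
        for name in ("water_signal", "muscle_signal"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.air_signal is not None and self.air_signal < 0:
            raise ValueError(f"air_signal must be >= 0, got {self.air_signal}")

    def reference(self, normalization: str) -> float:
        """Return the reference GU for ``normalization`` in {water, muscle}."""
        value = {"water": self.water_signal, "muscle": self.muscle_signal}.get(
            normalization
        )
        if value is None:
            raise ValueError(f"no {normalization!r} reference available")
        return value


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Load a 3D volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"``, ``"dicom-series"`` or ``None`` to infer
    from the path (directory -> DICOM series, file -> NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "dicom-series" if path.is_dir() else "nifti"
    if format == "nifti":
        return _load_nifti(path)
    if format == "dicom-series":
        return _load_dicom_series(path)
    raise ValueError(f"unknown format {format!r}")


def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or invalid voxel spacing {zooms}")
    data = np.asanyarray(img.dataobj, dtype=float)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return Volume(data=data, spacing=tuple(float(z) for z in zooms),
                  origin=origin, axis_labels=RAS_LABELS)


def _load_dicom_series(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append((p, ds))
    if not datasets:
        raise ValueError(f"{path}: no DICOM image files found")

    first = datasets[0][1]
    if not hasattr(first, "PixelSpacing"):
        raise ValueError(f"{path}: DICOM series lacks PixelSpacing metadata")
    iop = [float(x) for x in first.ImageOrientationPatient]
    row_dir = np.array(iop[:3])
    col_dir = np.array(iop[3:])
    normal = np.cross(row_dir, col_dir)

    for p, ds in datasets:
        if [float(x) for x in ds.ImageOrientationPatient] != iop:
            raise ValueError(f"{path}: inconsistent orientation in slice {p.name}")
        if [float(x) for x in ds.PixelSpacing] != [float(x) for x in first.PixelSpacing]:
            raise ValueError(f"{path}: inconsistent pixel spacing in slice {p.name}")

    # order slices by spatial position along the slice normal, not file name
    positions = [
        (float(np.dot(normal, np.array([float(x) for x in ds.ImagePositionPatient]))),
         p, ds)
        for p, ds in datasets
    ]
    positions.sort(key=lambda t: t[0])
    zs = np.array([t[0] for t in positions])

    if len(zs) > 1:
        gaps = np.diff(zs)
        median_gap = float(np.median(gaps))
        if median_gap <= 0:
            raise ValueError(f"{path}: duplicate or unordered slice positions")
        bad = np.where(np.abs(gaps - median_gap) > _SLICE_SPACING_RTOL * median_gap)[0]
        if bad.size:
            names = ", ".join(
                f"{positions[i + 1][1].name} (gap {gaps[i]:.3f} vs {median_gap:.3f} mm)"
                for i in bad
            )
            raise ValueError(f"{path}: inconsistent inter-slice spacing at {names}")
        slice_spacing = median_gap
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    # pixel_array is (rows, cols); store as (cols, rows, slices) so that the
    # DICOM row direction becomes grid axis 1 and column direction axis 0
    stack = np.stack([t[2].pixel_array.T for t in positions], axis=-1).astype(float)
    ps = [float(x) for x in first.PixelSpacing]  # [row spacing, col spacing]
    spacing = (ps[1], ps[0], slice_spacing)
    ipp0 = [float(x) for x in positions[0][2].ImagePositionPatient]
    return Volume(data=stack, spacing=spacing, origin=tuple(ipp0),
                  axis_labels=LPS_LABELS)


def save_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a volume (or mask geometry carrier) as NIfTI."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    nib.save(img, str(path))


def save_mask(mask: Mask, path: str | os.PathLike) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path: str | os.PathLike, like: Volume | None = None) -> Mask:
    """Load a binary mask from NIfTI; verify pairing against ``like``."""
    vol = load_volume(path, format="nifti")
    mask = Mask(data=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin,
                axis_labels=vol.axis_labels)
    if like is not None:
        mask.check_paired(like)
        mask.origin = like.origin
        mask.axis_labels = like.axis_labels
    return mask


def write_dicom_series(volume: Volume, directory: str | os.PathLike,
                       series_description: str = "lungaerate phantom") -> None:
    """Write a volume as an axial DICOM series (one file per slice).

    Intended for phantom export and round-trip testing; emits minimal MR
    Image Storage datasets with correct spacing/position/orientation tags.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    frame_uid = generate_uid()
    data = np.clip(np.rint(volume.data), 0, 65535).astype(np.uint16)
    nx, ny, nz = data.shape
    for k in range(nz):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = pydicom.uid.MRImageStorage
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "MR"
        ds.SeriesDescription = series_description
        ds.InstanceNumber = k + 1
        ds.Rows = ny
        ds.Columns = nx
        ds.PixelSpacing = [str(volume.spacing[1]), str(volume.spacing[0])]
        ds.SliceThickness = str(volume.spacing[2])
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0], volume.origin[1],
            volume.origin[2] + k * volume.spacing[2],
        ]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = data[:, :, k].T.tobytes()  # (rows, cols) order
        pydicom.dcmwrite(str(directory / f"slice_{k:04d}.dcm"), ds,
                         enforce_file_format=True)


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def mask_volume_ml(mask: Mask) -> float:
    """Segmented volume in mL: voxel count times voxel volume (mm^3 -> mL)."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3 / 1000.0


def mean_signal(volume: Volume, mask: Mask) -> float:
    """Mean intensity (GU) of the voxels under a non-empty mask."""
    mask.check_paired(volume)
    if not mask.data.any():
        raise ValueError("mean signal is undefined for an empty mask")
    return float(volume.data[mask.data].mean())


def roi_mask(volume: Volume, roi: RoiSpec) -> Mask:
    """Rasterize an analytic ROI onto the volume grid by voxel-center inclusion."""
    centers = [volume.voxel_centers_mm(ax) for ax in range(3)]
    lo = [c[0] - 0.5 * s for c, s in zip(centers, volume.spacing)]
    hi = [c[-1] + 0.5 * s for c, s in zip(centers, volume.spacing)]

    if roi.shape == "sphere":
        half = [roi.radius_mm] * 3
    elif roi.shape == "cube":
        half = [roi.side_mm / 2.0] * 3
    else:  # disc: in-plane extent only; slice position checked separately
        half = [roi.radius_mm, roi.radius_mm, 0.0]

    is_axis = volume.axis_for("IS") if roi.shape == "disc" else None
    for ax in range(3):
        if roi.shape == "disc" and ax == is_axis:
            continue
        if roi.center_mm[ax] - half[ax] < lo[ax] or roi.center_mm[ax] + half[ax] > hi[ax]:
            raise ValueError(
                f"ROI extends outside the volume along axis {ax} "
                f"({roi.center_mm[ax] - half[ax]:.1f}..{roi.center_mm[ax] + half[ax]:.1f} mm "
                f"vs grid {lo[ax]:.1f}..{hi[ax]:.1f} mm)"
            )

    if roi.shape == "sphere":
        dx = [centers[ax] - roi.center_mm[ax] for ax in range(3)]
        d2 = (dx[0][:, None, None] ** 2 + dx[1][None, :, None] ** 2
              + dx[2][None, None, :] ** 2)
        inside = d2 <= roi.radius_mm ** 2
    elif roi.shape == "cube":
        ok = [np.abs(centers[ax] - roi.center_mm[ax]) <= roi.side_mm / 2.0
              for ax in range(3)]
        inside = ok[0][:, None, None] & ok[1][None, :, None] & ok[2][None, None, :]
    else:
        if not (0 <= roi.slice_index < volume.data.shape[is_axis]):
            raise ValueError(
                f"disc slice_index {roi.slice_index} outside grid "
                f"(axis {is_axis}, {volume.data.shape[is_axis]} slices)"
            )
        plane_axes = [ax for ax in range(3) if ax != is_axis]
        da = centers[plane_axes[0]] - roi.center_mm[plane_axes[0]]
        db = centers[plane_axes[1]] - roi.center_mm[plane_axes[1]]
        inplane = (da[:, None] ** 2 + db[None, :] ** 2) <= roi.radius_mm ** 2
        inside = np.zeros(volume.data.shape, dtype=bool)
        sel: list = [slice(None)] * 3
        sel[is_axis] = roi.slice_index
        inside[tuple(sel)] = inplane

    if not inside.any():
        raise ValueError("ROI contains no voxel centers at this grid resolution")
    return Mask.from_volume(volume, inside)


def sample_roi(volume: Volume, roi: RoiSpec) -> float:
    """Mean intensity (GU) inside an analytic ROI (voxel-center inclusion)."""
    return mean_signal(volume, roi_mask(volume, roi))


def normalize_signal(signal: float | np.ndarray, reference: float):
    """Divide a signal (scalar or array) by a positive scalar reference."""
    if reference <= 0:
        raise ValueError(f"normalization reference must be > 0, got {reference}")
    return signal / reference


def normalize_volume(volume: Volume, reference: float) -> Volume:
    """Voxel-wise normalization; returns a muscle-normalized-unit Volume."""
    return replace(volume, data=normalize_signal(volume.data, reference),
                   units="muscle-normalized")


def snr(lung_signal: float, air_signal: float) -> float:
    """Signal-to-noise ratio: mean lung signal over mean background-air signal."""
    if air_signal <= 0:
        raise ValueError(f"air signal must be > 0 for SNR, got {air_signal}")
    return lung_signal / air_signal


def merge_blocks(blocks: Sequence[Volume], block_muscle_refs: Sequence[float]) -> Volume:
    """Merge consecutive breath-hold blocks into one muscle-normalized volume.

    Each block is divided by its own muscle reference before concatenation
    along the inferior-superior axis, so gains that differ between apnea
    periods cancel and the merged intensities are directly comparable.
    """
    if len(blocks) < 1:
        raise ValueError("need at least one block")
    if len(blocks) != len(block_muscle_refs):
        raise ValueError("one muscle reference required per block")
    first = blocks[0]
    axis = first.axis_for("IS")
    order = sorted(range(len(blocks)), key=lambda i: blocks[i].origin[axis])
    blocks = [blocks[i] for i in order]
    refs = [block_muscle_refs[i] for i in order]

    inplane = [ax for ax in range(3) if ax != axis]
    for b in blocks[1:]:
        if any(b.data.shape[ax] != first.data.shape[ax] for ax in inplane):
            raise ValueError(
                f"in-plane grid mismatch: {b.data.shape} vs {first.data.shape}"
            )
        if not np.allclose(b.spacing, first.spacing):
            raise ValueError(f"spacing mismatch: {b.spacing} vs {first.spacing}")

    dz = first.spacing[axis]
    for prev, nxt in zip(blocks, blocks[1:]):
        expected = prev.origin[axis] + prev.data.shape[axis] * dz
        gap = nxt.origin[axis] - expected
        if gap < -0.5 * dz:
            raise ValueError(
                f"blocks overlap along the merge axis: next block starts at "
                f"{nxt.origin[axis]:.1f} mm, previous ends at {expected:.1f} mm"
            )
        if gap > 0.5 * dz:
            raise ValueError(
                f"blocks are not contiguous: {gap:.1f} mm gap along the merge axis"
            )

    parts = [normalize_signal(b.data, r) for b, r in zip(blocks, refs)]
    merged = np.concatenate(parts, axis=axis)
    return Volume(data=merged, spacing=first.spacing, origin=blocks[0].origin,
                  axis_labels=first.axis_labels, units="muscle-normalized")
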