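"""Readers and writers.

NRRD is the canonical on-disk format for masks and dose (uint8 / float32,
grid metadata in the header, via SimpleITK); NIfTI is supported through
nibabel. DICOM-RT support is read-mostly: RTSTRUCT contours are rasterized
slice-wise with even-odd fill, RTDOSE grids are scaled to Gy. A minimal
RTSTRUCT/RTDOSE writer exists for interoperability round-trip tests only;
the objects it emits are synthetic, not clinical exports.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

from .dose import DoseGrid
from .volumes import GridMismatchError, StructureMask, VoxelGrid

# internal array axis order is (x, y, z); SimpleITK arrays are (z, y, x)


def _sitk():
    import SimpleITK as sitk
    return sitk


def write_image(path, array: np.ndarray, grid: VoxelGrid) -> None:
    sitk = _sitk()
    img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
    img.SetSpacing(tuple(grid.spacing))
    img.SetOrigin(tuple(grid.origin))
    sitk.WriteImage(img, str(path))


def read_image(path) -> tuple[np.ndarray, VoxelGrid]:
    sitk = _sitk()
    img = sitk.ReadImage(str(path))
    array = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    grid = VoxelGrid(shape=array.shape, spacing=tuple(img.GetSpacing()),
                     origin=tuple(img.GetOrigin()))
    return array, grid


def write_mask(path, mask: StructureMask) -> None:
    write_image(path, mask.data.astype(np.uint8), mask.grid)


def read_mask(path, name: str | None = None) -> StructureMask:
    array, grid = read_image(path)
    return StructureMask(grid, name or Path(path).stem, array > 0)


def write_dose(path, dose: DoseGrid) -> None:
    write_image(path, dose.data.astype(np.float32), dose.grid)


def read_dose(path) -> DoseGrid:
    array, grid = read_image(path)
    return DoseGrid(grid, array.astype(float), Path(path).stem)


def write_mask_nifti(path, mask: StructureMask) -> None:
    import nibabel as nib
    affine = np.diag(list(mask.grid.spacing) + [1.0])
    affine[:3, 3] = mask.grid.origin
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def read_mask_nifti(path, name: str | None = None) -> StructureMask:
    import nibabel as nib
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(affine[a, a]) for a in range(3))
    origin = tuple(float(affine[a, 3]) for a in range(3))
    data = np.asarray(img.dataobj) > 0
    grid = VoxelGrid(shape=data.shape, spacing=spacing, origin=origin)
    return StructureMask(grid, name or Path(path).stem, data)


# ---------------------------------------------------------------- DICOM-RT

class MissingStructureError(KeyError):
    pass


def read_rtstruct(path, grid: VoxelGrid, roi_names=None) -> dict[str, StructureMask]:
    """Rasterize RTSTRUCT planar contours onto a target grid.

    Each ROI's contours are filled slice-wise with the even-odd rule
    (multiple polygons on one slice XOR together, so holes work). Contours
    must be axial (constant z per contour).
    """
    import pydicom
    from skimage.draw import polygon as sk_polygon

    ds = pydicom.dcmread(str(path))
    rois = {roi.ROIName: roi.ROINumber for roi in ds.StructureSetROISequence}
    wanted = list(roi_names) if roi_names else list(rois)
    missing = [n for n in wanted if n not in rois]
    if missing:
        raise MissingStructureError(f"ROIs not in RTSTRUCT: {missing}")
    by_number = {c.ReferencedROINumber: c for c in ds.ROIContourSequence}

    out: dict[str, StructureMask] = {}
    zs = grid.origin[2] + grid.spacing[2] * np.arange(grid.shape[2])
    for name in wanted:
        data = np.zeros(grid.shape, bool)
        contour_seq = getattr(by_number.get(rois[name]), "ContourSequence", None) or []
        for contour in contour_seq:
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            if np.ptp(pts[:, 2]) > 1e-3:
                raise ValueError(f"non-axial contour in ROI {name!r}")
            k = int(np.argmin(np.abs(zs - pts[0, 2])))
            if abs(zs[k] - pts[0, 2]) > grid.spacing[2]:
                continue  # slice outside the grid
            ii = (pts[:, 0] - grid.origin[0]) / grid.spacing[0]
            jj = (pts[:, 1] - grid.origin[1]) / grid.spacing[1]
            rr, cc = sk_polygon(ii, jj, shape=grid.shape[:2])
            data[rr, cc, k] ^= True  # even-odd fill
        out[name] = StructureMask(grid, name, data)
    return out


def write_rtstruct(path, masks: dict[str, StructureMask]) -> None:
    """Write a synthetic RTSTRUCT (round-trip testing only): contours are
    extracted per slice with marching squares at the 0.5 level."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid
    from skimage import measure

    grid = next(iter(masks.values())).grid
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "synthetic"
    ds.StructureSetDate = datetime.date(2000, 1, 1).strftime("%Y%m%d")
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []

    frame_uid = generate_uid()
    for number, (name, mask) in enumerate(masks.items(), start=1):
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for k in range(grid.shape[2]):
            sl = mask.data[:, :, k]
            if not sl.any():
                continue
            z = grid.origin[2] + grid.spacing[2] * k
            padded = np.pad(sl.astype(float), 1)
            for contour in measure.find_contours(padded, 0.5):
                ij = contour - 1.0  # undo pad
                xs = grid.origin[0] + ij[:, 0] * grid.spacing[0]
                ys = grid.origin[1] + ij[:, 1] * grid.spacing[1]
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(xs)
                c.ContourData = [float(v) for xyz in zip(xs, ys) for v in (*xyz, z)]
                rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read an RTDOSE grid; physical dose in Gy = stored values times the
    file's DoseGridScaling."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    scaling = getattr(ds, "DoseGridScaling", None)
    units = getattr(ds, "DoseUnits", None)
    if scaling is None or units != "GY":
        raise ValueError("RTDOSE without Gy scaling metadata is rejected")
    arr = ds.pixel_array.astype(float) * float(scaling)  # (frames=z, rows=y, cols=x)
    data = arr.transpose(2, 1, 0)
    dz = float(ds.GridFrameOffsetVector[1] - ds.GridFrameOffsetVector[0]) \
        if len(ds.GridFrameOffsetVector) > 1 else 1.0
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), dz)
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = VoxelGrid(shape=data.shape, spacing=spacing, origin=origin)
    return DoseGrid(grid, data, Path(path).stem)


def write_rtdose(path, dose: DoseGrid, scaling: float = 1e-3) -> None:
    """Write a minimal synthetic RTDOSE (interoperability smoke tests)."""
    import pydicom
    from pydicom.dataset import FileMetaDataset
    from pydicom.uid import generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
    ds = pydicom.dataset.FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    grid = dose.grid
    ds.Rows = grid.shape[1]
    ds.Columns = grid.shape[0]
    ds.NumberOfFrames = grid.shape[2]
    ds.PixelSpacing = [grid.spacing[1], grid.spacing[0]]
    ds.GridFrameOffsetVector = [grid.spacing[2] * k for k in range(grid.shape[2])]
    ds.ImagePositionPatient = list(grid.origin)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    stored = np.round(dose.data / scaling).astype(np.uint32)
    ds.PixelData = stored.transpose(2, 1, 0).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def require_same_grid(dose: DoseGrid, masks: dict[str, StructureMask]) -> None:
    for name, mask in masks.items():
        if mask.grid != dose.grid:
            raise GridMismatchError(f"structure {name!r} is not on the dose grid")
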