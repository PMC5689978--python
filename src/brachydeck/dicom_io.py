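"""Readers and writers for the four DICOM RT objects used by the pipeline.

Everything is normalized on read to one convention: LPS patient frame,
millimetres, voxel centers.  Only axis-aligned axial volumes are supported;
oblique series are rejected.

Catheter/dwell encoding dialect
-------------------------------
DICOM brachy RT Plans are not uniquely transferable between planning
systems.  This package reads and writes one documented dialect:

* each channel's ``BrachyControlPointSequence`` lists, first, the catheter
  reconstruction points (tip first) each appearing **once** with an
  unchanged cumulative time weight, then each dwell position appearing
  **twice** (arrival/departure) with a weight increment;
* per-dwell time in seconds is reconstructed from the standard cumulative
  time-weight encoding::

      t_i = (w_depart - w_arrive) / FinalCumulativeTimeWeight * ChannelTotalTime

Files whose channels contain no duplicated control-point pairs carry no
dwell weights in this dialect and are rejected as an unknown layout.
"""
from __future__ import annotations

import csv
import os
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .errors import InputError
from .grids import CTVolume, DoseGrid
from .plan import PlanModel, Structure, StructureSet
from .sources import Catheter, DwellPosition

__all__ = [
    "read_ct_series", "write_ct_series", "read_rtplan", "write_rtplan",
    "read_rtdose", "write_rtdose", "read_rtstruct", "write_rtstruct",
    "export_dwell_csv", "UIDFactory",
]

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTPLAN_STORAGE = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"

_AXES = np.vstack([np.eye(3), -np.eye(3)])


class UIDFactory:
    """Deterministic UID generation so written fixtures are reproducible."""

    def __init__(self, seed: int = 0):
        self.seed = int(seed)
        self._n = 0

    def __call__(self) -> str:
        self._n += 1
        return f"2.25.{self.seed + 1}.{self._n}"


def _require_axis_aligned(row_dir, col_dir, what):
    for v in (row_dir, col_dir):
        if np.abs(_AXES @ v).max() < 1.0 - 1e-6:
            raise InputError(f"{what}: oblique orientation unsupported "
                             f"(direction {np.round(v, 6)})")


def _file_meta(sop_class, sop_uid) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _base_dataset(sop_class, uid_factory, modality) -> Dataset:
    ds = Dataset()
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = uid_factory()
    ds.file_meta = _file_meta(sop_class, ds.SOPInstanceUID)
    ds.Modality = modality
    ds.PatientName = "PHANTOM^BRACHYDECK"
    ds.PatientID = "BD000"
    ds.StudyInstanceUID = f"2.25.{uid_factory.seed + 1}.0.1"
    series = {"CT": 2, "RTPLAN": 3, "RTDOSE": 4, "RTSTRUCT": 5}[modality]
    ds.SeriesInstanceUID = f"2.25.{uid_factory.seed + 1}.0.{series}"
    ds.FrameOfReferenceUID = f"2.25.{uid_factory.seed + 1}.0.9"
    return ds


# --------------------------------------------------------------------------
# CT series
# --------------------------------------------------------------------------

def read_ct_series(directory) -> CTVolume:
    """Load one axial CT series from a directory of slice files.

    Slices are sorted by position along the slice normal; the rescale
    slope/intercept is applied; non-uniform slice spacing (> 1e-3 mm
    deviation) and mixed series are rejected.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and p.suffix.lower() == ".dcm")
    datasets = []
    for p in files:
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", "") == "CT":
            datasets.append(ds)
    if not datasets:
        raise InputError(f"{directory}: no CT slices found")
    uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(uids) > 1:
        raise InputError(f"{directory}: mixed CT series ({len(uids)} UIDs)")

    row_dir = np.array(datasets[0].ImageOrientationPatient[:3], dtype=float)
    col_dir = np.array(datasets[0].ImageOrientationPatient[3:], dtype=float)
    _require_axis_aligned(row_dir, col_dir, str(directory))
    normal = np.cross(row_dir, col_dir)

    pos = np.array([[float(v) for v in ds.ImagePositionPatient]
                    for ds in datasets])
    along = pos @ normal
    order = np.argsort(along)
    datasets = [datasets[i] for i in order]
    along = along[order]

    if len(datasets) > 1:
        gaps = np.diff(along)
        dz = float(np.median(gaps))
        bad = np.flatnonzero(np.abs(gaps - dz) > 1e-3)
        if bad.size:
            b = bad[0]
            raise InputError(
                f"{directory}: non-uniform slice spacing: gap of "
                f"{gaps[b]:.3f} mm between slices {b} and {b + 1} "
                f"(at {along[b]:.2f} -> {along[b + 1]:.2f} mm; "
                f"expected {dz:.3f} mm)")
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))

    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    hu = np.stack([ds.pixel_array for ds in datasets]).astype(np.float64)
    hu = slope * hu + intercept
    as_int = np.rint(hu)
    if np.abs(hu - as_int).max() < 1e-6:
        hu = as_int.astype(np.int16)

    ps = [float(v) for v in datasets[0].PixelSpacing]   # (row, col)
    origin = np.array([float(v) for v in datasets[0].ImagePositionPatient])
    return CTVolume(origin=origin, spacing=np.array([ps[1], ps[0], dz]),
                    row_dir=row_dir, col_dir=col_dir, hu=hu,
                    rescale=(slope, intercept))


def write_ct_series(vol: CTVolume, directory, seed: int = 0):
    """Write one file per slice; returns the list of paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    uids = UIDFactory(seed)
    series_uid = f"2.25.{uids.seed + 1}.0.2"
    hu = np.rint(np.asarray(vol.hu)).astype(np.int16)
    paths = []
    for k in range(hu.shape[0]):
        ds = _base_dataset(CT_STORAGE, uids, "CT")
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = list(vol.row_dir) + list(vol.col_dir)
        ipp = vol.origin + k * vol.spacing[2] * vol.slice_dir
        ds.ImagePositionPatient = [float(v) for v in ipp]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.Rows, ds.Columns = hu.shape[1], hu.shape[2]
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1   # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1
        ds.RescaleIntercept = 0
        ds.PixelData = np.ascontiguousarray(hu[k]).tobytes()
        p = directory / f"ct_{k:04d}.dcm"
        ds.save_as(p, enforce_file_format=True)
        paths.append(p)
    return paths


# --------------------------------------------------------------------------
# RT Plan
# --------------------------------------------------------------------------

def read_rtplan(path) -> PlanModel:
    """Parse a brachy RT Plan into catheters, dwells and times."""
    ds = pydicom.dcmread(path)
    try:
        setups = ds.ApplicationSetupSequence
    except AttributeError:
        raise InputError(f"{path}: no ApplicationSetupSequence; "
                         "not a brachy RT Plan")
    source_id = "unknown"
    if getattr(ds, "SourceSequence", None):
        source_id = str(getattr(ds.SourceSequence[0], "SourceManufacturer",
                                "unknown"))
    prescription = None
    if getattr(ds, "DoseReferenceSequence", None):
        v = getattr(ds.DoseReferenceSequence[0], "TargetPrescriptionDose",
                    None)
        prescription = float(v) if v is not None else None

    catheters, dwells = [], []
    dwell_index = 0
    for setup in setups:
        for ch in setup.ChannelSequence:
            cid = int(ch.ChannelNumber)
            total = float(ch.ChannelTotalTime)
            final_w = float(ch.FinalCumulativeTimeWeight)
            cps = ch.BrachyControlPointSequence
            pos = [np.array([float(v) for v in cp.ControlPoint3DPosition])
                   for cp in cps]
            try:
                w = [float(cp.CumulativeTimeWeight) for cp in cps]
            except AttributeError:
                raise InputError(f"{path}: control points without cumulative "
                                 "time weights")
            path_points, ch_dwells = [], []
            i = 0
            while i < len(pos):
                if (i + 1 < len(pos)
                        and np.linalg.norm(pos[i + 1] - pos[i]) < 1e-6):
                    dt = (w[i + 1] - w[i]) / final_w * total if final_w else 0.0
                    ch_dwells.append((pos[i], dt))
                    i += 2
                else:
                    path_points.append(pos[i])
                    i += 1
            if not ch_dwells:
                raise InputError(
                    f"{path}: channel {cid} has no duplicated control-point "
                    "pairs; unknown catheter/dwell layout")
            if len(path_points) < 2:
                raise InputError(f"{path}: channel {cid} has fewer than two "
                                 "catheter path points")
            catheters.append(Catheter(cid, np.array(path_points)))
            for center, dt in ch_dwells:
                dwells.append(DwellPosition(cid, center, dt, dwell_index))
                dwell_index += 1
    plan = PlanModel(source_id, catheters, dwells, prescription)
    if plan.total_time <= 0:
        raise InputError(f"{path}: zero total irradiation time")
    return plan


def write_rtplan(plan: PlanModel, path, seed: int = 0) -> str:
    uids = UIDFactory(seed)
    ds = _base_dataset(RTPLAN_STORAGE, uids, "RTPLAN")
    ds.RTPlanLabel = "brachydeck"
    ds.BrachyTreatmentTechnique = "INTERSTITIAL"
    ds.BrachyTreatmentType = "HDR"

    src = Dataset()
    src.SourceNumber = 1
    src.SourceType = "CYLINDER"
    src.SourceIsotopeName = "Ir-192"
    src.SourceManufacturer = plan.source_id
    ds.SourceSequence = [src]

    if plan.prescription_dose is not None:
        ref = Dataset()
        ref.DoseReferenceNumber = 1
        ref.DoseReferenceStructureType = "SITE"
        ref.DoseReferenceType = "TARGET"
        ref.TargetPrescriptionDose = float(plan.prescription_dose)
        ds.DoseReferenceSequence = [ref]

    setup = Dataset()
    setup.ApplicationSetupType = "BREAST"
    setup.ApplicationSetupNumber = 1
    channels = []
    for cath in plan.catheters:
        cath_dwells = [d for d in plan.dwells if d.catheter_id == cath.id]
        ch = Dataset()
        ch.ChannelNumber = int(cath.id)
        ch.ChannelLength = float(np.sum(np.linalg.norm(
            np.diff(cath.control_points, axis=0), axis=1)))
        ch.SourceMovementType = "STEPWISE"
        ch.ReferencedSourceNumber = 1
        total = float(sum(d.time for d in cath_dwells))
        ch.ChannelTotalTime = total
        final_w = 1000.0
        ch.FinalCumulativeTimeWeight = final_w
        cps = []
        idx = 0

        def _cp(position, weight):
            nonlocal idx
            cp = Dataset()
            cp.ControlPointIndex = idx
            cp.ControlPoint3DPosition = [float(v) for v in position]
            cp.CumulativeTimeWeight = float(weight)
            idx += 1
            return cp

        for p in cath.control_points:
            cps.append(_cp(p, 0.0))
        w = 0.0
        for d in cath_dwells:
            cps.append(_cp(d.center, w))
            w += (d.time / total * final_w) if total > 0 else 0.0
            cps.append(_cp(d.center, w))
        if cath_dwells:   # close float residue so weights end exactly final_w
            cps[-1].CumulativeTimeWeight = final_w if total > 0 else 0.0
        ch.NumberOfControlPoints = len(cps)
        ch.BrachyControlPointSequence = cps
        channels.append(ch)
    setup.ChannelSequence = channels
    ds.ApplicationSetupSequence = [setup]
    ds.save_as(path, enforce_file_format=True)
    return str(path)


# --------------------------------------------------------------------------
# RT Dose
# --------------------------------------------------------------------------

def read_rtdose(path) -> DoseGrid:
    ds = pydicom.dcmread(path)
    row_dir = np.array(ds.ImageOrientationPatient[:3], dtype=float)
    col_dir = np.array(ds.ImageOrientationPatient[3:], dtype=float)
    _require_axis_aligned(row_dir, col_dir, str(path))
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) > 1:
        steps = np.diff(offsets)
        if np.abs(steps - steps[0]).max() > 1e-3:
            raise InputError(f"{path}: non-uniform dose grid offsets")
        dz = float(steps[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0))
    scaling = float(ds.DoseGridScaling)
    values = ds.pixel_array.astype(np.float64) * scaling
    ps = [float(v) for v in ds.PixelSpacing]
    origin = np.array([float(v) for v in ds.ImagePositionPatient])
    return DoseGrid(origin=origin, spacing=np.array([ps[1], ps[0], dz]),
                    row_dir=row_dir, col_dir=col_dir, values=values)


def write_rtdose(grid: DoseGrid, path, seed: int = 0) -> str:
    """32-bit quantization: relative error <= 1e-6 of the grid maximum."""
    uids = UIDFactory(seed)
    ds = _base_dataset(RTDOSE_STORAGE, uids, "RTDOSE")
    values = np.asarray(grid.values, dtype=np.float64)
    vmax = float(values.max())
    scaling = vmax / (2 ** 32 - 1) if vmax > 0 else 1.0
    stored = np.rint(values / scaling).astype(np.uint32)
    nz, ny, nx = values.shape
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.ImageOrientationPatient = list(grid.row_dir) + list(grid.col_dir)
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.GridFrameOffsetVector = [float(k * grid.spacing[2])
                                for k in range(nz)]
    ds.NumberOfFrames = nz
    ds.FrameIncrementPointer = (0x3004, 0x000C)
    ds.Rows, ds.Columns = ny, nx
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.ascontiguousarray(stored, dtype="<u4").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return str(path)


# --------------------------------------------------------------------------
# RT Structure Set
# --------------------------------------------------------------------------

def read_rtstruct(path) -> StructureSet:
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName)
             for r in ds.StructureSetROISequence}
    structures = []
    for rc in ds.ROIContourSequence:
        n = int(rc.ReferencedROINumber)
        color = tuple(int(v) for v in getattr(rc, "ROIDisplayColor",
                                              [255, 0, 0]))
        contours = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData])
            contours.append(data.reshape(-1, 3))
        structures.append(Structure(names[n], contours, color))
    return StructureSet(structures)


def write_rtstruct(ss: StructureSet, path, seed: int = 0) -> str:
    uids = UIDFactory(seed)
    ds = _base_dataset(RTSTRUCT_STORAGE, uids, "RTSTRUCT")
    ds.StructureSetLabel = "brachydeck"
    rois, rcs = [], []
    for n, s in enumerate(ss.structures, start=1):
        roi = Dataset()
        roi.ROINumber = n
        roi.ROIName = s.name
        roi.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        rois.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = n
        rc.ROIDisplayColor = list(s.color)
        seq = []
        for poly in s.contours:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in np.asarray(poly).ravel()]
            seq.append(c)
        rc.ContourSequence = seq
        rcs.append(rc)
    ds.StructureSetROISequence = rois
    ds.ROIContourSequence = rcs
    ds.save_as(path, enforce_file_format=True)
    return str(path)


def export_dwell_csv(plan: PlanModel, path) -> str:
    """Catheter id, dwell coordinates (mm) and time (s) as CSV."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["catheter_id", "x_mm", "y_mm", "z_mm", "time_s"])
        for d in plan.dwells:
            w.writerow([d.catheter_id, f"{d.center[0]:.6f}",
                        f"{d.center[1]:.6f}", f"{d.center[2]:.6f}",
                        f"{d.time:.6f}"])
    return str(path)
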