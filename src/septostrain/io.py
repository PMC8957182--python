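"""Reading and writing the pipeline's on-disk formats.

Image sequences travel either as multi-frame secondary-capture DICOM
(uint16 pixel data with rescale slope/intercept) or as a PNG series with
a JSON sidecar holding frame rate, pixel spacing, intensity scaling and
optional valve timing. Strain curves are CSV (``time_s, strain_pct``),
segmentations are JSON lists of (x, y) pixel vertices, displacement
fields are compressed ``.npz`` archives with a JSON schema sidecar.

Coordinate convention (recorded in every sidecar): (x, y) pixels,
0-based, x rightward, y downward; displacements positive rightward /
downward.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .curves import StrainCurve
from .timing import CardiacTiming
from .tracking import DisplacementField, ImageSequence

__all__ = [
    "write_png_stack",
    "read_png_stack",
    "write_dicom",
    "read_dicom",
    "quantize_like_dicom",
    "write_strain_csv",
    "read_strain_csv",
    "write_timing_json",
    "read_timing_json",
    "write_segmentation_json",
    "read_segmentation_json",
    "write_displacement_field",
    "read_displacement_field",
]

_CONVENTION = "x,y pixels, 0-based, x rightward, y downward; displacement +x right, +y down"


def _quantize(frames: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Map float frames to uint16 with affine rescale metadata.

    Slope and intercept are rounded to 10 significant digits (the
    precision that survives a DICOM decimal-string round trip) before
    quantization, so re-reading reproduces exactly the stored mapping.
    """
    lo = float(frames.min())
    hi = float(frames.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    slope = float(f"{slope:.10g}")
    lo = float(f"{lo:.10g}")
    q = np.clip(np.round((frames - lo) / slope), 0, 65535).astype(np.uint16)
    return q, slope, lo


def quantize_like_dicom(seq: ImageSequence) -> ImageSequence:
    """The sequence as it will read back after a uint16 DICOM round trip."""
    q, slope, intercept = _quantize(np.asarray(seq.frames, dtype=np.float64))
    frames = q.astype(np.float64) * slope + intercept
    return ImageSequence(
        frames=frames,
        frame_rate=seq.frame_rate,
        pixel_spacing=seq.pixel_spacing,
    )


# ---------------------------------------------------------------------------
# PNG stack + JSON sidecar
# ---------------------------------------------------------------------------


def write_png_stack(
    seq: ImageSequence, directory: str | Path, timing: CardiacTiming | None = None
) -> Path:
    """Write one 16-bit PNG per frame plus a ``sequence.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(seq.frames, dtype=np.float64)
    q, slope, intercept = _quantize(frames)
    for k in range(seq.n_frames):
        iio.imwrite(directory / f"frame_{k:04d}.png", q[k])
    sidecar = {
        "format": "png-stack",
        "n_frames": int(seq.n_frames),
        "frame_rate_hz": seq.frame_rate,
        "pixel_spacing_mm": seq.pixel_spacing,
        "rescale_slope": slope,
        "rescale_intercept": intercept,
        "coordinate_convention": _CONVENTION,
        "timing": timing.to_dict() if timing else None,
    }
    path = directory / "sequence.json"
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_png_stack(directory: str | Path) -> tuple[ImageSequence, CardiacTiming | None]:
    directory = Path(directory)
    meta = json.loads((directory / "sequence.json").read_text())
    frames = []
    for k in range(meta["n_frames"]):
        frames.append(np.asarray(iio.imread(directory / f"frame_{k:04d}.png")))
    raw = np.stack(frames).astype(np.float64)
    raw = raw * meta["rescale_slope"] + meta["rescale_intercept"]
    seq = ImageSequence(
        frames=raw,
        frame_rate=meta["frame_rate_hz"],
        pixel_spacing=meta["pixel_spacing_mm"],
    )
    timing = CardiacTiming.from_dict(meta["timing"]) if meta.get("timing") else None
    return seq, timing


# ---------------------------------------------------------------------------
# multi-frame DICOM (secondary capture)
# ---------------------------------------------------------------------------


def write_dicom(
    seq: ImageSequence, path: str | Path, timing: CardiacTiming | None = None
) -> Path:
    """Write the loop as a multi-frame secondary-capture DICOM file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(seq.frames, dtype=np.float64)
    q, slope, intercept = _quantize(frames)
    n, h, w = q.shape

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "US"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.PatientName = "synthetic"
    ds.PatientID = "synthetic"
    ds.Rows = h
    ds.Columns = w
    ds.NumberOfFrames = n
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    ds.PixelSpacing = [f"{seq.pixel_spacing:.6g}", f"{seq.pixel_spacing:.6g}"]
    ds.FrameTime = f"{1000.0 / seq.frame_rate:.10g}"  # ms
    ds.CineRate = int(round(seq.frame_rate))
    if timing is not None:
        ds.ImageComments = json.dumps({"timing": timing.to_dict()})
    ds.PixelData = q.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dicom(path: str | Path) -> tuple[ImageSequence, CardiacTiming | None]:
    ds = pydicom.dcmread(path)
    frames = ds.pixel_array.astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    frames = frames * slope + intercept
    frame_rate = 1000.0 / float(ds.FrameTime)
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    timing = None
    comments = getattr(ds, "ImageComments", "")
    if comments:
        try:
            payload = json.loads(comments)
            if payload.get("timing"):
                timing = CardiacTiming.from_dict(payload["timing"])
        except (json.JSONDecodeError, TypeError, ValueError):
            timing = None
    seq = ImageSequence(frames=frames, frame_rate=frame_rate, pixel_spacing=spacing)
    return seq, timing


# ---------------------------------------------------------------------------
# strain curves, timing, segmentations, displacement fields
# ---------------------------------------------------------------------------


def write_strain_csv(curve: StrainCurve, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": curve.time, "strain_pct": curve.strain}).to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_strain_csv(path: str | Path, timing: CardiacTiming) -> StrainCurve:
    df = pd.read_csv(path)
    return StrainCurve(
        time=df["time_s"].to_numpy(),
        strain=df["strain_pct"].to_numpy(),
        timing=timing,
    )


def write_timing_json(timing: CardiacTiming, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(timing.to_dict(), indent=2, sort_keys=True))
    return path


def read_timing_json(path: str | Path) -> CardiacTiming:
    return CardiacTiming.from_dict(json.loads(Path(path).read_text()))


def write_segmentation_json(polygon: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "coordinate_convention": _CONVENTION,
        "vertices_xy_px": np.asarray(polygon, dtype=float).tolist(),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_segmentation_json(path: str | Path) -> np.ndarray:
    payload = json.loads(Path(path).read_text())
    return np.asarray(payload["vertices_xy_px"], dtype=float)


def write_displacement_field(field: DisplacementField, path: str | Path) -> Path:
    """Compressed array archive plus a JSON schema sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        displacements=field.displacements,
        scores=field.scores,
        valid=field.valid,
        trajectory=field.trajectory,
        mesh_points=field.mesh.points,
        segmentation=field.mesh.segmentation,
    )
    schema = {
        "coordinate_convention": _CONVENTION,
        "arrays": {
            "displacements": "(n_pairs, n_radial, n_long, 2) px, (dx, dy)",
            "scores": "(n_pairs, n_radial, n_long) NCC peak value",
            "valid": "(n_pairs, n_radial, n_long) bool, genuine matches",
            "trajectory": "(n_frames, n_radial, n_long, 2) cumulative positions",
            "mesh_points": "(n_radial, n_long, 2) reference mesh",
            "segmentation": "(m, 2) polygon vertices",
        },
    }
    Path(str(path) + ".schema.json").write_text(json.dumps(schema, indent=2))
    return path


def read_displacement_field(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(path) as data:
        return {k: data[k] for k in data.files}
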