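"""EPID strip-test image analysis.

The DRGS test delivers seven MLC-defined strips, each with a different
dose-rate/gantry-speed combination, followed by an open field.  The
strip image is divided pixelwise by the open-field image, cancelling the
beam profile, and each strip's mean *corrected* reading is compared to
the mean over all strips:

    deviation_i (%) = (mean_i / mean(all segments)) * 100 - 100

A well-behaved linac keeps every deviation near zero regardless of the
dose-rate/speed combination.  Routine QA additionally differences each
strip's mean corrected reading against a per-machine baseline built from
historical sessions; the vendor's acceptance criterion is below 3% for
any ROI.

Conventions chosen here (the published procedure leaves them open):

* the grand mean is the *unweighted* mean of the per-segment means, so
  the deviations average to zero exactly even with unequal ROI sizes;
* ROIs are ordered left to right in imager columns, ROI 1 leftmost;
* sampling rectangles are the strip apertures eroded on every side by a
  fraction of the strip width (default 0.25) to stay out of penumbra;
* pixels where the open field reads below a floor (default 5% of its
  median) are masked out of every average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .errors import BaselineError, ImageError, LayoutError
from .rtplan import TreatmentPlan

RTIMAGE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.1"


# ---------------------------------------------------------------------------
# images


@dataclass
class EpidImage:
    """One EPID acquisition: a 2-D detector reading in linear units."""

    pixels: np.ndarray  # float, shape (rows, cols)
    pixel_spacing: tuple[float, float]  # mm per pixel (row, col)
    kind: str = "STRIP"  # STRIP or OPEN
    machine_id: str = ""
    acquired: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ImageError(f"pixel array must be 2-D and non-empty, got shape {self.pixels.shape}")
        if min(self.pixel_spacing) <= 0:
            raise ImageError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_rtimage(path: str | Path, kind: str | None = None) -> EpidImage:
    """Read a DICOM RT Image with rescale slope/intercept applied."""
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(ds, "PixelSpacing", [1.0, 1.0])
    label = str(getattr(ds, "RTImageLabel", ""))
    if kind is None:
        kind = label if label in ("STRIP", "OPEN") else "STRIP"
    return EpidImage(
        pixels=arr,
        pixel_spacing=(float(spacing[0]), float(spacing[1])),
        kind=kind,
        machine_id=str(getattr(ds, "StationName", "")),
        acquired=str(getattr(ds, "AcquisitionDate", "")),
    )


def write_rtimage(image: EpidImage, out_path: str | Path) -> Path:
    """Write an EPID image as a 16-bit DICOM RT Image."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTIMAGE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTIMAGE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.PatientName = "QA"
    ds.PatientID = "QA"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.RTImageLabel = image.kind
    ds.StationName = image.machine_id
    if image.acquired:
        ds.AcquisitionDate = image.acquired

    lo = float(image.pixels.min())
    hi = float(image.pixels.max())
    slope = (hi - lo) / 65535.0 if hi > lo else 1.0
    stored = np.round((image.pixels - lo) / slope).astype(np.uint16)
    ds.Rows, ds.Columns = stored.shape
    ds.ImagePlanePixelSpacing = [image.pixel_spacing[0], image.pixel_spacing[1]]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = lo
    ds.PixelData = stored.tobytes()
    out = Path(out_path)
    ds.save_as(str(out), enforce_file_format=True)
    return out


# ---------------------------------------------------------------------------
# strip layout and ROI placement


@dataclass(frozen=True)
class RoiSpec:
    """Half-open sampling rectangle of one ROI (0-based pixel indices)."""

    roi_index: int  # 1-based, left to right
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)


@dataclass
class StripLayout:
    """Strip apertures on the imager: shared row band, per-strip columns."""

    rows: tuple[int, int]
    strips: list[tuple[int, int]]  # half-open column bounds, left to right

    def to_json(self, path: str | Path) -> Path:
        payload = {"rows": list(self.rows), "strips": [list(s) for s in self.strips]}
        Path(path).write_text(json.dumps(payload, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "StripLayout":
        raw = json.loads(Path(path).read_text())
        return cls(rows=tuple(raw["rows"]), strips=[tuple(s) for s in raw["strips"]])


@dataclass(frozen=True)
class ImagerGeometry:
    """Projection from MLC aperture coordinates (mm at isocenter) to pixels."""

    magnification: float = 1.0  # SID / SAD
    leaf_width_mm: float = 5.0  # at isocenter


def layout_from_plan(
    plan: TreatmentPlan,
    image: EpidImage,
    geometry: ImagerGeometry = ImagerGeometry(),
) -> StripLayout:
    """Project the arc beam's per-segment MLC apertures onto the imager.

    Segment i's aperture (CP i of the first arc beam) becomes strip i.
    Leaf pairs are indexed top to bottom and centered on the beam axis.
    """
    arcs = plan.arc_beams()
    if not arcs:
        raise LayoutError("plan has no arc beam to derive a strip layout from")
    beam = arcs[0]
    rows_px, cols_px = image.shape
    sp_r, sp_c = image.pixel_spacing
    c_row, c_col = rows_px / 2.0, cols_px / 2.0
    strips: list[tuple[int, int]] = []
    row_bounds: tuple[int, int] | None = None
    for cp in beam.control_points[:-1]:
        mlc = cp.mlc_leaf_positions
        if mlc is None:
            raise LayoutError(f"CP {cp.index} of beam {beam.beam_id} carries no MLC positions")
        bank_a, bank_b = mlc
        open_pairs = np.nonzero(bank_b - bank_a > 0.5)[0]
        if open_pairs.size == 0:
            raise LayoutError(f"CP {cp.index}: no open leaf pairs")
        x_lo = float(bank_a[open_pairs].min())
        x_hi = float(bank_b[open_pairs].max())
        c0 = int(round(c_col + x_lo * geometry.magnification / sp_c))
        c1 = int(round(c_col + x_hi * geometry.magnification / sp_c))
        n_pairs = bank_a.size
        y_lo = (open_pairs[0] - n_pairs / 2.0) * geometry.leaf_width_mm
        y_hi = (open_pairs[-1] + 1 - n_pairs / 2.0) * geometry.leaf_width_mm
        r0 = int(round(c_row + y_lo * geometry.magnification / sp_r))
        r1 = int(round(c_row + y_hi * geometry.magnification / sp_r))
        strips.append((c0, c1))
        row_bounds = (r0, r1) if row_bounds is None else (min(row_bounds[0], r0), max(row_bounds[1], r1))
    strips.sort(key=lambda s: s[0])
    assert row_bounds is not None
    return StripLayout(rows=row_bounds, strips=strips)


def locate_rois(
    source: StripLayout | TreatmentPlan,
    image: EpidImage,
    margin_fraction: float = 0.25,
    geometry: ImagerGeometry = ImagerGeometry(),
) -> list[RoiSpec]:
    """Place one sampling rectangle per strip, eroded away from penumbra.

    Each strip aperture is shrunk on all four sides by ``margin_fraction``
    of the strip *width*; 0.25 keeps the central half of each strip.
    """
    layout = source if isinstance(source, StripLayout) else layout_from_plan(source, image, geometry)
    if not (0 <= margin_fraction):
        raise LayoutError(f"margin_fraction must be >= 0, got {margin_fraction}")
    rows_px, cols_px = image.shape
    rois: list[RoiSpec] = []
    for i, (c0, c1) in enumerate(sorted(layout.strips), start=1):
        width = c1 - c0
        m = int(round(margin_fraction * width))
        r0, r1 = layout.rows[0] + m, layout.rows[1] - m
        cc0, cc1 = c0 + m, c1 - m
        if cc1 <= cc0 or r1 <= r0:
            raise LayoutError(f"ROI {i}: erosion by {m} px degenerates the rectangle")
        if cc0 < 0 or cc1 > cols_px or r0 < 0 or r1 > rows_px:
            raise LayoutError(f"ROI {i}: rectangle ({r0}:{r1}, {cc0}:{cc1}) outside image {image.shape}")
        rois.append(RoiSpec(i, r0, r1, cc0, cc1))
    for a, b in zip(rois, rois[1:]):
        if b.col_start < a.col_stop:
            raise LayoutError(f"ROIs {a.roi_index} and {b.roi_index} overlap after erosion")
    return rois


# ---------------------------------------------------------------------------
# the deviation statistic


def corrected_image(
    strip: EpidImage,
    open_field: EpidImage,
    floor_fraction: float = 0.05,
) -> np.ma.MaskedArray:
    """Strip image divided pixelwise by the open field.

    Pixels where the open field reads below ``floor_fraction`` of its
    median are masked and excluded from every downstream average.
    """
    if strip.shape != open_field.shape:
        raise ImageError(f"image shapes differ: {strip.shape} vs {open_field.shape}")
    if strip.pixel_spacing != open_field.pixel_spacing:
        raise ImageError(
            f"pixel spacings differ: {strip.pixel_spacing} vs {open_field.pixel_spacing}"
        )
    floor = floor_fraction * float(np.median(open_field.pixels))
    mask = open_field.pixels < floor
    if mask.all():
        raise ImageError("open-field image is below the floor everywhere")
    denom = np.where(mask, 1.0, open_field.pixels)
    return np.ma.MaskedArray(strip.pixels / denom, mask=mask)


@dataclass(frozen=True)
class RoiDeviation:
    """One segment's mean corrected reading and its percent deviation."""

    roi_index: int
    mean_corrected: float
    deviation_pct: float


def segment_deviations(
    corrected: np.ndarray | np.ma.MaskedArray,
    rois: Sequence[RoiSpec],
) -> list[RoiDeviation]:
    """Per-ROI deviation from the unweighted mean of segment means."""
    if len(rois) < 2:
        raise ImageError(f"need >= 2 ROIs, got {len(rois)}")
    arr = np.ma.asarray(corrected)
    means: list[float] = []
    for roi in rois:
        sub = arr[roi.slices]
        if sub.count() == 0:
            raise ImageError(f"ROI {roi.roi_index} is fully masked")
        means.append(float(sub.mean()))
    grand = float(np.mean(means))
    return [
        RoiDeviation(roi.roi_index, m, (m / grand) * 100.0 - 100.0)
        for roi, m in zip(rois, means)
    ]


# ---------------------------------------------------------------------------
# baselines and QA reports


@dataclass
class BaselineRecord:
    """Per-ROI reference means for one machine, from historical sessions."""

    machine_id: str
    baseline_means: list[float]
    date_range: str = ""
    n_sessions: int = 0

    def __post_init__(self) -> None:
        if not self.baseline_means or any(v <= 0 for v in self.baseline_means):
            raise BaselineError(f"baseline means must be positive, got {self.baseline_means}")

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "machine_id": self.machine_id,
            "date_range": self.date_range,
            "n_sessions": self.n_sessions,
            "rois": [
                {"index": i + 1, "baseline_mean": v} for i, v in enumerate(self.baseline_means)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))
        return Path(path)

    @classmethod
    def from_json(cls, path: str | Path) -> "BaselineRecord":
        raw = json.loads(Path(path).read_text())
        rois = sorted(raw["rois"], key=lambda r: r["index"])
        return cls(
            machine_id=raw.get("machine_id", ""),
            baseline_means=[float(r["baseline_mean"]) for r in rois],
            date_range=raw.get("date_range", ""),
            n_sessions=int(raw.get("n_sessions", 0)),
        )


@dataclass(frozen=True)
class RoiComparison:
    roi_index: int
    measured_mean: float
    baseline_mean: float
    difference_pct: float
    passed: bool


@dataclass
class QaReport:
    """Measured-vs-baseline comparison with a pass/fail verdict per ROI."""

    rows: list[RoiComparison]
    tolerance_pct: float
    max_abs_difference_pct: float

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.rows)

    @property
    def differences_rounded(self) -> list[float]:
        """Differences at the 1-decimal display precision."""
        return [round(r.difference_pct, 1) for r in self.rows]

    def to_dict(self) -> dict:
        return {
            "tolerance_pct": self.tolerance_pct,
            "max_abs_difference_pct": self.max_abs_difference_pct,
            "passed": self.passed,
            "rois": [
                {
                    "index": r.roi_index,
                    "measured_mean": r.measured_mean,
                    "baseline_mean": r.baseline_mean,
                    "difference_pct": r.difference_pct,
                    "difference_pct_1dp": round(r.difference_pct, 1),
                    "passed": r.passed,
                }
                for r in self.rows
            ],
        }

    def to_table(self) -> str:
        lines = [f"{'ROI':>4} {'measured':>10} {'baseline':>10} {'diff %':>8}  verdict"]
        for r in self.rows:
            lines.append(
                f"{r.roi_index:>4} {r.measured_mean:>10.4f} {r.baseline_mean:>10.4f} "
                f"{round(r.difference_pct, 1):>8.1f}  {'pass' if r.passed else 'FAIL'}"
            )
        lines.append(
            f"max |diff| = {round(self.max_abs_difference_pct, 1):.1f}% "
            f"(tolerance {self.tolerance_pct:g}%): {'PASS' if self.passed else 'FAIL'}"
        )
        return "\n".join(lines)


def compare_to_baseline(
    measured: Sequence[float] | Sequence[RoiDeviation],
    baseline: BaselineRecord,
    tolerance_pct: float = 3.0,
) -> QaReport:
    """Difference each measured segment mean against the baseline.

    The difference is the ratio form (measured/baseline - 1) * 100, the
    same style as the deviation statistic.
    """
    means = [m.mean_corrected if isinstance(m, RoiDeviation) else float(m) for m in measured]
    if len(means) != len(baseline.baseline_means):
        raise BaselineError(
            f"{len(means)} measured ROIs vs {len(baseline.baseline_means)} baseline ROIs"
        )
    rows: list[RoiComparison] = []
    for i, (m, b) in enumerate(zip(means, baseline.baseline_means), start=1):
        diff = (m / b) * 100.0 - 100.0
        rows.append(RoiComparison(i, m, b, diff, abs(diff) <= tolerance_pct))
    max_abs = max(abs(r.difference_pct) for r in rows)
    return QaReport(rows=rows, tolerance_pct=tolerance_pct, max_abs_difference_pct=max_abs)


def update_baseline(
    history: Sequence[Sequence[float]],
    machine_id: str = "",
    date_range: str = "",
) -> BaselineRecord:
    """Aggregate per-session ROI means into a baseline (arithmetic mean)."""
    if len(history) == 0:
        raise BaselineError("need at least one session to build a baseline")
    n_rois = len(history[0])
    if any(len(s) != n_rois for s in history):
        raise BaselineError("sessions have inconsistent ROI counts")
    arr = np.asarray(history, dtype=float)
    return BaselineRecord(
        machine_id=machine_id,
        baseline_means=[float(v) for v in arr.mean(axis=0)],
        date_range=date_range,
        n_sessions=len(history),
    )
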