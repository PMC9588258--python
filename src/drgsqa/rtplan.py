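"""Arc treatment-plan data model and DICOM RT Plan I/O.

The model keeps only the fields the toolkit's kinematics touch: per
control point the gantry angle (IEC 61217, degrees in [0, 360)), the
cumulative meterset weight, and optionally the MLC leaf positions; per
beam the total meterset (MU) resolved from the fraction group and the
final cumulative weight that normalizes the per-CP weights.  Everything
else in a vendor file is passed through untouched on write.

Reading is tolerant (extra beams, unrelated modules are fine); writing
edits a template in place so that the output differs from the template
only in the elements the plan changed plus fresh instance UIDs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from pydicom.valuerep import format_number_as_ds

from .errors import PlanValidationError, RTPlanFormatError

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"

RotationDirection = Literal["CW", "CC", "NONE"]


def normalize_angle(angle: float) -> float:
    """Map an angle onto the IEC 61217 scale [0, 360); 360 becomes 0."""
    a = float(angle) % 360.0
    return 0.0 if a == 360.0 else a


@dataclass
class ControlPoint:
    """One sampled machine state: gantry angle, cumulative weight, MLC."""

    index: int
    gantry_angle: float
    cumulative_weight: float
    mlc_leaf_positions: np.ndarray | None = None  # shape (2, n_pairs), mm

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ControlPoint):
            return NotImplemented
        if (self.index, self.gantry_angle, self.cumulative_weight) != (
            other.index,
            other.gantry_angle,
            other.cumulative_weight,
        ):
            return False
        a, b = self.mlc_leaf_positions, other.mlc_leaf_positions
        if a is None or b is None:
            return a is None and b is None
        return a.shape == b.shape and bool(np.array_equal(a, b))


@dataclass(eq=True)
class ArcBeam:
    """A beam's CP sequence plus its meterset and weight normalizer."""

    beam_id: str
    beam_meterset: float
    final_cumulative_weight: float
    rotation_direction: RotationDirection
    control_points: list[ControlPoint] = field(default_factory=list)

    @property
    def is_arc(self) -> bool:
        return self.rotation_direction in ("CW", "CC") and len(self.control_points) >= 2

    @property
    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points], dtype=float)

    @property
    def cumulative_weights(self) -> np.ndarray:
        return np.array([cp.cumulative_weight for cp in self.control_points], dtype=float)


@dataclass(eq=True)
class TreatmentPlan:
    """An ordered collection of beams read from one RT Plan file."""

    plan_label: str
    beams: list[ArcBeam] = field(default_factory=list)
    source_path: str = ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TreatmentPlan):
            return NotImplemented
        # provenance (source_path) deliberately excluded from equality
        return self.plan_label == other.plan_label and self.beams == other.beams

    @property
    def total_meterset(self) -> float:
        return float(sum(b.beam_meterset for b in self.beams))

    def arc_beams(self) -> list[ArcBeam]:
        return [b for b in self.beams if b.is_arc]


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    """One invariant violation, located by beam and CP index."""

    beam_id: str
    cp_index: int | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"beam {self.beam_id}"
        if self.cp_index is not None:
            where += f", CP {self.cp_index}"
        return f"{where}: {self.message}"


def validate_plan(plan: TreatmentPlan) -> list[Finding]:
    """Check every modeled invariant; return one finding per violation.

    Findings, not exceptions: a QA tool should report everything wrong
    with a file in one pass.
    """
    findings: list[Finding] = []
    if not plan.beams:
        findings.append(Finding("<plan>", None, "plan has no beams"))
    for beam in plan.beams:
        if beam.beam_meterset <= 0:
            findings.append(Finding(beam.beam_id, None, f"beam meterset {beam.beam_meterset} is not > 0"))
        if beam.final_cumulative_weight <= 0:
            findings.append(
                Finding(beam.beam_id, None, f"final cumulative weight {beam.final_cumulative_weight} is not > 0")
            )
        prev_w: float | None = None
        for cp in beam.control_points:
            if not (0.0 <= cp.gantry_angle < 360.0):
                findings.append(
                    Finding(beam.beam_id, cp.index, f"gantry angle {cp.gantry_angle} outside [0, 360)")
                )
            if prev_w is not None and cp.cumulative_weight < prev_w:
                findings.append(
                    Finding(
                        beam.beam_id,
                        cp.index,
                        f"cumulative weight decreases ({prev_w} -> {cp.cumulative_weight})",
                    )
                )
            prev_w = cp.cumulative_weight
        if beam.control_points and beam.final_cumulative_weight > 0:
            last = beam.control_points[-1].cumulative_weight
            if abs(last - beam.final_cumulative_weight) > 1e-6 * abs(beam.final_cumulative_weight):
                findings.append(
                    Finding(
                        beam.beam_id,
                        len(beam.control_points) - 1,
                        f"last cumulative weight {last} != final {beam.final_cumulative_weight}",
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# DICOM read


def _beam_metersets(ds: Dataset) -> dict[int, float]:
    """Map BeamNumber -> BeamMeterset from the first fraction group."""
    out: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            num = int(rb.ReferencedBeamNumber)
            if "BeamMeterset" in rb:
                out.setdefault(num, float(rb.BeamMeterset))
    return out


def _mlc_positions(cp: Dataset) -> np.ndarray | None:
    for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
            vals = np.asarray([float(v) for v in bld.LeafJawPositions], dtype=float)
            return vals.reshape(2, -1)
    return None


def dataset_to_plan(ds: Dataset, source: str = "") -> TreatmentPlan:
    """Build a :class:`TreatmentPlan` from an in-memory RT Plan dataset."""
    metersets = _beam_metersets(ds)
    beams: list[ArcBeam] = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        beam_id = str(getattr(beam_ds, "BeamName", "") or beam_ds.BeamNumber)
        if "ControlPointSequence" not in beam_ds or len(beam_ds.ControlPointSequence) == 0:
            raise RTPlanFormatError(f"beam {beam_id}: no control point sequence")
        beam_num = int(beam_ds.BeamNumber)
        if beam_num not in metersets:
            raise RTPlanFormatError(f"beam {beam_id}: no referenced beam meterset in fraction group")
        rotation: RotationDirection = "NONE"
        cps: list[ControlPoint] = []
        angle: float | None = None
        mlc: np.ndarray | None = None
        for i, cp_ds in enumerate(beam_ds.ControlPointSequence):
            if "GantryAngle" in cp_ds:
                angle = normalize_angle(float(cp_ds.GantryAngle))
            if angle is None:
                raise RTPlanFormatError(f"beam {beam_id}: CP {i} has no gantry angle")
            if i == 0:
                direction = str(getattr(cp_ds, "GantryRotationDirection", "NONE") or "NONE")
                rotation = direction if direction in ("CW", "CC") else "NONE"
            pos = _mlc_positions(cp_ds)
            if pos is not None:
                mlc = pos
            weight = float(cp_ds.CumulativeMetersetWeight)
            if cps and weight < cps[-1].cumulative_weight:
                raise PlanValidationError(
                    f"beam {beam_id}: cumulative meterset weight decreases at CP {i}"
                )
            cps.append(
                ControlPoint(
                    index=i,
                    gantry_angle=angle,
                    cumulative_weight=weight,
                    mlc_leaf_positions=None if mlc is None else mlc.copy(),
                )
            )
        final = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", cps[-1].cumulative_weight))
        beams.append(
            ArcBeam(
                beam_id=beam_id,
                beam_meterset=metersets[beam_num],
                final_cumulative_weight=final,
                rotation_direction=rotation,
                control_points=cps,
            )
        )
    if not beams:
        raise RTPlanFormatError("RT Plan contains no beams")
    label = str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "RTPlanName", "") or "plan")
    return TreatmentPlan(plan_label=label, beams=beams, source_path=source)


def read_rtplan(path: str | Path) -> TreatmentPlan:
    """Read the modeled fields of a DICOM RT Plan.

    Angles and weights are preserved at stored precision; beams with a
    single CP are retained (they are simply not arcs).
    """
    ds = pydicom.dcmread(str(path))
    return dataset_to_plan(ds, source=str(path))


# ---------------------------------------------------------------------------
# DICOM write


def write_rtplan(plan: TreatmentPlan, template_path: str | Path, out_path: str | Path) -> Path:
    """Write ``plan`` by editing a template RT Plan file.

    Only the referenced beam metersets are rewritten; all other elements
    are carried over from the template verbatim.  A fresh SOP instance
    UID is assigned so the output is a distinct DICOM object.
    """
    ds = pydicom.dcmread(str(template_path))
    tpl_beams = list(getattr(ds, "BeamSequence", []))
    if len(tpl_beams) != len(plan.beams):
        raise RTPlanFormatError(
            f"template has {len(tpl_beams)} beams but plan has {len(plan.beams)}"
        )
    by_number = {int(b.BeamNumber): i for i, b in enumerate(tpl_beams)}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            idx = by_number.get(int(rb.ReferencedBeamNumber))
            if idx is not None and "BeamMeterset" in rb:
                rb.BeamMeterset = format_number_as_ds(float(plan.beams[idx].beam_meterset))
    new_uid = generate_uid()
    ds.SOPInstanceUID = new_uid
    if ds.file_meta is not None:
        ds.file_meta.MediaStorageSOPInstanceUID = new_uid
    out = Path(out_path)
    ds.save_as(str(out), enforce_file_format=True)
    return out


# ---------------------------------------------------------------------------
# building datasets from scratch (used by the synthetic fixture module)


def _ds_num(x: float) -> str:
    """Format a float as a valid DICOM decimal string (<= 16 chars)."""
    return format_number_as_ds(float(x))


def build_rtplan_dataset(plan: TreatmentPlan, *, patient_id: str = "QA") -> pydicom.FileDataset:
    """Serialize a plan to a fresh, self-contained RT Plan dataset.

    Numeric values pass through DICOM decimal-string formatting, so a
    round trip through :func:`dataset_to_plan` is exact.
    """
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RTPLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.PatientName = patient_id
    ds.PatientID = patient_id
    ds.RTPlanLabel = plan.plan_label
    ds.RTPlanGeometry = "TREATMENT_DEVICE"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()

    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.NumberOfBeams = len(plan.beams)
    fg.ReferencedBeamSequence = []
    ds.FractionGroupSequence = [fg]
    ds.BeamSequence = []

    for num, beam in enumerate(plan.beams, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = num
        rb.BeamMeterset = _ds_num(beam.beam_meterset)
        fg.ReferencedBeamSequence.append(rb)

        b = Dataset()
        b.BeamNumber = num
        b.BeamName = beam.beam_id
        b.BeamType = "DYNAMIC" if beam.is_arc else "STATIC"
        b.RadiationType = "PHOTON"
        b.TreatmentDeliveryType = "TREATMENT"
        b.NumberOfControlPoints = len(beam.control_points)
        b.FinalCumulativeMetersetWeight = _ds_num(beam.final_cumulative_weight)
        b.ControlPointSequence = []
        for cp in beam.control_points:
            c = Dataset()
            c.ControlPointIndex = cp.index
            c.GantryAngle = _ds_num(cp.gantry_angle)
            c.CumulativeMetersetWeight = _ds_num(cp.cumulative_weight)
            if cp.index == 0:
                c.GantryRotationDirection = beam.rotation_direction
            if cp.mlc_leaf_positions is not None:
                bld = Dataset()
                bld.RTBeamLimitingDeviceType = "MLCX"
                bld.LeafJawPositions = [_ds_num(v) for v in cp.mlc_leaf_positions.ravel()]
                c.BeamLimitingDevicePositionSequence = [bld]
            b.ControlPointSequence.append(c)
        ds.BeamSequence.append(b)
    return ds


def quantize_plan(plan: TreatmentPlan) -> TreatmentPlan:
    """Pass all numeric fields through DICOM decimal-string precision.

    Fixture generators call this once at construction so that the plans
    they return are bit-identical to what a write->read cycle produces.
    """
    out = copy.deepcopy(plan)
    for beam in out.beams:
        beam.beam_meterset = float(_ds_num(beam.beam_meterset))
        beam.final_cumulative_weight = float(_ds_num(beam.final_cumulative_weight))
        for cp in beam.control_points:
            cp.gantry_angle = float(_ds_num(cp.gantry_angle))
            cp.cumulative_weight = float(_ds_num(cp.cumulative_weight))
            if cp.mlc_leaf_positions is not None:
                cp.mlc_leaf_positions = np.array(
                    [[float(_ds_num(v)) for v in row] for row in cp.mlc_leaf_positions]
                )
    return out


def write_new_rtplan(plan: TreatmentPlan, out_path: str | Path, *, patient_id: str = "QA") -> Path:
    """Write a plan as a fresh file (no template), e.g. a fixture plan."""
    ds = build_rtplan_dataset(plan, patient_id=patient_id)
    out = Path(out_path)
    ds.save_as(str(out), enforce_file_format=True)
    return out
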