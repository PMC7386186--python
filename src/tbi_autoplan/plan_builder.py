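"""Automated TBI plan construction against a mock treatment-planning data model.

Mirrors the scripted plan-building workflow: add a 40 cm water phantom with a
body contour, create a date-based course/plan name (suffixing on collision),
insert reference points with prescription-derived dose limits, add the static
TOTAL-technique fields with preset gantry angles, and set each field's MU by
inverting the plan-normalization / field-weight algebra of the planning
system.  The volumetric dose engine is replaced by :class:`MockDoseState`
with an explicit forward model — in the clinical workflow that dose
distribution is a placeholder and irrelevant for treatment; the inversion
algebra is the content worth testing.

Plans serialize losslessly to JSON and minimally to DICOM-RT (see
:func:`export_plan` for the tag mapping).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

from .mu_calc import CalcResult, Prescription, round_half_up


class PlanError(Exception):
    pass


class ConfigurationError(PlanError):
    pass


class UnattainableTargetError(PlanError):
    """Requested field MU cannot be reached within weight/normalization bounds."""


#: Per-arrangement field names and gantry angles (degrees).  Supplied as
#: configuration because clinics differ; validated, not hard-coded, in
#: :func:`build_plan`.
DEFAULT_GEOMETRY_PRESETS: dict[str, list[tuple[str, float]]] = {
    "AP/PA": [("AP", 270.0), ("PA", 90.0)],
    "RLat/LLat": [("RLat", 270.0), ("LLat", 90.0)],
}

#: Isocenter convention at extended SSD, recorded (not asserted) in the plan.
DEFAULT_ISOCENTER_CONVENTION = "phantom-center-at-500cm-SSD"

TECHNIQUE = "TOTAL"
WEIGHT_BOUNDS = (1e-3, 1.0)
NORMALIZATION_BOUNDS = (0.1, 1000.0)  # percent


@dataclass(frozen=True)
class PhantomSpec:
    """Cubic water phantom stand-in for the un-imaged patient."""

    side_cm: float = 40.0
    has_body_contour: bool = True


@dataclass(frozen=True)
class ReferencePoint:
    name: str
    session_limit: float  # cGy
    daily_limit: float  # cGy
    total_limit: float  # cGy

    def __post_init__(self) -> None:
        if not self.session_limit <= self.daily_limit <= self.total_limit:
            raise PlanError("reference point limits must be session <= daily <= total")


@dataclass(frozen=True)
class TreatmentField:
    name: str
    gantry: float  # degrees
    field_size: tuple[float, float]  # cm x cm collimator setting
    ssd: float  # cm
    energy: str
    mu: int
    dose_rate: float  # MU/min
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.mu < 1:
            raise PlanError(f"field {self.name}: MU must be >= 1")


@dataclass
class TbiPlan:
    course_name: str
    plan_name: str
    phantom: PhantomSpec
    reference_points: list[ReferencePoint]
    fields: list[TreatmentField]
    normalization: float  # percent
    created: _dt.date
    patient_id: str = ""
    patient_name: str = ""
    technique: str = TECHNIQUE
    isocenter_convention: str = DEFAULT_ISOCENTER_CONVENTION
    beam_data_version: str = ""

    def __post_init__(self) -> None:
        if not self.fields:
            raise PlanError("plan must contain at least one field")

    def to_dict(self) -> dict:
        return {
            "course_name": self.course_name,
            "plan_name": self.plan_name,
            "phantom": {"side_cm": self.phantom.side_cm,
                        "has_body_contour": self.phantom.has_body_contour},
            "reference_points": [
                {"name": rp.name, "session_limit": rp.session_limit,
                 "daily_limit": rp.daily_limit, "total_limit": rp.total_limit}
                for rp in self.reference_points
            ],
            "fields": [
                {"name": f.name, "gantry": f.gantry, "field_size": list(f.field_size),
                 "ssd": f.ssd, "energy": f.energy, "mu": f.mu,
                 "dose_rate": f.dose_rate, "weight": f.weight}
                for f in self.fields
            ],
            "normalization": self.normalization,
            "created": self.created.isoformat(),
            "patient_id": self.patient_id,
            "patient_name": self.patient_name,
            "technique": self.technique,
            "isocenter_convention": self.isocenter_convention,
            "beam_data_version": self.beam_data_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TbiPlan":
        return cls(
            course_name=d["course_name"],
            plan_name=d["plan_name"],
            phantom=PhantomSpec(d["phantom"]["side_cm"], d["phantom"]["has_body_contour"]),
            reference_points=[ReferencePoint(**rp) for rp in d["reference_points"]],
            fields=[
                TreatmentField(
                    name=f["name"], gantry=f["gantry"],
                    field_size=tuple(f["field_size"]), ssd=f["ssd"],
                    energy=f["energy"], mu=int(f["mu"]),
                    dose_rate=f["dose_rate"], weight=f["weight"],
                )
                for f in d["fields"]
            ],
            normalization=d["normalization"],
            created=_dt.date.fromisoformat(d["created"]),
            patient_id=d.get("patient_id", ""),
            patient_name=d.get("patient_name", ""),
            technique=d.get("technique", TECHNIQUE),
            isocenter_convention=d.get("isocenter_convention", DEFAULT_ISOCENTER_CONVENTION),
            beam_data_version=d.get("beam_data_version", ""),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TbiPlan):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def make_plan_name(today: _dt.date, existing_names: set[str]) -> str:
    """Date-based plan name, ``TBI_MM-YYYY``, suffixed ``-k`` on collision.

    The suffix is the smallest positive integer not already taken, so
    repeated same-day runs never collide.
    """
    base = f"TBI_{today.month:02d}-{today.year:04d}"
    if base not in existing_names:
        return base
    k = 1
    while f"{base}-{k}" in existing_names:
        k += 1
    return f"{base}-{k}"


@dataclass
class MockDoseState:
    """Placeholder dose engine: base MU delivered per field at weight 1, 100%.

    Forward model: ``delivered_mu[i] = base_mu[i] * weight[i] * 100 / normalization``.
    """

    base_mu: list[float]

    def __post_init__(self) -> None:
        if not self.base_mu or any(b <= 0 for b in self.base_mu):
            raise PlanError("base MU values must be positive")

    def delivered_mu(self, normalization: float, weights: list[float]) -> list[float]:
        if len(weights) != len(self.base_mu):
            raise PlanError("one weight per field required")
        return [b * w * 100.0 / normalization for b, w in zip(self.base_mu, weights)]


def set_field_mu(
    state: MockDoseState, targets: list[int]
) -> tuple[float, list[float]]:
    """Invert the normalization/weight model so every field hits its target MU.

    The largest weight is pinned to 1 and the plan normalization absorbs the
    overall scale: ``normalization = min_i 100 * base_mu[i] / target[i]``,
    ``weight[i] = target[i] * normalization / (100 * base_mu[i])``.  Raises
    :class:`UnattainableTargetError` if that solution leaves the bounds.
    """
    if len(targets) != len(state.base_mu):
        raise PlanError("one target per field required")
    if any(t < 1 for t in targets):
        raise UnattainableTargetError("target MU must be >= 1")
    ratios = [t / b for b, t in zip(state.base_mu, targets)]
    peak = max(ratios)
    normalization = 100.0 / peak
    weights = [r / peak for r in ratios]  # the largest is exactly 1.0
    lo_n, hi_n = NORMALIZATION_BOUNDS
    if not lo_n <= normalization <= hi_n:
        raise UnattainableTargetError(
            f"required normalization {normalization:.3g}% outside [{lo_n}, {hi_n}]"
        )
    lo_w, hi_w = WEIGHT_BOUNDS
    if any(not lo_w <= w <= hi_w for w in weights):
        raise UnattainableTargetError("required field weight outside bounds")
    return normalization, weights


def build_plan(
    prescription: Prescription,
    calc: CalcResult,
    geometry_presets: dict[str, list[tuple[str, float]]] | None = None,
    today: _dt.date | None = None,
    existing: set[str] | None = None,
) -> TbiPlan:
    """Construct the complete plan from a prescription and its calculation.

    Pure construction: neither input is mutated, and the same inputs always
    produce the same plan (dates are injected, never read from the clock
    inside the logic — ``today`` defaults to the current date only at the
    call boundary).
    """
    presets = geometry_presets if geometry_presets is not None else DEFAULT_GEOMETRY_PRESETS
    today = today or _dt.date.today()
    existing = existing or set()
    if prescription.arrangement not in presets:
        raise ConfigurationError(
            f"no geometry preset for arrangement {prescription.arrangement!r}"
        )
    field_specs = presets[prescription.arrangement]

    name = make_plan_name(today, existing)

    # Equally weighted opposed fields: every field carries the same MU.
    targets = [calc.mu_per_field] * len(field_specs)
    # Placeholder low-resolution dose: 100 MU per field at weight 1, 100%.
    state = MockDoseState(base_mu=[100.0] * len(field_specs))
    normalization, weights = set_field_mu(state, targets)

    fields = [
        TreatmentField(
            name=fname,
            gantry=gantry,
            field_size=(40.0, 40.0),
            ssd=calc.distance_to_point - calc.depth,
            energy=calc.energy,
            mu=calc.mu_per_field,
            dose_rate=calc.machine_dose_rate,
            weight=w,
        )
        for (fname, gantry), w in zip(field_specs, weights)
    ]

    daily = prescription.dose_per_field * len(field_specs)
    ref_points = [
        ReferencePoint(
            name="TBI midplane",
            session_limit=daily,
            daily_limit=daily,
            total_limit=daily * prescription.num_fractions,
        )
    ]

    return TbiPlan(
        course_name=name,
        plan_name=name,
        phantom=PhantomSpec(),
        reference_points=ref_points,
        fields=fields,
        normalization=normalization,
        created=today,
        patient_id=prescription.patient_id,
        patient_name=prescription.patient_name,
        beam_data_version=calc.beam_data_version,
    )


# ---------------------------------------------------------------------------
# export / import

RT_PLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


def export_plan(plan: TbiPlan, path: str | Path, format: str = "json") -> Path:
    """Write the plan to ``path`` as JSON (lossless) or DICOM-RT (minimal).

    DICOM mapping: one BeamSequence item per field (BeamName, gantry angle
    and nominal energy in a single control point, RadiationType PHOTON) and
    per-beam meterset in FractionGroupSequence/ReferencedBeamSequence
    (BeamMeterset = MU).  The plan name goes to RTPlanLabel, the technique
    tag to BeamDescription.  UIDs are derived from the plan content so export
    is deterministic.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(plan.to_dict(), sort_keys=True, indent=2) + "\n")
        return path
    if format == "dicom-rt":
        _write_dicom(plan, path)
        return path
    raise PlanError(f"unknown export format {format!r}")


def import_plan(path: str | Path, format: str = "json") -> TbiPlan:
    """Read back an exported plan (JSON is lossless; DICOM recovers the beams)."""
    path = Path(path)
    if format == "json":
        return TbiPlan.from_dict(json.loads(path.read_text()))
    if format == "dicom-rt":
        return _read_dicom(path)
    raise PlanError(f"unknown import format {format!r}")


def _content_uid(plan: TbiPlan, suffix: str) -> str:
    import hashlib

    import pydicom.uid

    digest = hashlib.sha256(
        (json.dumps(plan.to_dict(), sort_keys=True) + suffix).encode()
    ).hexdigest()
    return pydicom.uid.generate_uid(entropy_srcs=[digest])


def _write_dicom(plan: TbiPlan, path: Path) -> None:
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_PLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = _content_uid(plan, "sop")
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_PLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_name[:16]
    ds.RTPlanName = plan.plan_name
    ds.RTPlanDate = plan.created.strftime("%Y%m%d")
    ds.PatientID = plan.patient_id
    ds.PatientName = plan.patient_name
    ds.SeriesInstanceUID = _content_uid(plan, "series")
    ds.StudyInstanceUID = _content_uid(plan, "study")

    beam_seq = []
    ref_beam_seq = []
    for i, f in enumerate(plan.fields, start=1):
        beam = Dataset()
        beam.BeamNumber = i
        beam.BeamName = f.name
        beam.BeamDescription = plan.technique
        beam.BeamType = "STATIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentMachineName = "TBI-LINAC"
        beam.NumberOfControlPoints = 1
        cp = Dataset()
        cp.ControlPointIndex = 0
        cp.GantryAngle = f.gantry
        cp.NominalBeamEnergy = float(f.energy.rstrip("X"))
        cp.DoseRateSet = f.dose_rate
        beam.ControlPointSequence = [cp]
        beam_seq.append(beam)

        ref = Dataset()
        ref.ReferencedBeamNumber = i
        ref.BeamMeterset = float(f.mu)
        ref_beam_seq.append(ref)

    ds.BeamSequence = beam_seq
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfBeams = len(plan.fields)
    fg.ReferencedBeamSequence = ref_beam_seq
    ds.FractionGroupSequence = [fg]

    pydicom.dcmwrite(path, ds, enforce_file_format=True)


def _read_dicom(path: Path) -> TbiPlan:
    """Recover a TbiPlan skeleton from a minimal RT Plan file.

    Only what DICOM carries comes back (beams, MU, gantry, names); reference
    points, phantom and weights take defaults.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    mu_by_beam = {
        int(r.ReferencedBeamNumber): float(r.BeamMeterset)
        for fg in ds.FractionGroupSequence
        for r in fg.ReferencedBeamSequence
    }
    fields = []
    for beam in ds.BeamSequence:
        cp = beam.ControlPointSequence[0]
        fields.append(
            TreatmentField(
                name=str(beam.BeamName),
                gantry=float(cp.GantryAngle),
                field_size=(40.0, 40.0),
                ssd=500.0,
                energy=f"{int(cp.NominalBeamEnergy)}X",
                mu=int(round_half_up(mu_by_beam[int(beam.BeamNumber)])),
                dose_rate=float(cp.DoseRateSet),
            )
        )
    daily = 1.0
    return TbiPlan(
        course_name=str(ds.RTPlanName),
        plan_name=str(ds.RTPlanName),
        phantom=PhantomSpec(),
        reference_points=[ReferencePoint("TBI midplane", daily, daily, daily)],
        fields=fields,
        normalization=100.0,
        created=_dt.datetime.strptime(str(ds.RTPlanDate), "%Y%m%d").date(),
        patient_id=str(ds.PatientID),
        patient_name=str(ds.PatientName),
    )
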