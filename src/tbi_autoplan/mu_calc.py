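"""Monitor-unit and dose-rate hand calculation for extended-SSD TBI.

The prescription point is the patient midplane: depth = separation / 2 and
source-to-point distance = treatment SSD + separation / 2.  Dose per MU at
that point is the product of six factors,

    dose_per_mu = ISF * Sc * Sp * TMR(depth) * spoiler * water_to_muscle

with ISF = (cal_distance / (SSD + separation/2))^2 referenced to the 100 cm
calibration distance.  MU per field is the prescribed dose per field divided
by dose_per_mu, rounded half-up to an integer.  The machine dose-rate setting
is the largest deliverable rate whose instantaneous dose rate at the
prescription point stays within the prescription's limit (TG-29 style,
typically 10 cGy/min).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .beam_data import BeamDataSet, MachineGeometry, interpolate_factor, select_energy


class CalcError(Exception):
    """Base class for calculation failures."""


class DomainError(CalcError):
    """An input is outside its physical domain."""


class CalculationRefusedError(CalcError):
    """Result failed a sanity gate and was withheld rather than emitted."""


class NoFeasibleRateError(CalcError):
    """Even the slowest deliverable machine rate exceeds the dose-rate limit."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal, spreadsheet style."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


ARRANGEMENTS = ("AP/PA", "RLat/LLat")


@dataclass(frozen=True)
class ProtocolLimits:
    """Per-protocol clinical bounds used by prescription validation."""

    dose_rate_ceiling: float  # cGy/min at the prescription point
    dose_per_field: tuple[float, float]  # cGy
    separation: tuple[float, float]  # cm
    age_class: str  # "adult" | "pediatric"
    max_fractions: int = 16


#: Default protocol registry.  The instantaneous dose-rate ceiling is
#: 10 cGy/min for the standard protocols and 15 cGy/min for the high-rate
#: single-dose adult regimen.
DEFAULT_PROTOCOLS: dict[str, ProtocolLimits] = {
    "standard_adult": ProtocolLimits(10.0, (100.0, 300.0), (18.0, 60.0), "adult"),
    "standard_pediatric": ProtocolLimits(10.0, (50.0, 200.0), (8.0, 28.0), "pediatric"),
    "single_dose_adult": ProtocolLimits(15.0, (200.0, 600.0), (18.0, 60.0), "adult", 2),
}


@dataclass(frozen=True)
class Prescription:
    """The physician's order for one TBI course."""

    protocol: str
    dose_per_field: float  # cGy
    num_fractions: int
    separation: float  # cm
    max_dose_rate: float  # cGy/min
    arrangement: str  # "AP/PA" or "RLat/LLat"
    patient_id: str = ""
    patient_name: str = ""

    def __post_init__(self) -> None:
        if self.dose_per_field <= 0:
            raise DomainError("dose_per_field must be > 0")
        if self.num_fractions < 1:
            raise DomainError("num_fractions must be >= 1")
        if self.separation <= 0:
            raise DomainError("separation must be > 0")
        if self.max_dose_rate <= 0:
            raise DomainError("max_dose_rate must be > 0")
        if self.arrangement not in ARRANGEMENTS:
            raise DomainError(f"arrangement must be one of {ARRANGEMENTS}")

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "dose_per_field": self.dose_per_field,
            "num_fractions": self.num_fractions,
            "separation": self.separation,
            "max_dose_rate": self.max_dose_rate,
            "arrangement": self.arrangement,
            "patient_id": self.patient_id,
            "patient_name": self.patient_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prescription":
        return cls(
            protocol=str(d["protocol"]),
            dose_per_field=float(d["dose_per_field"]),
            num_fractions=int(d["num_fractions"]),
            separation=float(d["separation"]),
            max_dose_rate=float(d["max_dose_rate"]),
            arrangement=str(d["arrangement"]),
            patient_id=str(d.get("patient_id", "")),
            patient_name=str(d.get("patient_name", "")),
        )


def load_prescription(path) -> Prescription:
    """Read a prescription from a YAML or JSON document."""
    import yaml

    with open(path) as fh:
        return Prescription.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class CalcOptions:
    """Knobs that the clinic, not the physics, decides.

    ``sc_equivalent_square`` / ``sp_equivalent_square`` override the
    equivalent-square side (cm) at which the collimator and phantom scatter
    factors are looked up; by default both use the collimator setting
    (treatment_field).  ``mu_cap`` refuses absurd MU results outright rather
    than emitting them.
    """

    sc_equivalent_square: float | None = None
    sp_equivalent_square: float | None = None
    mu_cap: int = 30000
    rate_tolerance: float = 1e-9  # relative slack on the dose-rate inequality


@dataclass(frozen=True)
class FactorBreakdown:
    """The six multiplicative factors and their product (the audit trail)."""

    isf: float
    sc: float
    sp: float
    tmr: float
    spoiler: float
    muscle: float
    dose_per_mu: float  # cGy/MU

    def __post_init__(self) -> None:
        parts = (self.isf, self.sc, self.sp, self.tmr, self.spoiler, self.muscle)
        if any(f <= 0 for f in parts):
            raise DomainError("all factors must be > 0")
        prod = 1.0
        for f in parts:
            prod *= f
        if abs(self.dose_per_mu - prod) > 1e-12 * prod:
            raise DomainError("dose_per_mu is not the product of its factors")

    def to_dict(self) -> dict:
        return {
            "isf": self.isf,
            "sc": self.sc,
            "sp": self.sp,
            "tmr": self.tmr,
            "spoiler": self.spoiler,
            "muscle": self.muscle,
            "dose_per_mu": self.dose_per_mu,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorBreakdown":
        return cls(**{k: float(d[k]) for k in
                      ("isf", "sc", "sp", "tmr", "spoiler", "muscle", "dose_per_mu")})


@dataclass(frozen=True)
class CalcResult:
    """Complete hand-calculation output for one field of the arrangement."""

    energy: str
    depth: float  # cm, midplane
    distance_to_point: float  # cm
    factors: FactorBreakdown
    mu_per_field: int
    machine_dose_rate: float  # MU/min, member of the deliverable ladder
    achieved_dose_rate: float  # cGy/min at the prescription point
    beam_data_version: str
    beam_data_checksum: str = ""

    def to_dict(self) -> dict:
        return {
            "energy": self.energy,
            "depth": self.depth,
            "distance_to_point": self.distance_to_point,
            "factors": self.factors.to_dict(),
            "mu_per_field": self.mu_per_field,
            "machine_dose_rate": self.machine_dose_rate,
            "achieved_dose_rate": self.achieved_dose_rate,
            "beam_data_version": self.beam_data_version,
            "beam_data_checksum": self.beam_data_checksum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalcResult":
        return cls(
            energy=str(d["energy"]),
            depth=float(d["depth"]),
            distance_to_point=float(d["distance_to_point"]),
            factors=FactorBreakdown.from_dict(d["factors"]),
            mu_per_field=int(d["mu_per_field"]),
            machine_dose_rate=float(d["machine_dose_rate"]),
            achieved_dose_rate=float(d["achieved_dose_rate"]),
            beam_data_version=str(d["beam_data_version"]),
            beam_data_checksum=str(d.get("beam_data_checksum", "")),
        )


def inverse_square_factor(geometry: MachineGeometry, separation: float) -> float:
    """(cal_distance / (treatment_ssd + separation/2))**2."""
    if separation < 0:
        raise DomainError("separation must be >= 0")
    return (geometry.cal_distance / (geometry.treatment_ssd + separation / 2.0)) ** 2


def dose_per_mu(
    data: BeamDataSet,
    prescription: Prescription,
    options: CalcOptions = CalcOptions(),
) -> FactorBreakdown:
    """Assemble the six-factor breakdown for the prescription's midplane point."""
    energy = select_energy(data, prescription.separation)
    depth = prescription.separation / 2.0
    geom = data.geometry
    sc_sq = options.sc_equivalent_square or geom.treatment_field
    sp_sq = options.sp_equivalent_square or geom.treatment_field
    isf = inverse_square_factor(geom, prescription.separation)
    sc = interpolate_factor(data, energy, "Sc", sc_sq)
    sp = interpolate_factor(data, energy, "Sp", sp_sq)
    tmr = interpolate_factor(data, energy, "TMR", depth)
    spoiler = interpolate_factor(data, energy, "spoiler", 0.0)
    muscle = geom.water_to_muscle
    return FactorBreakdown(
        isf=isf, sc=sc, sp=sp, tmr=tmr, spoiler=spoiler, muscle=muscle,
        dose_per_mu=isf * sc * sp * tmr * spoiler * muscle,
    )


def compute_dose_rate(
    data: BeamDataSet,
    prescription: Prescription,
    factors: FactorBreakdown,
    options: CalcOptions = CalcOptions(),
) -> tuple[float, float]:
    """Largest deliverable machine rate within the prescription's limit.

    Returns ``(machine_rate MU/min, achieved cGy/min)``; the inequality
    ``rate * dose_per_mu <= max_dose_rate`` is inclusive (a rate that lands
    exactly on the limit is allowed).
    """
    limit = prescription.max_dose_rate * (1.0 + options.rate_tolerance)
    feasible = [r for r in data.dose_rates if r * factors.dose_per_mu <= limit]
    if not feasible:
        raise NoFeasibleRateError(
            f"slowest machine rate {data.dose_rates[0]} MU/min gives "
            f"{data.dose_rates[0] * factors.dose_per_mu:.2f} cGy/min "
            f"> limit {prescription.max_dose_rate} cGy/min"
        )
    rate = max(feasible)
    return rate, rate * factors.dose_per_mu


def compute_mu(
    data: BeamDataSet,
    prescription: Prescription,
    options: CalcOptions = CalcOptions(),
) -> CalcResult:
    """Full hand calculation: MU per field, machine dose rate, factor audit trail."""
    factors = dose_per_mu(data, prescription, options)
    raw_mu = prescription.dose_per_field / factors.dose_per_mu
    mu = int(round_half_up(raw_mu))
    if mu < 1:
        raise CalculationRefusedError(f"MU rounds to {mu}; prescription implausible")
    if mu > options.mu_cap:
        raise CalculationRefusedError(
            f"computed {mu} MU exceeds sanity cap {options.mu_cap}"
        )
    rate, achieved = compute_dose_rate(data, prescription, factors, options)
    return CalcResult(
        energy=select_energy(data, prescription.separation),
        depth=prescription.separation / 2.0,
        distance_to_point=data.geometry.treatment_ssd + prescription.separation / 2.0,
        factors=factors,
        mu_per_field=mu,
        machine_dose_rate=rate,
        achieved_dose_rate=achieved,
        beam_data_version=data.version,
        beam_data_checksum=data.checksum,
    )


@dataclass(frozen=True)
class Finding:
    """One machine-readable validation finding."""

    severity: str  # "info" | "warn" | "block"
    field: str
    message: str

    def to_dict(self) -> dict:
        return {"severity": self.severity, "field": self.field, "message": self.message}


def validate_prescription(
    prescription: Prescription,
    protocol_registry: dict[str, ProtocolLimits] = DEFAULT_PROTOCOLS,
) -> list[Finding]:
    """Check a prescription against its protocol's clinical bounds.

    Returns an empty list when consistent.  Parameters that fall in another
    protocol's characteristic range (an adult order with pediatric-range
    values, say) produce ``block`` findings: that is the wrong-worksheet
    error mode, with potential for mistreatment if not caught.
    """
    if prescription.protocol not in protocol_registry:
        raise KeyError(f"unknown protocol {prescription.protocol!r}")
    limits = protocol_registry[prescription.protocol]
    findings: list[Finding] = []

    lo, hi = limits.dose_per_field
    if not lo <= prescription.dose_per_field <= hi:
        findings.append(Finding(
            "block", "dose_per_field",
            f"{prescription.dose_per_field} cGy outside protocol range [{lo}, {hi}]",
        ))
    lo, hi = limits.separation
    if not lo <= prescription.separation <= hi:
        findings.append(Finding(
            "block", "separation",
            f"{prescription.separation} cm outside protocol range [{lo}, {hi}]"
            f" — check for a wrong-protocol ({limits.age_class}) calculation",
        ))
    if prescription.max_dose_rate > limits.dose_rate_ceiling:
        findings.append(Finding(
            "block", "max_dose_rate",
            f"{prescription.max_dose_rate} cGy/min exceeds protocol ceiling "
            f"{limits.dose_rate_ceiling} cGy/min",
        ))
    if prescription.num_fractions > limits.max_fractions:
        findings.append(Finding(
            "warn", "num_fractions",
            f"{prescription.num_fractions} fractions exceeds the usual "
            f"{limits.max_fractions} for this protocol",
        ))
    return findings
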