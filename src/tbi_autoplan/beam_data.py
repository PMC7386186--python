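"""Machine beam-data tables for extended-SSD total body irradiation.

The MU hand calculation draws every machine/technique factor from commissioned
look-up tables: tissue-maximum ratio (TMR) versus depth, collimator factor Sc
and phantom scatter factor Sp versus equivalent-square side, a per-energy beam
spoiler factor, a patient-separation-to-energy selection table, and the
discrete ladder of deliverable machine dose rates.  This module defines those
containers, validates them, interpolates them (piecewise linear, never
extrapolating), and can synthesize a physically plausible seeded fixture set
for testing and demos.

File format: one YAML master file (geometry, energy selection, dose rates,
version, checksum) referencing one two-column CSV per factor table
(``abscissa,value``).  The checksum is a SHA-256 over the canonical JSON form
of everything else and is verified on load, so a silently edited table cannot
be used for a calculation.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

TABLE_KINDS = ("TMR", "Sc", "Sp", "spoiler")


class BeamDataError(Exception):
    """Base class for beam-data problems."""


class SchemaError(BeamDataError):
    """The file is structurally invalid; the message names the offending field."""


class ValidationError(BeamDataError):
    """The data violate a physics/monotonicity invariant."""


class OutOfRangeError(BeamDataError):
    """Requested abscissa lies outside the tabulated range (no extrapolation)."""


class ChecksumError(BeamDataError):
    """Stored checksum does not match the recomputed one."""


@dataclass(frozen=True)
class MachineGeometry:
    """Calibration and treatment geometry of the extended-SSD technique.

    Dose is calibrated at ``cal_distance`` (cm) with a ``cal_field`` cm square
    field; treatment uses a ``treatment_field`` cm square collimator at
    ``treatment_ssd`` cm.  ``water_to_muscle`` is the dose-to-water to
    dose-to-muscle conversion applied to every calculation.
    """

    treatment_ssd: float = 500.0
    cal_distance: float = 100.0
    cal_field: float = 10.0
    treatment_field: float = 40.0
    water_to_muscle: float = 0.99

    def __post_init__(self) -> None:
        for name in ("treatment_ssd", "cal_distance", "cal_field", "treatment_field"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"geometry.{name} must be > 0")
        if self.treatment_ssd <= self.cal_distance:
            raise ValidationError("geometry.treatment_ssd must exceed cal_distance")
        if not 0 < self.water_to_muscle <= 1:
            raise ValidationError("geometry.water_to_muscle must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "treatment_ssd": self.treatment_ssd,
            "cal_distance": self.cal_distance,
            "cal_field": self.cal_field,
            "treatment_field": self.treatment_field,
            "water_to_muscle": self.water_to_muscle,
        }


@dataclass(frozen=True)
class FactorTable:
    """One tabulated dimensionless factor for one energy.

    ``abscissa`` is depth in cm for TMR, equivalent-square side in cm for
    Sc/Sp; the spoiler factor is a scalar stored as a single-knot table.
    """

    energy: str
    kind: str
    abscissa: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise SchemaError(f"table kind {self.kind!r} not one of {TABLE_KINDS}")
        if len(self.abscissa) != len(self.values):
            raise ValidationError(
                f"{self.energy}/{self.kind}: abscissa and values differ in length"
            )
        if not self.abscissa:
            raise ValidationError(f"{self.energy}/{self.kind}: empty table")
        if any(b <= a for a, b in zip(self.abscissa, self.abscissa[1:])):
            raise ValidationError(
                f"{self.energy}/{self.kind}: abscissa not strictly increasing"
            )
        if any(v <= 0 for v in self.values):
            raise ValidationError(f"{self.energy}/{self.kind}: non-positive value")
        if self.kind == "TMR" and any(v > 1.2 for v in self.values):
            raise ValidationError(f"{self.energy}/TMR: value exceeds 1.2")


@dataclass(frozen=True)
class EnergySelectionTable:
    """Half-open separation intervals [sep_min, sep_max) mapped to energies.

    Intervals must be contiguous and non-overlapping so selection is a total
    function on the covered range; the boundary point belongs to the upper
    interval.
    """

    rows: tuple[tuple[float, float, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("energy_selection: no rows")
        rows = sorted(self.rows, key=lambda r: r[0])
        for lo, hi, _ in rows:
            if hi <= lo:
                raise ValidationError("energy_selection: empty interval")
        for (_, hi, _), (lo2, _, _) in zip(rows, rows[1:]):
            if lo2 != hi:
                raise ValidationError(
                    "energy_selection: intervals must be contiguous and non-overlapping"
                )
        object.__setattr__(self, "rows", tuple(rows))

    @property
    def covered_range(self) -> tuple[float, float]:
        return self.rows[0][0], self.rows[-1][1]

    def energies(self) -> list[str]:
        out: list[str] = []
        for _, _, e in self.rows:
            if e not in out:
                out.append(e)
        return out


@dataclass
class BeamDataSet:
    """Validated collection of machine data for the TBI technique."""

    geometry: MachineGeometry
    tables: dict[tuple[str, str], FactorTable]
    energy_selection: EnergySelectionTable
    dose_rates: tuple[float, ...]
    version: str = "unversioned"
    checksum: str = field(default="")

    def __post_init__(self) -> None:
        self.dose_rates = tuple(float(r) for r in self.dose_rates)
        if not self.dose_rates:
            raise ValidationError("dose_rates: empty ladder")
        if any(r <= 0 for r in self.dose_rates):
            raise ValidationError("dose_rates: non-positive rate")
        if any(b <= a for a, b in zip(self.dose_rates, self.dose_rates[1:])):
            raise ValidationError("dose_rates: not strictly increasing")
        for energy in self.energy_selection.energies():
            for kind in TABLE_KINDS:
                if (energy, kind) not in self.tables:
                    raise ValidationError(
                        f"tables: energy {energy!r} missing {kind} table"
                    )
        if not self.checksum:
            self.checksum = self.compute_checksum()

    def _canonical(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "tables": [
                {
                    "energy": t.energy,
                    "kind": t.kind,
                    "abscissa": list(t.abscissa),
                    "values": list(t.values),
                }
                for t in sorted(self.tables.values(), key=lambda t: (t.energy, t.kind))
            ],
            "energy_selection": [list(r) for r in self.energy_selection.rows],
            "dose_rates": list(self.dose_rates),
            "version": self.version,
        }

    def compute_checksum(self) -> str:
        blob = json.dumps(self._canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def energies(self) -> list[str]:
        return self.energy_selection.energies()

    def __eq__(self, other: object) -> bool:  # value equality for round-trip tests
        if not isinstance(other, BeamDataSet):
            return NotImplemented
        return self._canonical() == other._canonical()


def interpolate_factor(data: BeamDataSet, energy: str, kind: str, x: float) -> float:
    """Piecewise-linear interpolation of a factor table; exact at knots.

    No extrapolation: an ``x`` outside the tabulated range raises
    :class:`OutOfRangeError` rather than returning a silently wrong factor.
    Spoiler tables are scalar; ``x`` is ignored for them.
    """
    try:
        table = data.tables[(energy, kind)]
    except KeyError:
        raise SchemaError(f"no {kind} table for energy {energy!r}") from None
    if kind == "spoiler" or len(table.abscissa) == 1:
        return table.values[0]
    lo, hi = table.abscissa[0], table.abscissa[-1]
    if not lo <= x <= hi:
        raise OutOfRangeError(
            f"{energy}/{kind}: abscissa {x} outside tabulated range [{lo}, {hi}]"
        )
    return float(np.interp(x, table.abscissa, table.values))


def select_energy(data: BeamDataSet, separation: float) -> str:
    """Pick the beam energy whose half-open separation interval contains the patient."""
    for lo, hi, energy in data.energy_selection.rows:
        if lo <= separation < hi:
            return energy
    lo, hi = data.energy_selection.covered_range
    raise OutOfRangeError(
        f"separation {separation} cm outside supported range [{lo}, {hi}) cm"
    )


# ---------------------------------------------------------------------------
# serialization

def save_beam_data(data: BeamDataSet, path: str | Path) -> Path:
    """Write the master YAML plus one CSV per factor table next to it.

    ``path`` is the master YAML file; CSVs are written in the same directory
    as ``<energy>_<kind>.csv``.  Returns the master path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table_entries = []
    for tab in sorted(data.tables.values(), key=lambda t: (t.energy, t.kind)):
        fname = f"{tab.energy}_{tab.kind}.csv"
        with open(path.parent / fname, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["abscissa", "value"])
            for a, v in zip(tab.abscissa, tab.values):
                writer.writerow([repr(a), repr(v)])
        table_entries.append({"energy": tab.energy, "kind": tab.kind, "file": fname})
    master = {
        "version": data.version,
        "checksum": data.compute_checksum(),
        "geometry": data.geometry.to_dict(),
        "dose_rates": list(data.dose_rates),
        "energy_selection": [
            {"sep_min": lo, "sep_max": hi, "energy": e}
            for lo, hi, e in data.energy_selection.rows
        ],
        "tables": table_entries,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(master, fh, sort_keys=False)
    return path


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required field {key!r}")
    return mapping[key]


def load_beam_data(path: str | Path) -> BeamDataSet:
    """Load and validate a beam-data master file, verifying its checksum."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"beam-data file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError("master file: top level must be a mapping")

    geom = MachineGeometry(**_require(raw, "geometry", "master file"))
    rows = tuple(
        (
            float(_require(r, "sep_min", "energy_selection")),
            float(_require(r, "sep_max", "energy_selection")),
            str(_require(r, "energy", "energy_selection")),
        )
        for r in _require(raw, "energy_selection", "master file")
    )
    tables: dict[tuple[str, str], FactorTable] = {}
    for entry in _require(raw, "tables", "master file"):
        energy = str(_require(entry, "energy", "tables"))
        kind = str(_require(entry, "kind", "tables"))
        csv_path = path.parent / _require(entry, "file", "tables")
        if not csv_path.exists():
            raise SchemaError(f"tables: referenced file missing: {csv_path.name}")
        abscissa: list[float] = []
        values: list[float] = []
        with open(csv_path) as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames != ["abscissa", "value"]:
                raise SchemaError(
                    f"{csv_path.name}: header must be 'abscissa,value'"
                )
            for row in reader:
                abscissa.append(float(row["abscissa"]))
                values.append(float(row["value"]))
        tables[(energy, kind)] = FactorTable(energy, kind, tuple(abscissa), tuple(values))

    ds = BeamDataSet(
        geometry=geom,
        tables=tables,
        energy_selection=EnergySelectionTable(rows),
        dose_rates=tuple(float(r) for r in _require(raw, "dose_rates", "master file")),
        version=str(raw.get("version", "unversioned")),
    )
    stored = raw.get("checksum")
    if stored and stored != ds.checksum:
        raise ChecksumError(
            f"checksum mismatch: stored {stored[:12]}…, recomputed {ds.checksum[:12]}…"
        )
    return ds


# ---------------------------------------------------------------------------
# seeded fixture generation

_ENERGY_PHYSICS = {
    # label: (dmax cm, effective attenuation /cm, TMR just past build-up)
    "6X": (1.5, 0.0485, 1.04),
    "10X": (2.4, 0.0442, 1.05),
    "15X": (2.9, 0.0410, 1.06),
    "18X": (3.2, 0.0390, 1.06),
}

FIXTURE_SEPARATION_RANGE = (10.0, 60.0)


def generate_fixture(seed: int, n_energies: int = 2) -> BeamDataSet:
    """Synthesize a physically plausible beam-data set, bit-reproducible per seed.

    TMR is strictly decreasing beyond the build-up depth with a realistic
    per-energy attenuation coefficient; Sc and Sp are near unity and increase
    gently with equivalent-square side; the spoiler factor is a per-energy
    scalar in (0.9, 1.1]; deliverable dose rates are the usual 100–600 MU/min
    ladder.  Separations from 10 to 60 cm are covered, partitioned evenly
    among the energies (thicker patients get the more penetrating beam).
    """
    if not 1 <= n_energies <= len(_ENERGY_PHYSICS):
        raise ValueError(f"n_energies must be 1..{len(_ENERGY_PHYSICS)}")
    rng = np.random.default_rng(seed)
    labels = list(_ENERGY_PHYSICS)[:n_energies]

    tables: dict[tuple[str, str], FactorTable] = {}
    for label in labels:
        dmax, mu_att, tmr0 = _ENERGY_PHYSICS[label]
        mu_att *= 1 + rng.uniform(-0.03, 0.03)
        tmr0 *= 1 + rng.uniform(-0.01, 0.01)
        depths = np.arange(np.ceil(dmax), 41.0)  # cm, covers midplane of any sep <= 60
        tmr = np.minimum(tmr0 * np.exp(-mu_att * (depths - dmax)), 1.2)
        tables[(label, "TMR")] = FactorTable(
            label, "TMR", tuple(depths.tolist()), tuple(np.round(tmr, 6).tolist())
        )
        sides = np.arange(4.0, 42.0, 2.0)
        sc = 0.95 + 0.0022 * (sides - 10.0) + rng.uniform(-0.002, 0.002)
        sp = 0.96 + 0.0018 * (sides - 10.0) + rng.uniform(-0.002, 0.002)
        tables[(label, "Sc")] = FactorTable(
            label, "Sc", tuple(sides.tolist()), tuple(np.round(sc, 6).tolist())
        )
        tables[(label, "Sp")] = FactorTable(
            label, "Sp", tuple(sides.tolist()), tuple(np.round(sp, 6).tolist())
        )
        spoiler = float(np.round(rng.uniform(0.95, 1.08), 4))
        tables[(label, "spoiler")] = FactorTable(label, "spoiler", (0.0,), (spoiler,))

    lo, hi = FIXTURE_SEPARATION_RANGE
    edges = np.linspace(lo, hi, n_energies + 1)
    rows = tuple(
        (float(edges[i]), float(edges[i + 1]), labels[i]) for i in range(n_energies)
    )

    return BeamDataSet(
        geometry=MachineGeometry(),
        tables=tables,
        energy_selection=EnergySelectionTable(rows),
        dose_rates=(100.0, 200.0, 300.0, 400.0, 500.0, 600.0),
        version=f"fixture-seed{seed}-e{n_energies}",
    )
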