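"""Patient calculation worksheet and automated pre-treatment plan checks.

Two safety mechanisms live here.  The worksheet renderer serializes the
calculation record into the patient document directly from the data model —
every number on the sheet is the number in the :class:`~tbi_autoplan.mu_calc.CalcResult`,
never retyped.  The check battery re-derives everything a physics plan check
would verify by hand: identifiers, field labelling, protocol consistency, an
independent MU recomputation, dose-rate feasibility, energy selection, and
geometry presets.

The MU recomputation is deliberately a separate code path (pure-Python table
walk, no calls into ``beam_data``/``mu_calc``): a checker that shares code
with the engine it audits cannot catch that engine's bugs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path

from .beam_data import BeamDataSet
from .mu_calc import (
    DEFAULT_PROTOCOLS,
    CalcResult,
    Prescription,
    ProtocolLimits,
    validate_prescription,
)
from .plan_builder import DEFAULT_GEOMETRY_PRESETS, TbiPlan


class WorksheetError(Exception):
    pass


class ExportBlockedError(Exception):
    """Strict mode: block findings present, export refused."""


@dataclass(frozen=True)
class CheckFinding:
    check_id: str
    severity: str  # "info" | "warn" | "block"
    message: str
    evidence: dict

    def to_dict(self) -> dict:
        return {
            "check_id": self.check_id,
            "severity": self.severity,
            "message": self.message,
            "evidence": self.evidence,
        }


# ---------------------------------------------------------------------------
# independent recomputation (the checker's own oracle)

def independent_dose_per_mu(data: BeamDataSet, prescription: Prescription,
                            sc_square: float | None = None,
                            sp_square: float | None = None) -> dict:
    """Recompute the factor breakdown from raw table knots, sharing no code
    with the calculation engine.  Pure-Python bracketing and arithmetic."""

    def lin(table, x):
        xs, ys = table.abscissa, table.values
        if len(xs) == 1:
            return ys[0]
        if x < xs[0] or x > xs[-1]:
            raise ValueError(f"{table.energy}/{table.kind}: {x} out of range")
        for i in range(len(xs) - 1):
            if xs[i] <= x <= xs[i + 1]:
                if x == xs[i]:
                    return ys[i]
                if x == xs[i + 1]:
                    return ys[i + 1]
                frac = (x - xs[i]) / (xs[i + 1] - xs[i])
                return ys[i] + frac * (ys[i + 1] - ys[i])
        raise AssertionError("unreachable")

    energy = None
    for lo, hi, e in data.energy_selection.rows:
        if lo <= prescription.separation < hi:
            energy = e
            break
    if energy is None:
        raise ValueError(f"separation {prescription.separation} not covered")

    geom = data.geometry
    depth = prescription.separation / 2.0
    isf = (geom.cal_distance / (geom.treatment_ssd + depth)) ** 2
    sc = lin(data.tables[(energy, "Sc")], sc_square or geom.treatment_field)
    sp = lin(data.tables[(energy, "Sp")], sp_square or geom.treatment_field)
    tmr = lin(data.tables[(energy, "TMR")], depth)
    spoiler = data.tables[(energy, "spoiler")].values[0]
    dpm = isf * sc * sp * tmr * spoiler * geom.water_to_muscle
    return {
        "energy": energy, "isf": isf, "sc": sc, "sp": sp, "tmr": tmr,
        "spoiler": spoiler, "muscle": geom.water_to_muscle, "dose_per_mu": dpm,
    }


def independent_mu(data: BeamDataSet, prescription: Prescription) -> int:
    """Independent MU: dose per field over recomputed dose/MU, half-up."""
    from decimal import ROUND_HALF_UP, Decimal

    dpm = independent_dose_per_mu(data, prescription)["dose_per_mu"]
    raw = prescription.dose_per_field / dpm
    return int(Decimal(repr(raw)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# worksheet

_WS_NUMERIC_FIELDS = (
    "dose_per_field", "num_fractions", "separation", "max_dose_rate",
    "depth", "distance_to_point", "isf", "sc", "sp", "tmr", "spoiler",
    "muscle", "dose_per_mu", "mu_per_field", "machine_dose_rate",
    "achieved_dose_rate",
)


def render_worksheet(
    prescription: Prescription,
    calc: CalcResult,
    path: str | Path,
    format: str = "markdown",
    operator_id: str = "auto",
    timestamp: _dt.datetime | None = None,
) -> Path:
    """Write the patient calculation worksheet (markdown or PDF).

    Refuses to render without patient identifiers — an unidentified worksheet
    is itself the documentation error this document exists to prevent.
    """
    if not prescription.patient_id:
        raise WorksheetError("patient_id (MRN) is required on the worksheet")
    if not prescription.patient_name:
        raise WorksheetError("patient_name is required on the worksheet")
    ts = timestamp or _dt.datetime.now()

    rows: list[tuple[str, str]] = [
        ("patient_name", prescription.patient_name),
        ("patient_id", prescription.patient_id),
        ("protocol", prescription.protocol),
        ("arrangement", prescription.arrangement),
        ("dose_per_field", repr(prescription.dose_per_field)),
        ("num_fractions", repr(prescription.num_fractions)),
        ("separation", repr(prescription.separation)),
        ("max_dose_rate", repr(prescription.max_dose_rate)),
        ("energy", calc.energy),
        ("depth", repr(calc.depth)),
        ("distance_to_point", repr(calc.distance_to_point)),
        ("isf", repr(calc.factors.isf)),
        ("sc", repr(calc.factors.sc)),
        ("sp", repr(calc.factors.sp)),
        ("tmr", repr(calc.factors.tmr)),
        ("spoiler", repr(calc.factors.spoiler)),
        ("muscle", repr(calc.factors.muscle)),
        ("dose_per_mu", repr(calc.factors.dose_per_mu)),
        ("mu_per_field", repr(calc.mu_per_field)),
        ("machine_dose_rate", repr(calc.machine_dose_rate)),
        ("achieved_dose_rate", repr(calc.achieved_dose_rate)),
        ("beam_data_version", calc.beam_data_version),
        ("beam_data_checksum", calc.beam_data_checksum),
        ("generated", ts.isoformat(timespec="seconds")),
        ("operator", operator_id),
    ]

    path = Path(path)
    if format == "markdown":
        lines = ["# TBI monitor-unit calculation worksheet", "",
                 "| field | value |", "| --- | --- |"]
        lines += [f"| {k} | {v} |" for k, v in rows]
        path.write_text("\n".join(lines) + "\n")
        return path
    if format == "pdf":
        _render_pdf(rows, path)
        return path
    raise WorksheetError(f"unknown worksheet format {format!r}")


def _render_pdf(rows: list[tuple[str, str]], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8.5, 11))
    ax.axis("off")
    ax.set_title("TBI monitor-unit calculation worksheet", loc="left")
    text = "\n".join(f"{k:>22}: {v}" for k, v in rows)
    ax.text(0.02, 0.96, text, family="monospace", fontsize=9, va="top")
    fig.savefig(path, format="pdf")
    plt.close(fig)


def parse_worksheet(path: str | Path) -> dict:
    """Parse a markdown worksheet back into a field→value mapping.

    Numeric fields come back as floats; everything else as strings.  Used by
    the parse-back test and by the document-consistency check.
    """
    out: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        if not line.startswith("|") or line.startswith(("| field", "| ---")):
            continue
        _, key, value, _ = (part.strip() for part in line.split("|"))
        out[key] = float(value) if key in _WS_NUMERIC_FIELDS else value
    return out


# ---------------------------------------------------------------------------
# check battery

def run_checks(
    plan: TbiPlan,
    prescription: Prescription,
    calc: CalcResult,
    beam_data: BeamDataSet,
    worksheet: dict | None = None,
    geometry_presets: dict[str, list[tuple[str, float]]] | None = None,
    protocol_registry: dict[str, ProtocolLimits] = DEFAULT_PROTOCOLS,
) -> list[CheckFinding]:
    """Run every automated pre-treatment check; returns findings, never raises.

    ``worksheet`` is the parsed calculation document (``parse_worksheet``
    output) when one is attached; ``None`` means no document, which is itself
    a finding.
    """
    presets = geometry_presets if geometry_presets is not None else DEFAULT_GEOMETRY_PRESETS
    findings: list[CheckFinding] = []

    def add(check_id: str, severity: str, message: str, **evidence) -> None:
        findings.append(CheckFinding(check_id, severity, message, evidence))

    # (a) identifier match between prescription, plan and worksheet
    if plan.patient_id != prescription.patient_id or plan.patient_name != prescription.patient_name:
        add("id_match", "block", "plan and prescription identifiers differ",
            plan_id=plan.patient_id, rx_id=prescription.patient_id,
            plan_name=plan.patient_name, rx_name=prescription.patient_name)
    if worksheet is not None:
        for key, expected in (("patient_id", prescription.patient_id),
                              ("patient_name", prescription.patient_name)):
            if worksheet.get(key) != expected:
                add("id_match", "block", f"worksheet {key} differs from prescription",
                    worksheet=worksheet.get(key), prescription=expected)

    # (b) field labels unique and consistent with the arrangement
    names = [f.name for f in plan.fields]
    expected_names = [n for n, _ in presets.get(prescription.arrangement, [])]
    if len(set(names)) != len(names):
        add("field_labels", "block", "duplicate field labels",
            labels=names)
    if expected_names and sorted(names) != sorted(expected_names):
        add("field_labels", "block",
            "field labels do not match the prescribed arrangement",
            labels=names, expected=expected_names)

    # (c) protocol / worksheet-type consistency
    try:
        for f in validate_prescription(prescription, protocol_registry):
            add("protocol_consistency", f.severity, f.message, field=f.field)
    except KeyError as exc:
        add("protocol_consistency", "block", str(exc))
    if worksheet is not None:
        for key, expected in (
            ("protocol", prescription.protocol),
            ("separation", prescription.separation),
            ("dose_per_field", prescription.dose_per_field),
            ("max_dose_rate", prescription.max_dose_rate),
        ):
            if worksheet.get(key) != expected:
                add("protocol_consistency", "block",
                    f"worksheet {key} differs from prescription",
                    worksheet=worksheet.get(key), prescription=expected)

    # (d) independent MU recomputation
    try:
        ref = independent_dose_per_mu(beam_data, prescription)
        mu_ref = independent_mu(beam_data, prescription)
        if abs(ref["dose_per_mu"] - calc.factors.dose_per_mu) > 1e-9 * ref["dose_per_mu"]:
            add("mu_recompute", "block",
                "calculation dose/MU differs from independent recomputation",
                engine=calc.factors.dose_per_mu, independent=ref["dose_per_mu"])
        for f in plan.fields:
            if f.mu != mu_ref:
                add("mu_recompute", "block",
                    f"field {f.name}: plan MU {f.mu} differs from independent "
                    f"recomputation {mu_ref}",
                    field=f.name, plan_mu=f.mu, independent_mu=mu_ref)
    except Exception as exc:  # recompute itself failed: that is a block too
        add("mu_recompute", "block", f"independent recomputation failed: {exc}")

    # (e) dose-rate feasibility against the prescription limit and the ladder
    try:
        dpm = independent_dose_per_mu(beam_data, prescription)["dose_per_mu"]
    except Exception:
        dpm = calc.factors.dose_per_mu
    rates = {f.dose_rate for f in plan.fields}
    if len(rates) > 1:
        add("dose_rate", "block", "fields carry different dose rates",
            rates=sorted(rates))
    for f in plan.fields:
        if f.dose_rate not in beam_data.dose_rates:
            add("dose_rate", "block",
                f"field {f.name}: {f.dose_rate} MU/min is not deliverable",
                field=f.name, ladder=list(beam_data.dose_rates))
        achieved = f.dose_rate * dpm
        if achieved > prescription.max_dose_rate * (1 + 1e-9):
            add("dose_rate", "block",
                f"field {f.name}: {achieved:.2f} cGy/min exceeds the "
                f"{prescription.max_dose_rate} cGy/min limit",
                field=f.name, achieved=achieved, limit=prescription.max_dose_rate)
        else:
            faster = [r for r in beam_data.dose_rates if r > f.dose_rate
                      and r * dpm <= prescription.max_dose_rate * (1 + 1e-9)]
            if faster:
                add("dose_rate", "warn",
                    f"field {f.name}: a faster deliverable rate ({max(faster)} "
                    "MU/min) would still satisfy the limit",
                    field=f.name, faster=max(faster))

    # (f) energy consistent with the separation look-up
    expected_energy = None
    for lo, hi, e in beam_data.energy_selection.rows:
        if lo <= prescription.separation < hi:
            expected_energy = e
            break
    if expected_energy is None:
        add("energy_selection", "block",
            f"separation {prescription.separation} cm not covered by the "
            "energy-selection table")
    else:
        for f in plan.fields:
            if f.energy != expected_energy:
                add("energy_selection", "block",
                    f"field {f.name}: energy {f.energy} but separation "
                    f"{prescription.separation} cm selects {expected_energy}",
                    field=f.name, plan=f.energy, expected=expected_energy)
        if calc.energy != expected_energy:
            add("energy_selection", "block",
                "calculation used the wrong energy for this separation",
                calc=calc.energy, expected=expected_energy)

    # (g) geometry: gantry, SSD and field size against the presets
    preset_map = dict(presets.get(prescription.arrangement, []))
    expected_ssd = beam_data.geometry.treatment_ssd
    for f in plan.fields:
        if f.name in preset_map and f.gantry != preset_map[f.name]:
            add("geometry", "block",
                f"field {f.name}: gantry {f.gantry}° differs from preset "
                f"{preset_map[f.name]}°",
                field=f.name, gantry=f.gantry, preset=preset_map[f.name])
        if f.field_size != (beam_data.geometry.treatment_field,) * 2:
            add("geometry", "block",
                f"field {f.name}: field size {f.field_size} differs from the "
                f"{beam_data.geometry.treatment_field} cm technique standard",
                field=f.name, field_size=list(f.field_size))
        if abs(f.ssd - expected_ssd) > 0.5:
            add("geometry", "warn",
                f"field {f.name}: SSD {f.ssd} cm differs from technique "
                f"standard {expected_ssd} cm",
                field=f.name, ssd=f.ssd, expected=expected_ssd)

    # (h) worksheet attached and versions agree
    if worksheet is None:
        add("worksheet_attached", "block",
            "no calculation worksheet attached to the plan")
    else:
        if worksheet.get("beam_data_version") != calc.beam_data_version:
            add("worksheet_attached", "block",
                "worksheet was generated from different beam data",
                worksheet=worksheet.get("beam_data_version"),
                calc=calc.beam_data_version)
        if worksheet.get("mu_per_field") != float(calc.mu_per_field):
            add("worksheet_attached", "block",
                "worksheet MU differs from the calculation record",
                worksheet=worksheet.get("mu_per_field"), calc=calc.mu_per_field)

    return findings


def assert_exportable(findings: list[CheckFinding], strict: bool = True) -> None:
    """Forcing function: with strict mode on, block findings stop the export."""
    blocks = [f for f in findings if f.severity == "block"]
    if strict and blocks:
        raise ExportBlockedError(
            f"{len(blocks)} blocking finding(s): "
            + "; ".join(f"{f.check_id}: {f.message}" for f in blocks)
        )
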