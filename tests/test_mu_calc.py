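"""The hand-calculation engine: factors, MU, dose rate, prescription checks."""

import numpy as np
import pytest

from tbi_autoplan.beam_data import (
    BeamDataSet,
    EnergySelectionTable,
    FactorTable,
    MachineGeometry,
    generate_fixture,
)
from tbi_autoplan.mu_calc import (
    DEFAULT_PROTOCOLS,
    CalcOptions,
    CalculationRefusedError,
    DomainError,
    FactorBreakdown,
    NoFeasibleRateError,
    Prescription,
    compute_dose_rate,
    compute_mu,
    dose_per_mu,
    inverse_square_factor,
    round_half_up,
    validate_prescription,
)


def _unit_tables_set(dose_rates=(100.0, 200.0, 300.0), spoiler=1.0):
    """A beam data set whose table factors are all exactly 1."""
    tables = {
        ("6X", "TMR"): FactorTable("6X", "TMR", (0.5, 60.0), (1.0, 1.0)),
        ("6X", "Sc"): FactorTable("6X", "Sc", (4.0, 40.0), (1.0, 1.0)),
        ("6X", "Sp"): FactorTable("6X", "Sp", (4.0, 40.0), (1.0, 1.0)),
        ("6X", "spoiler"): FactorTable("6X", "spoiler", (0.0,), (spoiler,)),
    }
    return BeamDataSet(
        geometry=MachineGeometry(),
        tables=tables,
        energy_selection=EnergySelectionTable(((1.0, 120.0, "6X"),)),
        dose_rates=dose_rates,
        version="unit",
    )


def _rx(**kw):
    base = dict(protocol="standard_adult", dose_per_field=150.0, num_fractions=6,
                separation=36.0, max_dose_rate=10.0, arrangement="AP/PA",
                patient_id="M1", patient_name="P")
    base.update(kw)
    return Prescription(**base)


class TestInverseSquare:
    def test_zero_separation_closed_form(self):
        assert inverse_square_factor(MachineGeometry(), 0.0) == pytest.approx(0.04, abs=1e-15)

    def test_forty_cm_separation(self):
        # (100 / (500 + 20))^2
        want = (100.0 / 520.0) ** 2
        assert inverse_square_factor(MachineGeometry(), 40.0) == pytest.approx(want, rel=1e-15)
        assert want == pytest.approx(0.036982, abs=5e-7)

    def test_strictly_decreasing_in_separation(self):
        geom = MachineGeometry()
        vals = [inverse_square_factor(geom, s) for s in np.arange(0.0, 60.5, 0.5)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_negative_separation_rejected(self):
        with pytest.raises(DomainError):
            inverse_square_factor(MachineGeometry(), -1.0)


class TestDosePerMu:
    def test_unit_tables_collapse_to_isf_times_muscle(self):
        """With every table factor 1 the product is ISF x 0.99; at ~zero
        separation that is 0.04 x 0.99 = 0.0396."""
        ds = _unit_tables_set()
        fb = dose_per_mu(ds, _rx(separation=1.0))
        isf = inverse_square_factor(ds.geometry, 1.0)
        assert fb.dose_per_mu == pytest.approx(isf * 0.99, rel=1e-14)
        assert fb.sc == fb.sp == fb.tmr == fb.spoiler == 1.0

    def test_spoiler_scales_multiplicatively(self):
        base = dose_per_mu(_unit_tables_set(spoiler=1.0), _rx())
        scaled = dose_per_mu(_unit_tables_set(spoiler=0.95), _rx())
        assert scaled.dose_per_mu == pytest.approx(0.95 * base.dose_per_mu, rel=1e-14)

    def test_matches_spreadsheet_style_recomputation(self, beam, rx):
        """Recompute from raw knots the way the spreadsheet would."""
        def bracket(table, x):
            xs, ys = table.abscissa, table.values
            i = max(j for j in range(len(xs)) if xs[j] <= x)
            if xs[i] == x:
                return ys[i]
            f = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] + f * (ys[i + 1] - ys[i])

        energy = next(e for lo, hi, e in beam.energy_selection.rows
                      if lo <= rx.separation < hi)
        depth = rx.separation / 2
        isf = (100.0 / (500.0 + depth)) ** 2
        want = (isf
                * bracket(beam.tables[(energy, "Sc")], 40.0)
                * bracket(beam.tables[(energy, "Sp")], 40.0)
                * bracket(beam.tables[(energy, "TMR")], depth)
                * beam.tables[(energy, "spoiler")].values[0]
                * 0.99)
        got = dose_per_mu(beam, rx)
        assert got.dose_per_mu == pytest.approx(want, rel=1e-12)

    def test_breakdown_product_invariant_enforced(self):
        with pytest.raises(DomainError, match="product"):
            FactorBreakdown(isf=0.04, sc=1.0, sp=1.0, tmr=1.0, spoiler=1.0,
                            muscle=0.99, dose_per_mu=0.05)


class TestComputeMu:
    def test_identity_dose_per_mu_gives_dose_in_mu(self):
        """dose_per_field / dose_per_mu with the quotient forced to be
        computable by hand: 200 cGy at 0.0396 cGy/MU -> 5051 MU."""
        assert round_half_up(200.0 / 0.0396) == 5051  # round(5050.505...)

    def test_mu_rounding_contract(self, beam, rx):
        res = compute_mu(beam, rx)
        dose_back = res.mu_per_field * res.factors.dose_per_mu
        assert abs(dose_back - rx.dose_per_field) <= 0.5 * res.factors.dose_per_mu

    def test_sanity_cap_refuses_absurd_mu(self, beam, rx):
        with pytest.raises(CalculationRefusedError, match="cap"):
            compute_mu(beam, rx, CalcOptions(mu_cap=100))

    def test_mu_nondecreasing_in_separation_at_fixed_energy(self, beam):
        lo, hi, energy = beam.energy_selection.rows[0]
        seps = np.linspace(lo + 0.5, hi - 0.5, 12)
        mus = [compute_mu(beam, _rx(separation=float(s))).mu_per_field for s in seps]
        assert all(b >= a for a, b in zip(mus, mus[1:]))

    def test_result_carries_audit_trail(self, beam, rx):
        res = compute_mu(beam, rx)
        assert res.beam_data_version == beam.version
        assert res.beam_data_checksum == beam.checksum
        assert res.depth == rx.separation / 2
        assert res.distance_to_point == 500.0 + rx.separation / 2

    def test_oracle_equivalence_25_prior_cases(self, beam):
        """Replanned prior-case equivalence: engine vs a from-scratch
        recomputation that reads raw knots and rebuilds every factor."""
        rng = np.random.default_rng(25)
        for _ in range(25):
            sep = float(rng.uniform(18.0, 59.0))
            dose = float(rng.uniform(100.0, 300.0))
            rx = _rx(separation=sep, dose_per_field=dose)
            res = compute_mu(beam, rx)

            energy = next(e for l, h, e in beam.energy_selection.rows
                          if l <= sep < h)
            depth = sep / 2

            def lin(table, x):
                xs, ys = table.abscissa, table.values
                i = max(j for j in range(len(xs) - 1) if xs[j] <= x)
                f = (x - xs[i]) / (xs[i + 1] - xs[i])
                return ys[i] * (1 - f) + ys[i + 1] * f

            dpm = ((100.0 / (500.0 + depth)) ** 2
                   * lin(beam.tables[(energy, "Sc")], 40.0)
                   * lin(beam.tables[(energy, "Sp")], 40.0)
                   * lin(beam.tables[(energy, "TMR")], depth)
                   * beam.tables[(energy, "spoiler")].values[0]
                   * 0.99)
            assert res.factors.dose_per_mu == pytest.approx(dpm, rel=1e-12)
            assert res.mu_per_field == int(round_half_up(dose / dpm))


class TestDoseRate:
    def test_brute_force_over_ladder(self):
        ds = _unit_tables_set(dose_rates=(100.0, 200.0, 300.0))
        fb = FactorBreakdown(isf=0.05, sc=1.0, sp=1.0, tmr=1.0, spoiler=1.0,
                             muscle=1.0, dose_per_mu=0.05)
        rate, achieved = compute_dose_rate(ds, _rx(max_dose_rate=10.0), fb)
        assert rate == 200.0
        assert achieved == pytest.approx(10.0)

    def test_limit_exactly_at_ladder_point_is_inclusive(self):
        ds = _unit_tables_set(dose_rates=(100.0, 250.0))
        fb = FactorBreakdown(isf=0.04, sc=1.0, sp=1.0, tmr=1.0, spoiler=1.0,
                             muscle=1.0, dose_per_mu=0.04)
        rate, achieved = compute_dose_rate(ds, _rx(max_dose_rate=10.0), fb)
        assert rate == 250.0 and achieved == pytest.approx(10.0)

    def test_infeasible_ladder_raises(self):
        ds = _unit_tables_set(dose_rates=(400.0,))
        fb = FactorBreakdown(isf=0.05, sc=1.0, sp=1.0, tmr=1.0, spoiler=1.0,
                             muscle=1.0, dose_per_mu=0.05)
        with pytest.raises(NoFeasibleRateError):
            compute_dose_rate(ds, _rx(max_dose_rate=10.0), fb)

    def test_feasible_and_maximal_seeded_sweep(self):
        """Chosen rate obeys the limit and the next ladder member breaks it."""
        rng = np.random.default_rng(1000)
        ladder = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0)
        beam = generate_fixture(seed=11, n_energies=2)
        for _ in range(1000):
            rx = _rx(separation=float(rng.uniform(10.5, 59.5)),
                     max_dose_rate=float(rng.uniform(4.0, 15.0)))
            fb = dose_per_mu(beam, rx)
            try:
                rate, achieved = compute_dose_rate(beam, rx, fb)
            except NoFeasibleRateError:
                assert ladder[0] * fb.dose_per_mu > rx.max_dose_rate
                continue
            assert achieved <= rx.max_dose_rate * (1 + 1e-9)
            above = [r for r in ladder if r > rate]
            if above:
                assert min(above) * fb.dose_per_mu > rx.max_dose_rate * (1 - 1e-9)


class TestValidatePrescription:
    def test_clean_prescription_passes(self):
        assert validate_prescription(_rx()) == []

    def test_adult_protocol_with_pediatric_parameters_blocks(self):
        findings = validate_prescription(_rx(separation=12.0, dose_per_field=60.0))
        assert any(f.severity == "block" and f.field == "separation" for f in findings)
        assert any(f.severity == "block" and f.field == "dose_per_field" for f in findings)

    def test_dose_rate_over_protocol_ceiling_blocks(self):
        findings = validate_prescription(_rx(max_dose_rate=15.0))
        assert any(f.field == "max_dose_rate" and f.severity == "block"
                   for f in findings)
        # the same 15 cGy/min is fine under the high-rate protocol
        ok = validate_prescription(_rx(protocol="single_dose_adult",
                                       max_dose_rate=15.0, dose_per_field=400.0,
                                       num_fractions=1))
        assert not any(f.field == "max_dose_rate" for f in ok)

    def test_unknown_protocol_raises(self):
        with pytest.raises(KeyError):
            validate_prescription(_rx(protocol="no_such_protocol"))

    def test_registry_is_configurable(self):
        registry = dict(DEFAULT_PROTOCOLS)
        ceiling5 = DEFAULT_PROTOCOLS["standard_pediatric"]
        registry["low_rate_pediatric"] = type(ceiling5)(
            5.0, (50.0, 150.0), (8.0, 28.0), "pediatric")
        findings = validate_prescription(
            _rx(protocol="low_rate_pediatric", separation=20.0,
                dose_per_field=100.0, max_dose_rate=10.0), registry)
        assert any(f.field == "max_dose_rate" for f in findings)
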