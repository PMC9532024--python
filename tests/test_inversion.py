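"""Measurement-to-permeability inversion: algebra, interpolants, cohort."""

import math

import numpy as np
import pytest

import collateralflow as cf
from collateralflow.inversion import (DEFAULT_COHORT_RANGES, PatientMeasurement,
                                      ResponseCurve, estimate_patient,
                                      flow_from_measurement,
                                      generate_synthetic_cohort,
                                      invert_to_resistance,
                                      permeability_from_resistance,
                                      read_measurements_csv,
                                      write_measurements_csv)
from collateralflow.thrombus import darcy_resistance


def _measurement(**kw):
    base = dict(patient_id="p0", transit_time_s=5.0, void_fraction=0.2,
                length_mm=10.0, lumen_area_mm2=4.5)
    base.update(kw)
    return PatientMeasurement(**base)


class TestFlowFromMeasurement:
    def test_reference_value(self):
        # 0.2 * 4.5 mm^2 * 10 mm / 5 s = 1.8 mm^3/s = 1.8e-3 ml/s
        assert flow_from_measurement(_measurement()) == pytest.approx(1.8e-3)

    def test_impervious_gives_zero(self):
        assert flow_from_measurement(_measurement(void_fraction=0.0)) == 0.0

    def test_transit_time_proportionality(self):
        q1 = flow_from_measurement(_measurement(transit_time_s=5.0))
        q2 = flow_from_measurement(_measurement(transit_time_s=10.0))
        assert q2 == pytest.approx(q1 / 2)

    def test_invalid_measurement(self):
        with pytest.raises(ValueError):
            _measurement(transit_time_s=-1.0)
        with pytest.raises(ValueError):
            _measurement(void_fraction=1.5)


class TestPermeabilityAlgebra:
    def test_round_trip_through_darcy_law(self):
        kappa, area, length, mu = 3.7e-6, 4.5, 12.0, 3.5e-3
        r_vessel = 55.0
        r_t = darcy_resistance(kappa, area, length, mu) + r_vessel
        back = permeability_from_resistance(r_t, length, area, mu, r_vessel)
        assert back == pytest.approx(kappa, rel=1e-12)

    def test_reference_inverse(self):
        kappa = permeability_from_resistance(7.78e5, 10.0, 4.5, 3.5e-3, 0.0)
        assert kappa == pytest.approx(1e-5, rel=1e-2)

    def test_unbounded_sentinel(self):
        with pytest.warns(UserWarning, match="unbounded"):
            assert permeability_from_resistance(10.0, 10.0, 4.5, 3.5e-3,
                                                50.0) == math.inf


def _synthetic_curve() -> ResponseCurve:
    """Analytic stand-in response: Q = Q0 / (1 + R/Rc), strictly decreasing."""
    grid = np.logspace(3, 10, 15)
    q = 1.5 / (1 + grid / 3e5)
    dp = 11_000.0 * (grid / 3e5) / (1 + grid / 3e5)
    iv = 160.0 * (grid / 3e5) / (1 + grid / 3e5)
    return ResponseCurve(collateral_probability=0.25, R_T_Pa_s_ml=grid,
                         Q_thrombus_ml_s=q, dp_Pa=dp, infarct_ml=iv,
                         occluded_dp_Pa=11_000.0, occluded_infarct_ml=160.0,
                         host_r0_mm=1.4, host_vessel_resistance_Pa_s_ml=190.0)


class TestResponseCurve:
    def test_knot_identity(self):
        curve = _synthetic_curve()
        assert np.allclose(curve.flow_at(curve.R_T_Pa_s_ml),
                           curve.Q_thrombus_ml_s, rtol=1e-14)

    def test_inverse_identity_at_knots(self):
        curve = _synthetic_curve()
        for r, q in zip(curve.R_T_Pa_s_ml[1:-1], curve.Q_thrombus_ml_s[1:-1]):
            assert invert_to_resistance(q, curve) == pytest.approx(r, rel=1e-9)

    def test_monotone_inversion(self):
        curve = _synthetic_curve()
        qs = np.linspace(*curve.flow_range, 12)[1:-1]
        rs = [invert_to_resistance(q, curve) for q in qs]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_out_of_range_raises_or_clamps(self):
        curve = _synthetic_curve()
        with pytest.raises(ValueError, match="outside"):
            invert_to_resistance(10.0, curve)
        with pytest.warns(UserWarning, match="clamped"):
            r = invert_to_resistance(10.0, curve, clamp=True)
        assert r == pytest.approx(curve.R_T_Pa_s_ml[0])

    def test_non_monotone_tabulation_rejected(self):
        grid = np.logspace(3, 10, 8)
        q = np.array([1.5, 1.2, 1.3, 0.9, 0.5, 0.1, 0.01, 0.001])
        with pytest.raises(ValueError, match="monotone"):
            ResponseCurve(0.25, grid, q, np.ones(8), np.ones(8), 1.0, 1.0,
                          1.4, 190.0)


class TestEstimatePatient:
    def test_impervious_branch_uses_occluding_simulation(self):
        curve = _synthetic_curve()
        est = estimate_patient(_measurement(void_fraction=0.0), curve)
        assert est.resistance_Pa_s_ml == math.inf
        assert est.kappa_mm2 == 0.0
        assert est.dp_mmHg == pytest.approx(11_000.0 / 133.322)
        assert est.infarct_ml == pytest.approx(160.0)

    def test_pressure_drop_physiologic(self):
        curve = _synthetic_curve()
        est = estimate_patient(_measurement(), curve)
        assert 0.0 < est.dp_mmHg < (12_500 - 666) / 133.322

    def test_monotone_chain_flow_to_permeability(self):
        curve = _synthetic_curve()
        kappas = []
        for dt in (20.0, 10.0, 5.0, 2.0):   # shorter transit -> more flow
            est = estimate_patient(_measurement(transit_time_s=dt), curve)
            kappas.append(est.kappa_mm2)
        assert all(a < b for a, b in zip(kappas, kappas[1:]))


class TestSyntheticCohort:
    def test_cohort_size_and_ranges(self):
        cohort = generate_synthetic_cohort(44, seed=5)
        assert len(cohort) == 44
        for m in cohort:
            lo, hi = DEFAULT_COHORT_RANGES["length_mm"]
            assert lo <= m.length_mm <= hi
            assert 1.0 <= m.transit_time_s <= 30.0
            assert 0.0 <= m.void_fraction <= 0.5

    def test_seed_reproducibility(self):
        a = generate_synthetic_cohort(10, seed=3)
        b = generate_synthetic_cohort(10, seed=3)
        assert [m.__dict__ for m in a] == [m.__dict__ for m in b]

    def test_csv_round_trip(self, tmp_path):
        cohort = generate_synthetic_cohort(6, seed=1)
        path = tmp_path / "m.csv"
        write_measurements_csv(cohort, path)
        back = read_measurements_csv(path)
        assert [m.__dict__ for m in back] == [m.__dict__ for m in cohort]
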