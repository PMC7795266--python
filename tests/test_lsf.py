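"""Squeezing-flow kinematics, stress and flow-curve fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import doughrheo as dr
from doughrheo.lsf import (
    NoUsableSamplesError,
    PlatenOvertravelError,
    biaxial_strain,
    biaxial_strain_rate,
    biaxial_viscosity,
    extract_at_strain,
    fit_flow_curve,
    height_at_time,
    process_trace,
    stress,
)


class TestKinematics:
    @pytest.mark.parametrize(
        "t, h0, v, expected",
        [(0.0, 20.0, 10.0, 20.0), (1.8, 20.0, 10.0, 2.0), (0.9, 20.0, 10.0, 11.0)],
    )
    def test_height_at_time(self, t, h0, v, expected):
        assert height_at_time(t, h0, v) == pytest.approx(expected)

    def test_platen_overtravel_rejected(self):
        with pytest.raises(PlatenOvertravelError):
            height_at_time(2.1, 20.0, 10.0)

    @pytest.mark.parametrize(
        "h_t, h0, expected",
        [(20.0, 20.0, 0.0), (2.0, 20.0, 0.5 * np.log(10.0)), (20.0 * np.exp(-2.0), 20.0, 1.0)],
    )
    def test_biaxial_strain(self, h_t, h0, expected):
        assert biaxial_strain(h_t, h0) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("h_t", [-1.0, 0.0, 25.0])
    def test_strain_domain_errors(self, h_t):
        with pytest.raises(ValueError):
            biaxial_strain(h_t, 20.0)

    @given(
        h0=st.floats(5.0, 50.0),
        f1=st.floats(0.1, 0.99),
        f2=st.floats(0.1, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_strain_additivity(self, h0, f1, f2):
        """Hencky strain accumulates: eps(h0->h1) + eps(h1->h2) = eps(h0->h2)."""
        h1, h2 = h0 * f1, h0 * f1 * f2
        total = biaxial_strain(h2, h0)
        assert biaxial_strain(h1, h0) + biaxial_strain(h2, h1) == pytest.approx(total, rel=1e-9)

    @pytest.mark.parametrize(
        "v, h_t, expected", [(10.0, 2.0, 2.5), (0.1, 20.0, 0.0025), (0.0, 5.0, 0.0)]
    )
    def test_biaxial_strain_rate(self, v, h_t, expected):
        assert biaxial_strain_rate(v, h_t) == pytest.approx(expected)

    def test_stress_examples(self):
        assert stress(0.0, 10.0) == 0.0
        assert stress(np.pi, 1000.0) == pytest.approx(1.0)  # 1 m plate: unit identity
        assert stress(1.0, 22.5) == pytest.approx(628.8, rel=1e-3)

    def test_viscosity_is_stress_over_rate(self):
        assert biaxial_viscosity(1.0, 22.5, 2.5) == pytest.approx(stress(1.0, 22.5) / 2.5)
        with pytest.raises(ValueError):
            biaxial_viscosity(1.0, 22.5, 0.0)


class TestProcessTrace:
    def test_matches_simulator_closed_form(self, clean_params, clean_speed_set):
        """The noise-free simulator is the oracle: eta = sigma/rate exactly."""
        for trace in clean_speed_set:
            p = process_trace(trace)
            sigma_true = clean_params.stress(p.rate, p.strain)
            np.testing.assert_allclose(p.stress, sigma_true, rtol=1e-9)
            np.testing.assert_allclose(p.viscosity, p.stress / p.rate, rtol=1e-12)

    def test_kinematic_invariants(self, clean_processed):
        for p in clean_processed:
            assert np.all(np.diff(p.strain) >= 0)
            assert np.all(np.diff(p.rate) > 0)
            assert p.strain.max() == pytest.approx(0.5 * np.log(10.0), rel=1e-9)

    def test_constant_force_gives_decreasing_viscosity(self):
        t = np.linspace(0.0, 1.7, 300)
        trace = dr.LSFTrace(
            time=t, force=np.full_like(t, 5.0), platen_speed=10.0,
            initial_height=20.0, plate_radius=22.5,
        )
        p = process_trace(trace)
        assert np.ptp(p.stress) == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(p.viscosity) < 0)

    def test_rate_scales_linearly_in_speed_at_fixed_strain(self, clean_processed):
        """rate(eps) = v * exp(2 eps) / (2 h0), so rate/v collapses across speeds."""
        grids = [extract_at_strain(p, [0.5]) for p in clean_processed]
        scaled = [g["rate"].iloc[0] / p.platen_speed for g, p in zip(grids, clean_processed)]
        expected = np.exp(2 * 0.5) / (2 * 20.0)
        np.testing.assert_allclose(scaled, expected, rtol=1e-9)

    def test_settle_samples_dropped(self):
        t = np.linspace(0.0, 1.7, 100)
        force = np.where(t < 0.2, 0.001, 5.0)  # below the 0.01 N noise floor early
        trace = dr.LSFTrace(t, force, 10.0, 20.0, 22.5)
        p = process_trace(trace)
        assert p.time[0] >= 0.2

    def test_no_usable_samples(self):
        t = np.linspace(0.0, 1.0, 10)
        trace = dr.LSFTrace(t, np.full_like(t, 1e-4), 10.0, 20.0, 22.5)
        with pytest.raises(NoUsableSamplesError):
            process_trace(trace)


class TestExtractAtStrain:
    def test_existing_grid_point_exact(self, clean_processed):
        p = clean_processed[0]
        i = p.strain.size // 2
        row = extract_at_strain(p, [p.strain[i]]).iloc[0]
        assert row["stress"] == pytest.approx(p.stress[i], rel=1e-12)
        assert row["rate"] == pytest.approx(p.rate[i], rel=1e-12)

    def test_log_linear_interpolation_is_exact_on_model(self, clean_params, clean_processed):
        for p in clean_processed:
            row = extract_at_strain(p, [0.5]).iloc[0]
            sigma_true = clean_params.stress(row["rate"], 0.5)
            assert row["stress"] == pytest.approx(sigma_true, rel=1e-6)

    def test_protocol_grid_fully_reachable_at_slowest_speed(self, clean_processed):
        slow = next(p for p in clean_processed if p.platen_speed == 0.1)
        table = extract_at_strain(slow, dr.DEFAULT_STRAIN_GRID)
        assert table["in_range"].all()

    def test_out_of_range_flagged_not_fatal(self, clean_processed):
        table = extract_at_strain(clean_processed[0], [0.5, 2.0])
        assert bool(table["in_range"].iloc[0]) and not bool(table["in_range"].iloc[1])
        assert np.isnan(table["stress"].iloc[1])


class TestFlowCurve:
    def test_exact_power_law_recovery(self):
        rates = np.logspace(-2, 1, 8)
        fit = fit_flow_curve(rates, 1000.0 * rates ** (0.4 - 1.0))
        assert fit.K == pytest.approx(1000.0, rel=1e-9)
        assert fit.n == pytest.approx(0.4, rel=1e-9)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(7)
        rates = np.logspace(-2, 1, 5)
        eta = 1000.0 * rates ** (0.4 - 1.0) * rng.lognormal(0, 0.02, rates.shape)
        fit = fit_flow_curve(rates, eta)
        assert abs(fit.n - 0.4) < 3 * fit.stderr_n
        assert abs(fit.K - 1000.0) < 3 * fit.stderr_K

    def test_extension_thinning_classification(self, clean_params, clean_processed):
        rows = [extract_at_strain(p, [1.0]).iloc[0] for p in clean_processed]
        fit = fit_flow_curve([r["rate"] for r in rows], [r["viscosity"] for r in rows])
        # eta = C exp(S eps) rate**(m-1): flow index n = m < 1 -> thinning
        assert fit.n == pytest.approx(clean_params.m, rel=1e-9)
        assert fit.K == pytest.approx(clean_params.C * np.exp(clean_params.shi_true), rel=1e-9)
        assert fit.is_extension_thinning

    def test_refuses_insufficient_points(self):
        with pytest.raises(ValueError):
            fit_flow_curve([1.0, 2.0], [3.0, 4.0])
        with pytest.warns(UserWarning, match="duplicate"), pytest.raises(ValueError):
            fit_flow_curve([1.0, 1.0, 1.0], [3.0, 4.0, 5.0])
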