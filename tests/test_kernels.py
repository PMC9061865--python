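"""Mechanism kernels and their BR/BRD superpositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanorelease import (
    MechanismParams,
    ParticleGeometry,
    br_model,
    brd_model,
    burst_fraction,
    degradation_fraction,
    diffusion_fraction,
    mechanism_contributions,
)
from nanorelease.tables import brd_params_at


class TestBurst:
    @pytest.mark.parametrize(
        "t, k_b, expected",
        [
            (0.0, 1.8053, 0.0),
            (1000.0, 0.5, 1.0),
            (1.0, 1.8053, 0.8355748783592077),  # 1 - e^{-1.8053}
        ],
    )
    def test_values(self, t, k_b, expected):
        assert burst_fraction(t, k_b) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            burst_fraction(-1.0, 1.0)
        with pytest.raises(ValueError):
            burst_fraction(1.0, 0.0)


class TestDegradation:
    @pytest.mark.parametrize(
        "t, k_r, t_max, expected",
        [
            (20.1849, 0.1109, 20.1849, 0.5),  # sigmoid midpoint
            (1e6, 0.1109, 20.1849, 1.0),
            (0.0, 0.1109, 20.1849, 0.09634558689122301),  # 1/(1+e^{2.2385})
        ],
    )
    def test_values(self, t, k_r, t_max, expected):
        assert degradation_fraction(t, k_r, t_max) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("k_r, t_max", [(0.0, 1.0), (1.0, 0.0), (-1.0, 1.0)])
    def test_domain_errors(self, k_r, t_max):
        with pytest.raises(ValueError):
            degradation_fraction(1.0, k_r, t_max)


class TestDiffusion:
    def test_exact_zero_at_t0(self):
        assert diffusion_fraction(0.0, 3.4908e-18) == 0.0

    def test_asymptote(self, geom):
        assert diffusion_fraction(1e9, 9.2404e-18, geom) == pytest.approx(1.0)

    def test_table_diffusivity_at_5_days(self, geom):
        # frozen from an independent 1e5-term summation of the series
        val = diffusion_fraction(5.0, 3.4908e-18, geom, tol=1e-12)
        assert val == pytest.approx(0.49574820753878557, abs=1e-9)

    def test_truncation_convergence(self, geom):
        t = np.array([0.05, 0.5, 5.0])
        for tol in (1e-6, 1e-8, 1e-10):
            a = diffusion_fraction(t, 3.4908e-18, geom, tol=tol)
            b = diffusion_fraction(t, 3.4908e-18, geom, tol=tol / 2)
            assert np.max(np.abs(a - b)) < tol

    def test_max_terms_warning(self, geom):
        with pytest.warns(RuntimeWarning, match="max_terms"):
            diffusion_fraction(1e-9, 3.4908e-18, geom, tol=1e-12, max_terms=5)

    def test_domain_error(self, geom):
        with pytest.raises(ValueError):
            diffusion_fraction(1.0, -1e-18, geom)


class TestBRModel:
    def test_time_zero(self, br37):
        # theta_b * 0 + (1 - theta_b) * logistic(0)
        assert br_model(0.0, br37) == pytest.approx(0.0427, abs=2e-4)

    def test_at_t_max(self, br37):
        # burst is saturated (k_b * t_max ~ 36), relaxation at its midpoint
        assert br_model(20.1849, br37) == pytest.approx(0.7784, abs=2e-4)

    def test_asymptote(self, br37):
        assert br_model(1e6, br37) == pytest.approx(1.0)


class TestBRDModel:
    def test_degenerate_pure_burst(self, geom):
        p = MechanismParams(theta_b=1.0, theta_r=0.0, k_b=2.0, k_r=0.1,
                            t_max=10.0, D_e=1e-18)
        t = np.linspace(0, 27, 50)
        np.testing.assert_allclose(
            brd_model(t, p, geom), burst_fraction(t, 2.0), atol=1e-15
        )

    def test_57C_negligible_relaxation_weight(self, geom):
        # theta_r ~ 2.6e-9: the curve is burst + diffusion to that accuracy
        p = brd_params_at(57)
        t = np.linspace(0, 27, 60)
        expected = p.theta_b * burst_fraction(t, p.k_b) + p.theta_d * (
            diffusion_fraction(t, p.D_e, geom)
        )
        np.testing.assert_allclose(brd_model(t, p, geom), expected, atol=1e-8)

    def test_reduces_to_br_when_theta_d_zero(self, geom, br37):
        p = MechanismParams(
            theta_b=br37.theta_b, theta_r=1.0 - br37.theta_b,
            k_b=br37.k_b, k_r=br37.k_r, t_max=br37.t_max, D_e=1e-18,
        )
        t = np.linspace(0, 40, 200)
        np.testing.assert_allclose(
            brd_model(t, p, geom), br_model(t, br37), atol=1e-14
        )

    def test_weight_constraint_violation(self):
        with pytest.raises(ValueError):
            MechanismParams(theta_b=0.7, theta_r=0.5, k_b=1.0, k_r=0.1,
                            t_max=10.0, D_e=1e-18)


class TestContributions:
    def test_br_weights_and_sum(self, br37, dense_grid):
        dec = mechanism_contributions(dense_grid, br37)
        assert dec["weights"] == {"burst": 0.5567, "relaxation": pytest.approx(0.4433)}
        total = sum(dec["curves"].values())
        np.testing.assert_allclose(total, br_model(dense_grid, br37), atol=1e-15)

    def test_brd_weights_47C(self, geom, dense_grid):
        p = brd_params_at(47)
        dec = mechanism_contributions(dense_grid, p, geom)
        w = dec["weights"]
        assert (w["burst"], w["relaxation"], w["diffusion"]) == (
            0.3988, 0.0688, pytest.approx(0.5324),
        )
        total = sum(dec["curves"].values())
        np.testing.assert_allclose(total, brd_model(dense_grid, p, geom), atol=1e-15)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    theta_b=st.floats(0.0, 1.0),
    theta_r_frac=st.floats(0.0, 1.0),
    k_b=st.floats(0.05, 20.0),
    k_r=st.floats(0.01, 5.0),
    t_max=st.floats(0.5, 40.0),
    log_de=st.floats(-20.0, -15.0),
)
def test_models_bounded_and_nondecreasing(theta_b, theta_r_frac, k_b, k_r,
                                          t_max, log_de):
    """Any valid parameter set yields a curve in [0,1], nondecreasing in t."""
    t = np.linspace(0.0, 50.0, 300)
    br = MechanismParams(theta_b=theta_b, k_b=k_b, k_r=k_r, t_max=t_max)
    brd = MechanismParams(
        theta_b=theta_b, theta_r=(1 - theta_b) * theta_r_frac,
        k_b=k_b, k_r=k_r, t_max=t_max, D_e=10.0**log_de,
    )
    for f in (br_model(t, br), brd_model(t, brd)):
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(np.diff(f) >= -1e-12)
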