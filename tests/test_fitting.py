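"""Constrained least-squares estimation of the release models."""

import numpy as np
import pytest

from nanorelease import (
    BurstRelaxationModel,
    MechanismParams,
    NoiseSpec,
    ReleaseProfile,
    fit_br,
    fit_brd,
    generate_profile,
    goodness_of_fit,
)
from nanorelease.tables import brd_params_at


class TestGoodnessOfFit:
    def test_worked_adjustment_example(self):
        """R2=0.9929 with 25 points and 4 parameters adjusts to 0.99148."""
        obs = np.array([0.0, 1.0, 2.0, 4.0])
        # build a prediction with a known R2 analytically: SSres = (1-R2)*SStot
        r2_target = 0.9929
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        shift = np.sqrt((1 - r2_target) * ss_tot / obs.size)
        r2, _ = goodness_of_fit(obs, obs + shift, p=1)
        assert r2 == pytest.approx(r2_target, abs=1e-12)
        # the adjustment formula itself, at the tabulated bookkeeping
        r2_adj = 1 - (1 - 0.9929) * (25 - 1) / (25 - 4 - 1)
        assert r2_adj == pytest.approx(0.99148, abs=5e-6)

    def test_zero_parameters_reduces_to_r2(self):
        obs = np.array([0.1, 0.4, 0.5, 0.9])
        pred = obs + 0.05
        r2, r2_adj = goodness_of_fit(obs, pred, p=0)
        assert r2_adj == pytest.approx(r2)

    def test_perfect_fit(self):
        obs = np.array([0.1, 0.4, 0.5, 0.9, 1.0, 0.2])
        r2, r2_adj = goodness_of_fit(obs, obs, p=2)
        assert r2 == 1.0 and r2_adj == 1.0

    def test_adjusted_never_exceeds_r2(self):
        obs = np.array([0.1, 0.35, 0.58, 0.7, 0.9, 0.95, 0.99])
        pred = obs + np.linspace(-0.02, 0.02, obs.size)
        r2, r2_adj = goodness_of_fit(obs, pred, p=3)
        assert r2_adj <= r2

    def test_errors(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2, 3], [1, 2, 3], p=2)  # n <= p+1
        with pytest.raises(ValueError):
            goodness_of_fit([1.0, 1.0, 1.0, 1.0], [1, 1, 1, 1], p=1)  # no variance


class TestProfileValidation:
    def test_overshoot_flagged_but_accepted(self):
        with pytest.warns(UserWarning, match="overshoot"):
            prof = ReleaseProfile(
                times=np.arange(8.0), fractions=np.array(
                    [0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0, 1.02]
                ),
            )
        assert prof.n_points == 8

    def test_rejects_large_overshoot_and_bad_times(self):
        with pytest.raises(ValueError):
            ReleaseProfile(times=np.arange(6.0), fractions=np.array(
                [0, 0.1, 0.2, 0.3, 0.4, 1.2]))
        with pytest.raises(ValueError):
            ReleaseProfile(times=np.array([0.0, 1.0, 1.0, 2.0, 3.0, 4.0]),
                           fractions=np.zeros(6))


class TestBRFit:
    def test_noiseless_recovery(self, br37, noiseless_br37_profile):
        res = fit_br(noiseless_br37_profile)
        g = res.params
        for got, want in [(g.theta_b, br37.theta_b), (g.k_b, br37.k_b),
                          (g.k_r, br37.k_r), (g.t_max, br37.t_max)]:
            assert got == pytest.approx(want, rel=1e-4)
        assert res.p == 4 and res.n_dp == 30
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)
        assert not any(res.at_bound.values())

    def test_pure_burst_hits_weight_bound(self):
        p = MechanismParams(theta_b=1.0, k_b=2.0, k_r=0.2, t_max=10.0)
        prof = generate_profile(p, noise=NoiseSpec(sd=0.0))
        res = fit_br(prof)
        assert res.at_bound["theta_b"]
        assert res.params.theta_b == pytest.approx(1.0, abs=1e-6)
        assert res.params.k_b == pytest.approx(2.0, rel=1e-3)

    def test_reorder_invariance(self, br37, noiseless_br37_profile):
        t, y = noiseless_br37_profile.times, noiseless_br37_profile.fractions
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.size)
        a = BurstRelaxationModel().fit(t, y)
        b = BurstRelaxationModel().fit(t[perm], y[perm])
        assert a.params_.k_r == pytest.approx(b.params_.k_r, rel=1e-8)
        assert a.result_.residual_sum_of_squares == pytest.approx(
            b.result_.residual_sum_of_squares, abs=1e-12
        )

    def test_sklearn_surface(self, noiseless_br37_profile):
        est = BurstRelaxationModel()
        t = noiseless_br37_profile.times.reshape(-1, 1)  # column-vector form
        est.fit(t, noiseless_br37_profile.fractions)
        pred = est.predict(t)
        assert est.score(t, noiseless_br37_profile.fractions) == pytest.approx(1.0)
        assert pred.shape == (30,)
        assert est.get_params()["starts"] == "lattice"


class TestBRDFit:
    def test_noiseless_recovery_47C(self, geom):
        p = brd_params_at(47)
        prof = generate_profile(p, noise=NoiseSpec(sd=0.0), geom=geom)
        res = fit_brd(prof, geometry=geom)
        g = res.params
        assert g.theta_b == pytest.approx(p.theta_b, rel=1e-3)
        assert g.theta_r == pytest.approx(p.theta_r, rel=1e-3)
        assert g.k_b == pytest.approx(p.k_b, rel=1e-3)
        assert g.k_r == pytest.approx(p.k_r, rel=1e-3)
        assert g.t_max == pytest.approx(p.t_max, rel=1e-3)
        assert np.log10(g.D_e) == pytest.approx(np.log10(p.D_e), rel=1e-3)
        assert res.p == 6

    def test_nesting_against_br(self, geom, br37):
        """With zero diffusion weight the 6-parameter model collapses onto
        the 4-parameter one, and R2 cannot decrease with the extra terms."""
        p = MechanismParams(
            theta_b=br37.theta_b, theta_r=1.0 - br37.theta_b,
            k_b=br37.k_b, k_r=br37.k_r, t_max=br37.t_max, D_e=1e-20,
        )
        prof = generate_profile(p, noise=NoiseSpec(sd=0.0), geom=geom)
        res_br = fit_br(prof)
        res_brd = fit_brd(prof, geometry=geom)
        assert res_brd.params.theta_b == pytest.approx(
            res_br.params.theta_b, rel=0.01
        )
        assert res_brd.params.k_b == pytest.approx(res_br.params.k_b, rel=0.01)
        assert res_brd.r_squared >= res_br.r_squared - 1e-9
        assert res_brd.r_squared_adjusted <= res_brd.r_squared

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            prof = ReleaseProfile(times=np.arange(7.0),
                                  fractions=np.linspace(0, 0.9, 7))
            fit_brd(prof)
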