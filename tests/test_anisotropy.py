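"""Anisotropy binding models against brute-force equilibrium oracles,
and Kd recovery by nonlinear fitting."""
import warnings

import numpy as np
import pytest
from scipy.optimize import brentq

from pepforge.anisotropy import (CompetitiveModel, DirectModel,
                                 TitrationCurve, bound_fraction_competitive,
                                 bound_fraction_direct,
                                 competitive_anisotropy,
                                 default_competition_design,
                                 direct_anisotropy, fit_competitive,
                                 fit_direct, simulate_titration)


def oracle_direct(kd, lt, pt):
    """Bisection on free protein for the 1:1 mass balance."""
    if pt == 0:
        return 0.0
    pf = brentq(lambda p: p + lt * p / (kd + p) - pt, 0.0, pt,
                xtol=1e-30, rtol=8.9e-16)
    return pf / (kd + pf)


def oracle_competitive(kd1, kd2, pt, lst, lt):
    """Bisection on free protein for the three-species mass balance."""
    pf = brentq(lambda p: p + lst * p / (kd1 + p) + lt * p / (kd2 + p) - pt,
                0.0, pt, xtol=1e-30, rtol=8.9e-16)
    return pf / (kd1 + pf)


class TestDirectModel:
    def test_no_protein_gives_free_anisotropy(self):
        m = DirectModel(r0=0.05, rb=0.25, kd=13e-9, lt=50e-9, pt=0.0)
        assert direct_anisotropy(m) == 0.05

    def test_tight_binding_saturates(self):
        m = DirectModel(r0=0.05, rb=0.25, kd=1e-15, lt=50e-9, pt=100e-9)
        assert direct_anisotropy(m) == pytest.approx(0.25, abs=1e-6)

    def test_agrees_with_equilibrium_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(500):
            kd = 10 ** rng.uniform(-10, -5)
            lt = 10 ** rng.uniform(-9, -6)
            pt = 10 ** rng.uniform(-9, -5)
            assert bound_fraction_direct(kd, lt, pt) == pytest.approx(
                oracle_direct(kd, lt, pt), abs=1e-9)

    def test_zero_labeled_concentration_rejected(self):
        with pytest.raises(ValueError):
            bound_fraction_direct(1e-8, 0.0, 1e-7)

    def test_bound_fraction_within_unit_interval(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            fb = bound_fraction_direct(10 ** rng.uniform(-10, -4),
                                       10 ** rng.uniform(-9, -5),
                                       10 ** rng.uniform(-10, -4))
            assert -1e-12 <= fb <= 1.0 + 1e-12


class TestCompetitiveModel:
    def test_no_competitor_reduces_to_direct(self):
        fb = bound_fraction_competitive(13e-9, 1e-7, 250e-9, 50e-9, 0.0)
        assert fb == pytest.approx(
            bound_fraction_direct(13e-9, 50e-9, 250e-9), abs=1e-12)

    def test_infinitely_weak_competitor_is_direct(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fb = bound_fraction_competitive(13e-9, 1e3, 250e-9, 50e-9,
                                            1e-6)
        assert fb == pytest.approx(
            bound_fraction_direct(13e-9, 50e-9, 250e-9), abs=1e-9)

    def test_agrees_with_equilibrium_oracle(self):
        rng = np.random.default_rng(12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for _ in range(500):
                kd1 = 10 ** rng.uniform(-9, -6)
                kd2 = 10 ** rng.uniform(-9, -5)
                pt = 10 ** rng.uniform(-8, -5)
                lst = pt * rng.uniform(0.01, 0.9)
                lt = 10 ** rng.uniform(-9, -4)
                assert bound_fraction_competitive(kd1, kd2, pt, lst, lt) \
                    == pytest.approx(
                        oracle_competitive(kd1, kd2, pt, lst, lt),
                        abs=1e-9)

    def test_assay_assumption_violation_warns(self):
        with pytest.warns(RuntimeWarning, match="assay assumption"):
            CompetitiveModel(kd1=1e-8, kd2=1e-7, pt=40e-9, lst=50e-9,
                             lt=0.0, r0=0.05, rb=0.25)

    def test_anisotropy_between_endpoints(self):
        m = CompetitiveModel(kd1=13e-9, kd2=50e-9, pt=250e-9, lst=50e-9,
                             lt=1e-6, r0=0.05, rb=0.25)
        assert 0.05 <= competitive_anisotropy(m) <= 0.25


class TestSimulator:
    def test_noiseless_points_equal_model(self):
        m = DirectModel(r0=0.05, rb=0.25, kd=13e-9, lt=50e-9)
        design = np.logspace(-9, -6, 8)
        curve = simulate_titration(m, design, sigma=0.0, replicates=2)
        for c, a in zip(curve.conc, curve.anisotropy):
            want = direct_anisotropy(DirectModel(
                r0=0.05, rb=0.25, kd=13e-9, lt=50e-9, pt=c))
            assert a == pytest.approx(want, abs=1e-12)

    def test_seed_determinism(self):
        m = DirectModel(r0=0.05, rb=0.25, kd=13e-9, lt=50e-9)
        design = np.logspace(-9, -6, 8)
        c1 = simulate_titration(m, design, sigma=0.01, seed=4)
        c2 = simulate_titration(m, design, sigma=0.01, seed=4)
        assert np.array_equal(c1.anisotropy, c2.anisotropy)

    def test_direct_response_monotone_in_protein(self):
        m = DirectModel(r0=0.05, rb=0.25, kd=13e-9, lt=50e-9)
        design = np.logspace(-10, -5, 20)
        curve = simulate_titration(m, design, sigma=0.0, replicates=1)
        assert (np.diff(curve.anisotropy) >= -1e-12).all()


class TestFitting:
    def test_direct_noiseless_recovery(self):
        true = DirectModel(r0=0.05, rb=0.25, kd=13e-9, lt=50e-9)
        design = 250e-9 * 2.0 ** np.arange(-7, 6)
        curve = simulate_titration(true, design, sigma=0.0, replicates=1)
        fit = fit_direct(curve, lt=50e-9)
        assert fit.converged
        assert fit.params["kd"] == pytest.approx(13e-9, rel=1e-6)
        assert fit.params["r0"] == pytest.approx(0.05, abs=1e-8)
        assert fit.params["rb"] == pytest.approx(0.25, abs=1e-8)

    def test_degenerate_design_rejected(self):
        curve = TitrationCurve(conc=np.full(8, 1e-7),
                               anisotropy=np.full(8, 0.1),
                               replicate=np.zeros(8, dtype=int))
        with pytest.raises(ValueError, match="degenerate design"):
            fit_direct(curve, lt=50e-9)

    def test_competitive_noiseless_recovery(self):
        true = CompetitiveModel(kd1=13e-9, kd2=80e-9, pt=250e-9, lst=50e-9,
                                lt=0.0, r0=0.05, rb=0.25)
        curve = simulate_titration(true, default_competition_design(),
                                   sigma=0.0, replicates=1)
        fit = fit_competitive(curve, kd1=13e-9)
        assert fit.converged
        assert fit.params["kd2"] == pytest.approx(80e-9, rel=1e-6)

    def test_flat_curve_flags_unidentifiable_kd2(self):
        true = CompetitiveModel(kd1=13e-9, kd2=1.0, pt=250e-9, lst=50e-9,
                                lt=0.0, r0=0.05, rb=0.25)
        curve = simulate_titration(true, default_competition_design(),
                                   sigma=0.0, replicates=1)
        fit = fit_competitive(curve, kd1=13e-9)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_baseline_below_free_peptide_warns(self):
        true = CompetitiveModel(kd1=13e-9, kd2=5e-9, pt=250e-9, lst=50e-9,
                                lt=0.0, r0=0.05, rb=0.25)
        curve = simulate_titration(true, default_competition_design(
            n=12, top=1e-3), sigma=0.0, replicates=1)
        # corrupt the high-competitor tail below the free-peptide value,
        # as an unintended competitor-tracer interaction would
        tail = curve.conc >= np.sort(np.unique(curve.conc))[-3]
        curve.anisotropy[tail] = 0.02
        with pytest.warns(RuntimeWarning, match="free-peptide"):
            fit = fit_competitive(curve, kd1=13e-9)
        assert any("baseline" in f for f in fit.flags)

    def test_recovery_under_noise(self):
        """Across simulated noisy assays the median log-Kd error stays
        within a tenth of a log unit (reduced-size version of the full
        simulation study in the acceptance suite)."""
        rng = np.random.default_rng(77)
        errs = []
        for k in range(30):
            kd2 = 10 ** rng.uniform(-8.5, -6.5)
            true = CompetitiveModel(kd1=13e-9, kd2=kd2, pt=250e-9,
                                    lst=50e-9, lt=0.0, r0=0.05, rb=0.25)
            curve = simulate_titration(true, default_competition_design(),
                                       sigma=0.005, replicates=3,
                                       seed=1000 + k)
            fit = fit_competitive(curve, kd1=13e-9)
            errs.append(abs(np.log10(fit.params["kd2"] / kd2)))
        assert np.median(errs) < 0.1
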