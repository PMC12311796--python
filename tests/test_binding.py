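"""Binding models: closed forms, independent oracles, self-inversion."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from g4se.binding import (
    FrapRecoveryModel,
    HillBindingModel,
    KineticParams,
    SprKineticsModel,
    TwoSiteBindingModel,
    fit_frap,
    fit_hill,
    fit_spr,
    fit_two_site,
    frap_curve,
    hill_curve,
    spr_trace,
    two_site_free_fraction,
)
from g4se.simulate import simulate_binding_trace


class TestTwoSiteForward:
    def test_no_protein_gives_free_fraction_one(self):
        assert two_site_free_fraction(12.0, 1e-12, 6.0) == pytest.approx(1.0)

    def test_tight_binding_excess_sites_gives_zero(self):
        # K_d -> 0 with S_T = 2B >= G: everything bound
        assert two_site_free_fraction(10.0, 6.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_matches_mass_action_root_oracle(self):
        """The quadratic root equals the solution of the mass-action balance
        K_d*C = (G-C)(S-C) found by an independent bracketed root search."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            G = float(rng.uniform(0.1, 100))
            B = float(rng.uniform(0.01, 100))
            Kd = float(10 ** rng.uniform(-3, 3))
            S = 2 * B
            C_oracle = brentq(
                lambda C: Kd * C - (G - C) * (S - C), 0, min(G, S), xtol=1e-14,
                rtol=1e-15,
            )
            f = two_site_free_fraction(G, B, Kd)
            assert f == pytest.approx((G - C_oracle) / G, abs=1e-10)

    def test_monotone_in_kd_and_protein(self):
        kds = np.geomspace(0.01, 100, 20)
        f = [two_site_free_fraction(12.0, 4.2, k) for k in kds]
        assert np.all(np.diff(f) > 0)
        bs = np.linspace(0.1, 50, 20)
        f2 = [two_site_free_fraction(12.0, b, 6.0) for b in bs]
        assert np.all(np.diff(f2) < 0)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            two_site_free_fraction(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            two_site_free_fraction(1.0, 1.0, 0.0)


class TestTwoSiteFit:
    def design(self, kd=6.0):
        # titration regime: ~12 uM folded G4, protein up to 8.4 uM
        B = np.array([1.4, 2.8, 4.2, 5.6, 7.0, 8.4])
        G = np.full_like(B, 12.0)
        y = two_site_free_fraction(G, B, kd)
        return np.column_stack([G, B, y])

    def test_noise_free_recovery_to_three_digits(self):
        fit = fit_two_site(self.design(kd=6.0), n_boot=0)
        assert fit.params["K_d"] == pytest.approx(6.0, rel=1e-4)
        assert np.allclose(fit.residuals, 0, atol=1e-10)

    def test_unidentifiable_when_all_intensities_at_one(self):
        obs = self.design()
        obs[:, 2] = 1.0
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_two_site(obs, n_boot=0)
        assert any("unidentifiable" in f for f in fit.flags)

    def test_noisy_recovery_within_30_percent(self):
        """Median recovered K_d over 200 seeds within +/-30% of truth at
        realistic noise (sd 0.02, 5 signals per titration point)."""
        kds = []
        for seed in range(200):
            df, _ = simulate_binding_trace(
                "two_site", {"K_d": 6.0},
                design={"B_total": [1.4, 2.8, 4.2, 5.6, 7.0, 8.4], "n_signals": 5},
                noise_sd=0.02, seed=seed,
            )
            obs = df[df.B_total > 0][["G_total", "B_total", "intensity"]].to_numpy()
            kds.append(fit_two_site(obs, n_boot=0).params["K_d"])
        med = float(np.median(kds))
        assert 0.7 * 6.0 <= med <= 1.3 * 6.0

    def test_bootstrap_ci_brackets_truth_noise_free(self):
        fit = fit_two_site(self.design(kd=6.0), n_boot=50, random_state=1)
        lo, hi = fit.ci["K_d"]
        assert lo <= 6.0 <= hi or abs(fit.params["K_d"] - 6.0) < 1e-3


class TestSpr:
    params = KineticParams(k_a=0.01, k_d=0.05, r_max=120.0)

    def test_equilibrium_plateau(self):
        t = np.array([1e6])
        for C in (1.0, 5.0, 25.0):
            r = spr_trace(self.params, C, t, t_assoc=2e6)
            r_eq = self.params.r_max * C / (C + self.params.K_d)
            assert r[0] == pytest.approx(r_eq, rel=1e-9)

    def test_half_saturation_at_kd(self):
        C = self.params.K_d
        r = spr_trace(self.params, C, np.array([1e7]), t_assoc=2e7)
        assert r[0] == pytest.approx(self.params.r_max / 2, rel=1e-9)

    def test_closed_form_matches_ode_integration(self):
        """dR/dt = k_a C (R_max - R) - k_d R, then pure dissociation."""
        C, t_assoc = 25.0, 120.0
        t = np.linspace(0, 300, 301)
        closed = spr_trace(self.params, C, t, t_assoc)

        def assoc(_t, R):
            return self.params.k_a * C * (self.params.r_max - R[0]) - \
                self.params.k_d * R[0]

        sol_a = solve_ivp(assoc, (0, t_assoc), [0.0], t_eval=t[t <= t_assoc],
                          rtol=1e-12, atol=1e-12)
        r_end = sol_a.y[0][-1]

        def dissoc(_t, R):
            return -self.params.k_d * R[0]

        sol_d = solve_ivp(dissoc, (t_assoc, 300), [r_end],
                          t_eval=t[t > t_assoc], rtol=1e-12, atol=1e-12)
        ode = np.concatenate([sol_a.y[0], sol_d.y[0]])
        assert np.max(np.abs(closed - ode)) < 1e-8

    def test_noise_free_global_fit_recovery(self):
        df, _ = simulate_binding_trace(
            "spr", {"k_a": 0.01, "k_d": 0.05, "r_max": 120.0}, noise_sd=0.0
        )
        traces = [(c, g.time.to_numpy(), g.response.to_numpy())
                  for c, g in df.groupby("concentration")]
        fit = fit_spr(traces, t_assoc=120.0)
        assert fit.params["k_a"] == pytest.approx(0.01, rel=1e-4)
        assert fit.params["k_d"] == pytest.approx(0.05, rel=1e-4)
        assert fit.params["K_d"] == pytest.approx(5.0, rel=1e-4)

    def test_duplicate_traces_do_not_change_fit(self):
        df, _ = simulate_binding_trace(
            "spr", {"k_a": 0.01, "k_d": 0.05, "r_max": 120.0}, noise_sd=0.0
        )
        traces = [(c, g.time.to_numpy(), g.response.to_numpy())
                  for c, g in df.groupby("concentration")]
        single = fit_spr(traces, t_assoc=120.0)
        doubled = fit_spr(traces + traces, t_assoc=120.0)
        assert doubled.params["K_d"] == pytest.approx(single.params["K_d"], rel=1e-6)

    def test_noisy_recovery_within_25_percent(self):
        """K_d within +/-25% of truth over seeds at SNR ~ 20."""
        kds = []
        for seed in range(40):
            df, _ = simulate_binding_trace(
                "spr", {"k_a": 0.01, "k_d": 0.05, "r_max": 120.0},
                design={"dt": 2.0}, noise_sd=5.0, seed=seed,
            )
            traces = [(c, g.time.to_numpy(), g.response.to_numpy())
                      for c, g in df.groupby("concentration")]
            kds.append(fit_spr(traces, t_assoc=120.0).params["K_d"])
        assert abs(np.median(kds) - 5.0) <= 0.25 * 5.0

    def test_kd_identity_holds(self):
        p = KineticParams(0.02, 0.08, 100.0)
        assert p.K_d == pytest.approx(p.k_d / p.k_a, rel=1e-15)


class TestHill:
    def test_midpoint_at_ec50_with_h1(self):
        f = hill_curve(10.0, 0.2, 0.8, 10.0, 1.0)
        assert f == pytest.approx(0.5)

    def test_noise_free_self_inversion(self):
        L = 200.0 / 2 ** np.arange(12)[::-1]
        y = hill_curve(L, 0.1, 0.9, 12.0, 1.7)
        fit = fit_hill(np.column_stack([L, y]))
        assert fit.params["EC50"] == pytest.approx(12.0, rel=1e-4)
        assert fit.params["h"] == pytest.approx(1.7, rel=1e-4)

    def test_fixed_h_reduces_to_hyperbolic(self):
        L = 200.0 / 2 ** np.arange(12)[::-1]
        y = hill_curve(L, 0.0, 1.0, 8.0, 1.0)
        free = fit_hill(np.column_stack([L, y]))
        fixed = fit_hill(np.column_stack([L, y]), fix_h=1.0)
        assert fixed.params["EC50"] == pytest.approx(free.params["EC50"], rel=1e-3)
        assert fixed.params["h"] == 1.0

    def test_flat_curve_flagged(self):
        L = np.array([1.0, 2.0, 4.0, 8.0])
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_hill(np.column_stack([L, np.full(4, 0.5)]))
        assert fit.flags


class TestFrap:
    def test_noise_free_self_inversion(self):
        t = np.arange(0, 10, 1 / 6)
        y = frap_curve(t, 0.25, 1.0)
        fit = fit_frap(t, y)
        assert fit.params["plateau"] == pytest.approx(0.25, rel=1e-4)
        assert fit.params["k"] == pytest.approx(1.0, rel=1e-4)

    def test_flat_curve_flagged_as_immobile(self):
        t = np.arange(0, 10, 0.5)
        with pytest.warns(UserWarning, match="immobile"):
            fit = fit_frap(t, np.zeros_like(t))
        assert fit.params["plateau"] == pytest.approx(0.0, abs=1e-3)

    def test_halving_rate_doubles_half_recovery_time(self):
        # t_half = ln(2)/k from the closed form
        for k in (0.5, 1.0, 2.0):
            t_half = np.log(2) / k
            assert frap_curve(t_half, 1.0, k) == pytest.approx(0.5)


class TestEstimatorInterface:
    """The fitters behave as sklearn estimators."""

    def test_get_set_params_round_trip(self):
        m = TwoSiteBindingModel(n_boot=7)
        assert m.get_params()["n_boot"] == 7
        m.set_params(n_boot=3)
        assert m.n_boot == 3

    def test_fitted_attributes_and_predict(self):
        B = np.array([1.4, 2.8, 4.2, 5.6, 7.0, 8.4])
        X = np.column_stack([np.full_like(B, 12.0), B])
        y = two_site_free_fraction(X[:, 0], X[:, 1], 6.0)
        m = TwoSiteBindingModel(n_boot=0).fit(X, y)
        assert hasattr(m, "kd_") and hasattr(m, "residuals_")
        assert np.allclose(m.predict(X), y, atol=1e-8)
        r2 = m.score(X, y)
        assert r2 == pytest.approx(1.0, abs=1e-8)

    def test_clone_compatibility(self):
        from sklearn.base import clone

        for est in (TwoSiteBindingModel(), HillBindingModel(fix_h=1.0),
                     SprKineticsModel(t_assoc=120.0), FrapRecoveryModel()):
            c = clone(est)
            assert c.get_params() == est.get_params()
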