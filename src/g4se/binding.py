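"""Equilibrium and kinetic binding models with least-squares fitters.

Four measurement models are implemented, each as a forward function plus an
sklearn-style estimator (``fit``/``predict``, fitted attributes with trailing
underscores), so they compose with sklearn model-selection utilities:

* Two-site equilibrium binding — a receptor (G4 DNA) titrated with a protein
  (BRD4) carrying two equivalent, independent binding sites (its two
  bromodomains). The observable is the free fraction of the receptor
  (imino-proton NMR signal intensity, normalized to a buffer control), and
  the single fitted parameter is the per-site dissociation constant K_d
  defined by K_d = [G4]_free x [BD]_free / [BD.G4].
* Hill binding — dose-response of normalized fluorescence (thermophoresis)
  vs ligand concentration, with EC50 and Hill coefficient h.
* 1:1 interaction kinetics (surface plasmon resonance) — association
  R(t) = R_eq (1 - exp(-(k_a C + k_d) t)) with R_eq = R_max C / (C + K_D),
  dissociation R(t) = R(t_assoc) exp(-k_d (t - t_assoc)); K_D = k_d / k_a.
* Mono-exponential recovery after photobleaching —
  I(t) = plateau (1 - exp(-k t)); the plateau is the mobile fraction.

Units: concentrations in uM, SPR time in seconds, recovery time in minutes.
Every fitter inverts its own noise-free forward model (see the test suite);
multi-start least squares guards against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BindingFit",
    "KineticParams",
    "HillParams",
    "FrapParams",
    "two_site_free_fraction",
    "spr_trace",
    "hill_curve",
    "frap_curve",
    "TwoSiteBindingModel",
    "HillBindingModel",
    "SprKineticsModel",
    "FrapRecoveryModel",
    "fit_two_site",
    "fit_hill",
    "fit_spr",
    "fit_frap",
]


# ---------------------------------------------------------------- containers


@dataclass
class KineticParams:
    """1:1 kinetic constants; K_d (equilibrium) is k_d/k_a by construction."""

    k_a: float  # 1/(uM s)
    k_d: float  # 1/s
    r_max: float  # response units

    @property
    def K_d(self) -> float:
        return self.k_d / self.k_a


@dataclass
class HillParams:
    f_unbound: float
    f_bound: float
    ec50: float  # uM
    h: float


@dataclass
class FrapParams:
    plateau: float  # mobile fraction
    k: float  # 1/min


@dataclass
class BindingFit:
    """Fitted parameters with residual diagnostics."""

    params: dict
    residuals: np.ndarray
    ci: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))


# ------------------------------------------------------------ forward models


def two_site_free_fraction(G_total, B_total, K_d):
    """Free fraction of G4 at equilibrium with a two-site protein.

    With S_total = 2 B_total binding sites, mass action gives the bound
    complex concentration C as the admissible root of
    C^2 - (G_T + S_T + K_d) C + G_T S_T = 0, i.e.
    C = ((G_T + S_T + K_d) - sqrt((G_T + S_T + K_d)^2 - 4 G_T S_T)) / 2,
    which satisfies 0 <= C <= min(G_T, S_T). Returns (G_T - C)/G_T.
    Accepts scalars or arrays; B_total may be 0 (free fraction 1).
    """
    G = np.asarray(G_total, dtype=float)
    B = np.asarray(B_total, dtype=float)
    if np.any(G <= 0):
        raise ValueError("G_total must be > 0")
    if np.any(B < 0) or (np.ndim(K_d) == 0 and K_d <= 0):
        raise ValueError("B_total must be >= 0 and K_d > 0")
    S = 2.0 * B
    s = G + S + K_d
    C = (s - np.sqrt(s * s - 4.0 * G * S)) / 2.0
    out = (G - C) / G
    return out if out.ndim else float(out)


def spr_trace(params: KineticParams, C: float, t: np.ndarray, t_assoc: float):
    """Closed-form 1:1 sensogram at analyte concentration C (uM).

    Association for t <= t_assoc, exponential dissociation afterwards.
    """
    t = np.asarray(t, dtype=float)
    k_obs = params.k_a * C + params.k_d
    r_eq = params.r_max * C / (C + params.K_d)
    r_assoc = r_eq * (1.0 - np.exp(-k_obs * np.minimum(t, t_assoc)))
    r_end = r_eq * (1.0 - np.exp(-k_obs * t_assoc))
    r_dissoc = r_end * np.exp(-params.k_d * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, r_assoc, r_dissoc)


def hill_curve(L, f_unbound, f_bound, ec50, h):
    L = np.asarray(L, dtype=float)
    Lh = np.power(L, h)
    return f_unbound + (f_bound - f_unbound) * Lh / (np.power(ec50, h) + Lh)


def frap_curve(t, plateau, k):
    t = np.asarray(t, dtype=float)
    return plateau * (1.0 - np.exp(-k * t))


# -------------------------------------------------------------- estimators


def _multistart_least_squares(residual_fn, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual_fn, x0, bounds=bounds)
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best


class TwoSiteBindingModel(BaseEstimator, RegressorMixin):
    """Single-parameter K_d fit of the two-site equilibrium model.

    X is an (n, 2) array of (G_total, B_total) in uM; y is the normalized
    free fraction in (0, 1]. Each observation (e.g. each imino-proton signal
    at a titration point) is treated as an independent measurement of the
    same free fraction; no per-observation scale factor is fitted.

    Attributes
    ----------
    kd_ : fitted dissociation constant (uM)
    residuals_ : y - predicted
    kd_ci_ : (lo, hi) percentile bootstrap CI, if n_boot > 0
    flags_ : list of data-quality warnings
    """

    def __init__(self, kd_bounds=(1e-4, 1e5), n_starts=5, n_boot=200, random_state=0):
        self.kd_bounds = kd_bounds
        self.n_starts = n_starts
        self.n_boot = n_boot
        self.random_state = random_state

    def _fit_kd(self, G, B, y):
        def resid(logkd):
            return two_site_free_fraction(G, B, 10.0 ** logkd[0]) - y

        starts = np.log10(
            np.geomspace(self.kd_bounds[0] * 10, self.kd_bounds[1] / 10, self.n_starts)
        )[:, None]
        lo, hi = np.log10(self.kd_bounds)
        best = _multistart_least_squares(resid, starts, ([lo], [hi]))
        return 10.0 ** best.x[0]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (G_total, B_total)")
        if len(X) < 1:
            raise ValueError("need at least one observation")
        self.flags_ = []
        if np.all(y >= 1.0):
            self.flags_.append("all intensities >= 1: K_d unidentifiable")
            warnings.warn("all free fractions >= 1; K_d is unidentifiable")
        G, B = X[:, 0], X[:, 1]
        self.kd_ = self._fit_kd(G, B, y)
        self.residuals_ = y - two_site_free_fraction(G, B, self.kd_)
        if self.n_boot > 0 and len(y) > 1:
            rng = np.random.default_rng(self.random_state)
            fitted = y - self.residuals_
            boots = []
            for _ in range(self.n_boot):
                y_b = fitted + rng.choice(self.residuals_, size=len(y), replace=True)
                try:
                    boots.append(self._fit_kd(G, B, y_b))
                except RuntimeError:
                    continue
            if boots:
                self.kd_ci_ = (
                    float(np.percentile(boots, 2.5)),
                    float(np.percentile(boots, 97.5)),
                )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return two_site_free_fraction(X[:, 0], X[:, 1], self.kd_)


class HillBindingModel(BaseEstimator, RegressorMixin):
    """Hill-model fit of a dose-response curve.

    X is the ligand concentration (uM, shape (n,) or (n, 1)); y the
    normalized signal. ``fix_h`` pins the Hill coefficient (e.g. 1 for
    hyperbolic saturation).
    """

    def __init__(self, fix_h=None, max_h=8.0):
        self.fix_h = fix_h
        self.max_h = max_h

    def fit(self, X, y):
        L = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        if len(L) < 4:
            raise ValueError("need >= 4 points for a Hill fit")
        self.flags_ = []
        if np.ptp(y) < 1e-12:
            self.flags_.append("no curvature: parameters unidentifiable")
            warnings.warn("flat dose-response; Hill parameters unidentifiable")
        f_lo = y[np.argmin(L)]
        f_hi = y[np.argmax(L)]
        ec50_0 = np.median(L[L > 0]) if np.any(L > 0) else 1.0
        span = max(np.ptp(y), 1e-6)
        lo_f = min(y.min(), f_lo) - 2 * span
        hi_f = max(y.max(), f_hi) + 2 * span

        if self.fix_h is None:
            def resid(p):
                return hill_curve(L, p[0], p[1], 10.0 ** p[2], p[3]) - y

            starts = [
                [f_lo, f_hi, np.log10(ec50_0 * s), h0]
                for s in (0.1, 1.0, 10.0)
                for h0 in (1.0, 2.0)
            ]
            bounds = ([lo_f, lo_f, -6, 0.05], [hi_f, hi_f, 6, self.max_h])
            best = _multistart_least_squares(resid, starts, bounds)
            self.f_unbound_, self.f_bound_ = best.x[0], best.x[1]
            self.ec50_, self.h_ = 10.0 ** best.x[2], best.x[3]
        else:
            h = float(self.fix_h)

            def resid(p):
                return hill_curve(L, p[0], p[1], 10.0 ** p[2], h) - y

            starts = [[f_lo, f_hi, np.log10(ec50_0 * s)] for s in (0.1, 1.0, 10.0)]
            bounds = ([lo_f, lo_f, -6], [hi_f, hi_f, 6])
            best = _multistart_least_squares(resid, starts, bounds)
            self.f_unbound_, self.f_bound_ = best.x[0], best.x[1]
            self.ec50_, self.h_ = 10.0 ** best.x[2], h
        self.residuals_ = y - self.predict(L)
        return self

    def predict(self, X):
        L = np.asarray(X, dtype=float).ravel()
        return hill_curve(L, self.f_unbound_, self.f_bound_, self.ec50_, self.h_)

    @property
    def params_(self) -> HillParams:
        return HillParams(self.f_unbound_, self.f_bound_, self.ec50_, self.h_)


class SprKineticsModel(BaseEstimator, RegressorMixin):
    """Global 1:1 kinetic fit over sensograms at several concentrations.

    X is an (n, 2) array of (analyte concentration uM, time s); y the
    response. All rows share k_a, k_d, R_max. The association phase ends at
    ``t_assoc`` seconds.
    """

    def __init__(self, t_assoc: float, n_starts=3, random_state=0):
        self.t_assoc = t_assoc
        self.n_starts = n_starts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have columns (concentration, time)")
        conc, t = X[:, 0], X[:, 1]
        self.flags_ = []
        if len(np.unique(conc)) < 2:
            self.flags_.append("single analyte concentration: fit poorly constrained")
            warnings.warn("SPR fit from a single concentration is poorly constrained")

        def model(p):
            ka, kd, rmax = 10.0 ** p
            out = np.empty_like(y)
            for c in np.unique(conc):
                m = conc == c
                out[m] = spr_trace(KineticParams(ka, kd, rmax), c, t[m], self.t_assoc)
            return out

        def resid(p):
            return model(p) - y

        rmax0 = max(y.max(), 1e-6) * 1.5
        starts = [
            [lka, lkd, np.log10(rmax0)]
            for lka in (-3.0, -2.0, -1.0)
            for lkd in (-3.0, -2.0, -1.0)
        ]
        bounds = ([-8, -8, -6], [4, 4, 8])
        best = _multistart_least_squares(resid, starts, bounds)
        ka, kd, rmax = 10.0 ** best.x
        self.params_ = KineticParams(k_a=ka, k_d=kd, r_max=rmax)
        self.ka_, self.kdis_, self.rmax_ = ka, kd, rmax
        self.KD_ = self.params_.K_d
        self.residuals_ = y - model(best.x)
        # non-monotone association beyond noise suggests a non-1:1 mechanism;
        # smooth before differencing so single noisy points do not trigger it
        for c in np.unique(conc):
            m = (conc == c) & (t <= self.t_assoc)
            if m.sum() >= 10:
                yy = y[m][np.argsort(t[m])]
                w = 5
                smooth = np.convolve(yy, np.ones(w) / w, mode="valid")
                noise = np.std(self.residuals_[m]) + 1e-12
                if np.min(np.diff(smooth)) < -3 * noise / np.sqrt(w):
                    self.flags_.append(
                        f"non-monotone association phase at C={c} beyond noise"
                    )
                    warnings.warn("non-monotone association phase beyond noise")
                    break
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        conc, t = X[:, 0], X[:, 1]
        out = np.empty(len(X))
        for c in np.unique(conc):
            m = conc == c
            out[m] = spr_trace(self.params_, c, t[m], self.t_assoc)
        return out


class FrapRecoveryModel(BaseEstimator, RegressorMixin):
    """Mono-exponential recovery fit I(t) = plateau (1 - exp(-k t)).

    X is time after bleach (minutes); y the bleach-normalized intensity
    (0 at t = 0, 1 = pre-bleach). ``plateau_`` is the mobile fraction.
    """

    def __init__(self, plateau_max=1.5):
        self.plateau_max = plateau_max

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float)
        self.flags_ = []

        def resid(p):
            return frap_curve(t, p[0], 10.0 ** p[1]) - y

        p0 = max(y.max(), 1e-3)
        starts = [[p0, lk] for lk in (-2.0, -1.0, 0.0, 1.0)]
        bounds = ([0.0, -4], [self.plateau_max, 3])
        best = _multistart_least_squares(resid, starts, bounds)
        self.plateau_, self.k_ = best.x[0], 10.0 ** best.x[1]
        self.residuals_ = y - frap_curve(t, self.plateau_, self.k_)
        if self.plateau_ < 0.02:
            self.flags_.append("non-recovering curve: plateau ~ 0")
            warnings.warn("recovery plateau ~ 0: immobile sample")
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).ravel()
        return frap_curve(t, self.plateau_, self.k_)

    @property
    def params_(self) -> FrapParams:
        return FrapParams(self.plateau_, self.k_)


# ------------------------------------------------------- function wrappers


def fit_two_site(observations, n_boot=200, random_state=0) -> BindingFit:
    """Fit K_d from (G_total, B_total, free_fraction) observations."""
    obs = np.asarray(observations, dtype=float)
    est = TwoSiteBindingModel(n_boot=n_boot, random_state=random_state)
    est.fit(obs[:, :2], obs[:, 2])
    ci = {"K_d": est.kd_ci_} if hasattr(est, "kd_ci_") else {}
    return BindingFit(
        params={"K_d": est.kd_}, residuals=est.residuals_, ci=ci, flags=est.flags_
    )


def fit_hill(points, fix_h=None) -> BindingFit:
    """Fit Hill parameters from (ligand_conc, signal) pairs."""
    pts = np.asarray(points, dtype=float)
    est = HillBindingModel(fix_h=fix_h).fit(pts[:, 0], pts[:, 1])
    p = est.params_
    return BindingFit(
        params={
            "f_unbound": p.f_unbound,
            "f_bound": p.f_bound,
            "EC50": p.ec50,
            "h": p.h,
        },
        residuals=est.residuals_,
        flags=est.flags_,
    )


def fit_spr(traces, t_assoc) -> BindingFit:
    """Global 1:1 fit from a list of (concentration, times, responses)."""
    rows_X, rows_y = [], []
    for c, t, r in traces:
        t = np.asarray(t, dtype=float)
        r = np.asarray(r, dtype=float)
        rows_X.append(np.column_stack([np.full(len(t), float(c)), t]))
        rows_y.append(r)
    X = np.vstack(rows_X)
    y = np.concatenate(rows_y)
    est = SprKineticsModel(t_assoc=t_assoc).fit(X, y)
    return BindingFit(
        params={
            "k_a": est.ka_,
            "k_d": est.kdis_,
            "R_max": est.rmax_,
            "K_d": est.KD_,
        },
        residuals=est.residuals_,
        flags=est.flags_,
    )


def fit_frap(times, intensities) -> BindingFit:
    """Fit mobile fraction and rate from a normalized recovery curve."""
    est = FrapRecoveryModel().fit(times, intensities)
    return BindingFit(
        params={"plateau": est.plateau_, "k": est.k_},
        residuals=est.residuals_,
        flags=est.flags_,
    )
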