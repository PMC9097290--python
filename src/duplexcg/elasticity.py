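"""Inference of elastic constants and persistence lengths from trajectories.

The duplex under force f and torque tau is modeled as a linear elastic rod
with stretching modulus S (pN), twist modulus C (pN nm^2) and twist-stretch
coupling g (pN nm).  Minimizing the rod energy gives the linear equilibrium
response

    dL     = (L0/S~) f - (g L0 / (C S~)) tau
    dtheta = -(g L0 / (C S~)) f + (L0/C)(1 + g^2/(C S~)) tau

with S~ = S - g^2/C the effective stretching modulus measured at zero
torque.  Two extraction routes are implemented:

* benchmark route — slopes A1 (dL vs f) and A2 (dtheta vs f) at tau = 0 plus
  the equipartition relation var(dtheta) = kB T L0 / C (the twist-stretch
  coupling term is neglected in that relation, as is conventional);
* stretch-torsion route — slopes A1 (dL vs f at tau = 0), A3 (dL vs tau) and
  A4 (dtheta vs tau) at constant f, inverted in closed form.

g < 0 means the duplex overwinds when stretched (dtheta grows with f), which
shows up as a positive A3.

Persistence lengths come from tangent-vector correlations: c_p from the
thermal ensemble, c_s from the minimum-energy structure, and the dynamic
part c_d = c_p / c_s, so the harmonic relation 1/l_p = 1/l_s + 1/l_d holds
exactly by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import CONSTANTS


class FitError(ValueError):
    pass


class InversionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Monte-Carlo linear fits
# ---------------------------------------------------------------------------

@dataclass
class LinearFit:
    slope: float
    intercept: float
    slope_err: float
    intercept_err: float


def fit_linear_mc(x, y, dy=None, n_draws: int = 10_000,
                  seed: int = 0) -> LinearFit:
    """Straight-line fit with Monte-Carlo error propagation.

    The central values are the ordinary least-squares estimates.  Errors are
    the standard deviations of the fit parameters over ``n_draws`` refits in
    which each y_i is resampled from a Gaussian of mean y_i and standard
    deviation dy_i.  With ``dy=None`` (or all zero) the errors are zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise FitError("need at least 3 points")
    slope, intercept = np.polyfit(x, y, 1)
    if dy is None:
        return LinearFit(float(slope), float(intercept), 0.0, 0.0)
    dy = np.broadcast_to(np.asarray(dy, dtype=float), y.shape)
    if np.any(dy < 0):
        raise FitError("dy must be nonnegative")
    if np.all(dy == 0):
        return LinearFit(float(slope), float(intercept), 0.0, 0.0)
    rng = np.random.default_rng(seed)
    draws = y[None, :] + rng.normal(0.0, 1.0, size=(n_draws, len(y))) * dy[None, :]
    # vectorized least squares over all draws
    xm = x - x.mean()
    denom = float(np.sum(xm * xm))
    slopes = draws @ xm / denom
    intercepts = draws.mean(axis=1) - slopes * x.mean()
    return LinearFit(float(slope), float(intercept),
                     float(slopes.std(ddof=1)), float(intercepts.std(ddof=1)))


# ---------------------------------------------------------------------------
# elastic-rod constants
# ---------------------------------------------------------------------------

@dataclass
class ElasticRodModel:
    """Fitted rod parameters.  Units: pN, nm, rad; kB T in pN nm."""

    S_eff: float                 # effective stretching modulus, pN
    C: float                     # twist modulus, pN nm^2
    g: float                     # twist-stretch coupling, pN nm
    L0: float                    # equilibrium extension, nm
    theta0: float = math.nan     # equilibrium twist, rad
    S_eff_err: float = 0.0
    C_err: float = 0.0
    g_err: float = 0.0
    slopes: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def S(self) -> float:
        """Bare stretching modulus S = S~ + g^2/C."""
        return self.S_eff + self.g**2 / self.C


def twist_variance_modulus(var_theta: float, L0: float, T: float = 300.0) -> float:
    """C (pN nm^2) from equipartition: var(dtheta) = kB T L0 / C."""
    if var_theta <= 0:
        raise InversionError("twist variance must be positive")
    return CONSTANTS.kB_pN_nm * T * L0 / var_theta


def extract_benchmark_constants(forces, L, theta, var_dtheta: float,
                                dL=None, dtheta=None, T: float = 300.0,
                                n_draws: int = 10_000, seed: int = 0) -> ElasticRodModel:
    """Rod constants from force-only (tau = 0) pulling data.

    ``forces`` in pN, ``L`` in nm, ``theta`` (cumulative twist) in rad,
    ``var_dtheta`` in rad^2 measured at the smallest force.  S~ = L0/A1,
    C = kB T L0 / var(dtheta), g = -C A2 / A1.
    """
    fit_L = fit_linear_mc(forces, L, dL, n_draws=n_draws, seed=seed)
    fit_t = fit_linear_mc(forces, theta, dtheta, n_draws=n_draws, seed=seed + 1)
    A1, L0 = fit_L.slope, fit_L.intercept
    A2, theta0 = fit_t.slope, fit_t.intercept
    if A1 <= 0 or L0 <= 0:
        raise InversionError("extension response must have positive slope and intercept")
    S_eff = L0 / A1
    C = twist_variance_modulus(var_dtheta, L0, T)
    g = -C * A2 / A1
    # Monte-Carlo propagation through the closed-form inversion
    rng = np.random.default_rng(seed + 2)
    A1_d = rng.normal(A1, fit_L.slope_err or 0.0, n_draws)
    A2_d = rng.normal(A2, fit_t.slope_err or 0.0, n_draws)
    ok = A1_d > 0
    S_err = float(np.std(L0 / A1_d[ok], ddof=1)) if fit_L.slope_err else 0.0
    g_err = float(np.std(-C * A2_d[ok] / A1_d[ok], ddof=1)) \
        if (fit_L.slope_err or fit_t.slope_err) else 0.0
    flags = []
    if fit_L.slope_err and abs(A1) < 2 * fit_L.slope_err:
        flags.append("A1 not significant")
    if fit_t.slope_err and abs(A2) < 2 * fit_t.slope_err:
        flags.append("A2 not significant")
    return ElasticRodModel(S_eff=S_eff, C=C, g=g, L0=L0, theta0=theta0,
                           S_eff_err=S_err, g_err=g_err,
                           slopes={"A1": A1, "A2": A2}, flags=flags)


def extract_stretch_torsion_constants(A1: float, A3: float, A4: float,
                                      L0: float) -> ElasticRodModel:
    """Invert the slope system A1 = L0/S~, A3 = -g L0/(C S~),
    A4 = (L0/C)(1 + g^2/(C S~)) for (S~, C, g).

    Closed form: S~ = L0/A1; C = L0 / (A4 - A3^2/A1); g = -A3 S~ / (A4 - A3^2/A1).
    """
    if A1 <= 0 or L0 <= 0:
        raise InversionError("A1 and L0 must be positive")
    S_eff = L0 / A1
    u = A4 - A3**2 / A1        # u = L0 / C
    if u <= 0:
        raise InversionError(
            "inconsistent slopes: A4 - A3^2/A1 must be positive for a stable rod")
    C = L0 / u
    g = -A3 * S_eff / u
    return ElasticRodModel(S_eff=S_eff, C=C, g=g, L0=L0,
                           slopes={"A1": A1, "A3": A3, "A4": A4})


def extract_stretch_torsion_from_data(f_tau0, L_tau0, tau_f, L_f, theta_f,
                                      dL_tau0=None, dL_f=None, dtheta_f=None,
                                      n_draws: int = 10_000, seed: int = 0) -> ElasticRodModel:
    """Full stretch-torsion analysis from the two data tables.

    ``(f_tau0, L_tau0)``: extension vs force at tau = 0 (gives A1 and L0);
    ``(tau_f, L_f, theta_f)``: extension and twist vs torque at constant f
    (gives A3 and A4).
    """
    fit_A1 = fit_linear_mc(f_tau0, L_tau0, dL_tau0, n_draws=n_draws, seed=seed)
    fit_A3 = fit_linear_mc(tau_f, L_f, dL_f, n_draws=n_draws, seed=seed + 1)
    fit_A4 = fit_linear_mc(tau_f, theta_f, dtheta_f, n_draws=n_draws, seed=seed + 2)
    model = extract_stretch_torsion_constants(fit_A1.slope, fit_A3.slope,
                                              fit_A4.slope, fit_A1.intercept)
    if any(e > 0 for e in (fit_A1.slope_err, fit_A3.slope_err, fit_A4.slope_err)):
        rng = np.random.default_rng(seed + 3)
        vals = []
        for _ in range(n_draws):
            try:
                m = extract_stretch_torsion_constants(
                    rng.normal(fit_A1.slope, fit_A1.slope_err or 1e-300),
                    rng.normal(fit_A3.slope, fit_A3.slope_err or 1e-300),
                    rng.normal(fit_A4.slope, fit_A4.slope_err or 1e-300),
                    fit_A1.intercept)
            except InversionError:
                continue
            vals.append((m.S_eff, m.C, m.g))
        if len(vals) > 10:
            arr = np.array(vals)
            model.S_eff_err, model.C_err, model.g_err = arr.std(axis=0, ddof=1)
    return model


def crookedness_stiffness(forces, cos_beta, d_cos_beta=None,
                          n_draws: int = 10_000, seed: int = 0):
    """Crookedness force constant from cos(beta) = cos(beta0) (1 + f/k_beta).

    Returns (k_beta pN, beta0 rad, LinearFit).  A negative slope (softening
    with force) is unphysical under this model and is flagged via
    ``FitError``.
    """
    fit = fit_linear_mc(forces, cos_beta, d_cos_beta, n_draws=n_draws, seed=seed)
    if fit.intercept <= 0 or fit.intercept > 1:
        raise FitError("cos(beta0) intercept outside (0, 1]")
    if fit.slope < 0:
        raise FitError("negative cos(beta) slope: straightening model violated")
    k_beta = fit.intercept / fit.slope if fit.slope > 0 else math.inf
    return k_beta, math.acos(min(1.0, fit.intercept)), fit


def effective_twist_modulus(var_theta: float, L0: float, T: float = 300.0) -> float:
    """C_eff(f) = kB T L0 / var(theta) for the twist-bend geometry (pN nm^2).

    The twist-bend coupling makes C_eff < C at low force; C_eff grows toward
    C as tension suppresses bending fluctuations.
    """
    if var_theta <= 0:
        raise InversionError("zero twist variance: rigid-rotor input is degenerate")
    return twist_variance_modulus(var_theta, L0, T)


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

def tangent_vectors(centers: np.ndarray, half_window: int = 5):
    """Unit tangents t_i = R_{i-w,i+w} / |R_{i-w,i+w}| from center positions.

    ``centers`` is (n, 3); tangents are defined for i = w..n-1-w (0-based).
    Returns (tangents, l) where l is the mean per-step distance between
    consecutive application points (the contour spacing of the tangents).
    """
    centers = np.asarray(centers, dtype=float)
    n = len(centers)
    w = int(half_window)
    if n <= 2 * w:
        raise FitError(f"chain of {n} centers too short for half-window {w}")
    R = centers[2 * w:] - centers[:-2 * w]
    t = R / np.linalg.norm(R, axis=1, keepdims=True)
    steps = np.linalg.norm(np.diff(centers[w:n - w], axis=0), axis=1)
    return t, float(steps.mean())


@dataclass
class CorrelationFunctions:
    """Tangent correlations and fitted decay lengths (units of the input)."""

    s: np.ndarray                # contour separations
    c_p: np.ndarray
    c_s: np.ndarray
    c_d: np.ndarray
    l: float                     # tangent contour spacing
    l_p: float
    l_s: float
    l_d: float
    l_p_err: float = 0.0
    l_s_err: float = 0.0
    l_d_err: float = 0.0
    fit_points: int = 0
    flags: list = field(default_factory=list)


def _mean_tangent_correlation(tangents: np.ndarray, max_lag: int) -> np.ndarray:
    """<t_i . t_{i+k}> averaged over i (and ensemble axis if 3-D input)."""
    t = tangents if tangents.ndim == 3 else tangents[None]
    n = t.shape[1]
    out = np.empty(max_lag + 1)
    out[0] = 1.0
    for k in range(1, max_lag + 1):
        out[k] = float(np.mean(np.sum(t[:, :n - k] * t[:, k:], axis=-1)))
    return out


def _fit_decay_length(s, c, fit_mask):
    """Decay length from a log-linear fit c ~ A exp(-s/l) on the masked range.

    Fitting the amplitude A jointly removes the window-averaging offset of
    coarse tangents; the decay length is -1/slope of log c vs s.  Returns
    (l, err, slope).  A non-decaying correlation yields l = inf.
    """
    s_fit = s[fit_mask]
    c_fit = c[fit_mask]
    if len(s_fit) < 3:
        raise FitError("fewer than 3 points in the correlation fit range")
    logc = np.log(c_fit)
    A = np.vstack([s_fit, np.ones_like(s_fit)]).T
    coef, res, *_ = np.linalg.lstsq(A, logc, rcond=None)
    slope = coef[0]
    dof = len(s_fit) - 2
    var_slope = 0.0
    if dof > 0 and res.size:
        sxx = float(np.sum((s_fit - s_fit.mean()) ** 2))
        var_slope = float(res[0]) / dof / sxx
    if slope >= -1e-12:
        return math.inf, math.inf, slope
    l = -1.0 / slope
    err = math.sqrt(var_slope) / slope**2 if var_slope else 0.0
    return float(l), float(err), float(slope)


def persistence_decomposition(traj_centers: np.ndarray,
                              ground_centers: Optional[np.ndarray] = None,
                              half_window: int = 5,
                              fit_min_c: float = 0.3,
                              max_lag: Optional[int] = None) -> CorrelationFunctions:
    """Static/dynamic decomposition of the persistence length.

    ``traj_centers`` is (n_frames, n, 3) sugar-center (or equivalent)
    positions from an equilibrated ensemble; ``ground_centers`` is the
    minimum-energy conformation (n, 3).  c_p averages tangent correlations
    over frames and positions; c_s uses the ground state only; c_d = c_p/c_s.
    Decay lengths come from log-linear fits restricted to the separations
    where both c_p and c_s exceed ``fit_min_c`` (the same range for all
    three, which preserves 1/l_p = 1/l_s + 1/l_d exactly for exponential
    fits with free amplitude).

    If no ground state is supplied, the static correlation is that of a
    straight rod (c_s = 1, l_s = inf) and l_d coincides with l_p.
    """
    traj_centers = np.asarray(traj_centers, dtype=float)
    if traj_centers.ndim == 2:
        traj_centers = traj_centers[None]
    tangents = []
    ls = []
    for frame in traj_centers:
        t, l = tangent_vectors(frame, half_window)
        tangents.append(t)
        ls.append(l)
    tangents = np.array(tangents)
    l = float(np.mean(ls))

    n_t = tangents.shape[1]
    if max_lag is None:
        max_lag = n_t - 1
    max_lag = min(max_lag, n_t - 1)
    lags = np.arange(max_lag + 1)
    s = lags * l

    c_p = _mean_tangent_correlation(tangents, max_lag)
    flags = []
    if ground_centers is not None:
        t_min, _ = tangent_vectors(np.asarray(ground_centers, dtype=float), half_window)
        c_s = _mean_tangent_correlation(t_min, max_lag)
    else:
        c_s = np.ones_like(c_p)
        flags.append("no ground state: static correlation set to 1 (l_s = inf)")
    c_d = c_p / c_s

    positive = (c_p > fit_min_c) & (c_s > fit_min_c) & (c_d > 0)
    if not np.all(positive):
        first_bad = int(np.argmin(positive))
        fit_mask = np.zeros_like(positive)
        fit_mask[:first_bad] = True
        flags.append(f"fit range truncated at lag {first_bad}")
    else:
        fit_mask = positive
    fit_mask &= lags > 0  # the trivial c(0)=1 point carries no decay information

    l_p, l_p_err, _ = _fit_decay_length(s, c_p, fit_mask)
    l_s, l_s_err, _ = _fit_decay_length(s, np.maximum(c_s, 1e-300), fit_mask)
    l_d, l_d_err, _ = _fit_decay_length(s, np.maximum(c_d, 1e-300), fit_mask)
    if math.isinf(l_s):
        flags.append("static correlation does not decay (straight ground state)")
    return CorrelationFunctions(s=s, c_p=c_p, c_s=c_s, c_d=c_d, l=l,
                                l_p=l_p, l_s=l_s, l_d=l_d,
                                l_p_err=l_p_err, l_s_err=l_s_err, l_d_err=l_d_err,
                                fit_points=int(fit_mask.sum()), flags=flags)
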