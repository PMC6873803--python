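"""The imaging-FCS ACF model and its nonlinear least-squares fit.

For a square (binned) pixel of side ``a`` and a Gaussian PSF of 1/e²
radius ``ω₀``, the temporal autocorrelation of a freely diffusing species
with diffusivity D and mean particle number N in the observation area is

    G(τ) = (1/N) · [ g(p(τ)) / g(p(0)) ]² · T(τ) + G_∞,
    g(p)  = erf(p) + (exp(−p²) − 1)/(√π·p),
    p(τ)  = a / sqrt(4Dτ + ω₀²),
    T(τ)  = 1 + (F_t/(1−F_t))·exp(−τ/t_f)        (optional triplet term).

The fitted parameters are N, D, F_t, t_f and G_∞.  The diffusion time is
defined as τ_D = A_eff / D with A_eff the pixel–PSF effective observation
area, which makes the diffusion law τ_D(A_eff) = τ₀ + A_eff/D_eff exact
with τ₀ = 0 for ideal free diffusion.

`ACFModel` wraps one `ACFCurve` plus the known optics and exposes
``fit() -> ACFFitResults`` in the statsmodels style (params, bse,
cov_params, summary).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import lmfit
import numpy as np
from scipy.special import erf

from .correlate import ACFCurve
from .optics import effective_area

__all__ = ["acf_model", "acf_model_multi", "amplitude_weights", "ACFModel",
           "ACFFitResults"]

_SQRT_PI = np.sqrt(np.pi)


def _g_factor(p: np.ndarray) -> np.ndarray:
    return erf(p) + (np.exp(-(p**2)) - 1.0) / (_SQRT_PI * p)


def acf_model(tau: np.ndarray, N: float, D: float, a: float, omega0: float,
              F_t: float = 0.0, t_f: float = 1e-3, G_inf: float = 0.0) -> np.ndarray:
    """Single-component imaging-FCS ACF model G(τ)."""
    tau = np.asarray(tau, dtype=float)
    p_tau = a / np.sqrt(4.0 * D * tau + omega0**2)
    p0 = a / omega0
    shape = (_g_factor(p_tau) / _g_factor(np.asarray(p0))) ** 2
    triplet = 1.0
    if F_t > 0.0:
        triplet = 1.0 + (F_t / (1.0 - F_t)) * np.exp(-tau / t_f)
    return shape * triplet / N + G_inf


def amplitude_weights(brightness: np.ndarray, mean_n: np.ndarray) -> np.ndarray:
    """Component amplitude weights α_i = B_i²⟨N_i⟩ / (Σ_i B_i⟨N_i⟩)².

    For a single component this reduces to 1/N.
    """
    b = np.asarray(brightness, dtype=float)
    n = np.asarray(mean_n, dtype=float)
    return b**2 * n / np.sum(b * n) ** 2


def acf_model_multi(tau: np.ndarray, alphas: np.ndarray, Ds: np.ndarray,
                    a: float, omega0: float, F_t: float = 0.0,
                    t_f: float = 1e-3, G_inf: float = 0.0) -> np.ndarray:
    """N_d-component ACF model: Σ_i α_i·shape_i(τ), shared triplet and offset."""
    tau = np.asarray(tau, dtype=float)
    p0 = a / omega0
    g0 = _g_factor(np.asarray(p0))
    total = np.zeros_like(tau)
    for alpha, d in zip(np.atleast_1d(alphas), np.atleast_1d(Ds)):
        p_tau = a / np.sqrt(4.0 * d * tau + omega0**2)
        total = total + alpha * (_g_factor(p_tau) / g0) ** 2
    triplet = 1.0
    if F_t > 0.0:
        triplet = 1.0 + (F_t / (1.0 - F_t)) * np.exp(-tau / t_f)
    return total * triplet + G_inf


@dataclass
class ACFFitResults:
    """Fitted ACF parameters with uncertainties and derived quantities."""

    params: dict[str, float]
    bse: dict[str, float]
    cov_params: Optional[np.ndarray]
    param_names: list[str]
    chi2_reduced: float
    converged: bool
    a: float
    omega0: float
    curve: ACFCurve = field(repr=False)
    model: "ACFModel" = field(repr=False)

    @property
    def N(self) -> float:
        return self.params["N"]

    @property
    def D(self) -> float:
        return self.params["D"]

    @property
    def A_eff(self) -> float:
        """Effective observation area of the fitted pixel, μm²."""
        return effective_area(self.a, self.omega0)

    @property
    def tau_D(self) -> float:
        """Diffusion time τ_D = A_eff / D, s."""
        return self.A_eff / self.params["D"]

    def predict(self, tau: Optional[np.ndarray] = None) -> np.ndarray:
        if tau is None:
            tau = self.curve.lags
        p = self.params
        return acf_model(tau, p["N"], p["D"], self.a, self.omega0,
                         p.get("F_t", 0.0), p.get("t_f", 1e-3), p["G_inf"])

    def summary(self) -> str:
        lines = [
            "ACF model fit (single diffusive component)",
            f"  pixel side a       : {self.a:.4g} um",
            f"  PSF 1/e2 radius w0 : {self.omega0:.4g} um",
            f"  A_eff              : {self.A_eff:.4g} um^2",
            f"  converged          : {self.converged}",
            f"  reduced chi^2      : {self.chi2_reduced:.4g}",
            "  parameter   estimate     std.err.",
        ]
        for name in self.param_names:
            se = self.bse.get(name, float("nan"))
            lines.append(f"  {name:<10} {self.params[name]:>12.6g} {se:>12.3g}")
        lines.append(f"  tau_D = A_eff/D    : {self.tau_D:.4g} s")
        return "\n".join(lines)


class ACFModel:
    """One ACF curve plus known optics, fit by weighted nonlinear least squares.

    Parameters
    ----------
    curve : ACFCurve
        Correlation curve (lag 0 excluded).
    a, omega0 : float
        Binned pixel side and PSF 1/e² radius in the sample plane, μm.
    triplet : bool
        Include the triplet blinking term (adds F_t, t_f as free parameters).
    weights : {"variance", "none"}
        Inverse per-lag-variance weights when the curve carries variance
        estimates; otherwise unweighted.
    """

    def __init__(self, curve: ACFCurve, a: float, omega0: float,
                 triplet: bool = False, weights: str = "variance") -> None:
        if a <= 0 or omega0 <= 0:
            raise ValueError("a and omega0 must be > 0")
        n_free = 3 + (2 if triplet else 0)
        if len(curve.lags) <= n_free:
            raise ValueError(
                f"curve has {len(curve.lags)} lags but the model has {n_free} parameters")
        self.curve = curve
        self.a = a
        self.omega0 = omega0
        self.triplet = triplet
        self.weights = weights

    def _initial(self) -> lmfit.Parameters:
        curve = self.curve
        g0 = max(curve.G[0], 1e-6)
        n0 = min(max(1.0 / g0, 1e-3), 1e9)
        a_eff = effective_area(self.a, self.omega0)
        half = g0 / 2.0
        below = np.nonzero(curve.G <= half)[0]
        tau_half = curve.lags[below[0]] if len(below) else curve.lags[-1]
        d0 = min(max(a_eff / (4.0 * tau_half), 1e-5), 1e2)
        params = lmfit.Parameters()
        params.add("N", value=n0, min=1e-6, max=1e12)
        params.add("D", value=d0, min=1e-6, max=1e3)
        params.add("G_inf", value=0.0, min=-np.inf, max=np.inf)
        if self.triplet:
            params.add("F_t", value=0.05, min=0.0, max=0.5)
            params.add("t_f", value=1e-3, min=1e-6, max=1.0)
        return params

    def fit(self, init: Optional[dict[str, float]] = None) -> ACFFitResults:
        curve = self.curve
        params = self._initial()
        if init:
            for k, v in init.items():
                params[k].set(value=v)
        if self.weights == "variance" and curve.var_G is not None:
            w = 1.0 / np.sqrt(curve.var_G)
        else:
            w = np.ones_like(curve.G)

        def residual(p: lmfit.Parameters) -> np.ndarray:
            model = acf_model(
                curve.lags, p["N"].value, p["D"].value, self.a, self.omega0,
                p["F_t"].value if self.triplet else 0.0,
                p["t_f"].value if self.triplet else 1e-3,
                p["G_inf"].value)
            return (model - curve.G) * w

        result = lmfit.minimize(residual, params, method="leastsq",
                                max_nfev=5000, ftol=1e-12, xtol=1e-12)
        # restart once from the optimum: resets the trust region and polishes
        # shallow-valley solutions to machine precision on clean data
        polished = lmfit.minimize(residual, result.params.copy(),
                                  method="leastsq", max_nfev=5000,
                                  ftol=1e-12, xtol=1e-12)
        if polished.success and polished.chisqr <= result.chisqr:
            result = polished
        names = list(result.params.keys())
        est = {k: float(result.params[k].value) for k in names}
        bse = {k: float(result.params[k].stderr) if result.params[k].stderr is not None
               else float("nan") for k in names}
        d = est["D"]
        converged = bool(result.success) and 1.01e-6 < d < 0.99e3
        cov = getattr(result, "covar", None)
        return ACFFitResults(
            params=est, bse=bse, cov_params=cov, param_names=names,
            chi2_reduced=float(result.redchi), converged=converged,
            a=self.a, omega0=self.omega0, curve=curve, model=self)
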