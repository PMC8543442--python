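"""Surface thermodynamics from tabulated surface energies u_s(T).

The temperature dependence of the surface (excess) energy is interpolated by
a constrained [2/1] rational (Pade) form

    u(T) = (b + c T + d T^2) / (1 + f T),   with  c = b f,

equivalently u(T) = u0 + alpha T^2 / (1 + f T) with u0 = b and alpha = d.
The constraint enforces u'(0) = 0, so u is quadratic at low T (harmonic
solids) and asymptotically linear at high T.  From the fit:

    c_s(T) = du/dT            (surface specific heat, analytic)
    s_s(T) = int_0^T c_s/T' dT'   (surface entropy; c_s/T' -> 2 alpha at 0)
    gamma(T) = u(T) - T s_s(T)    (surface free energy)

The same machinery applies to adsorption energies per molecule, giving the
adsorption entropy S_A(T) and its free-energy contribution -T S_A(T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, optimize

from .errors import FitError, ValidationError

__all__ = [
    "ThermoSeries",
    "PadeModel",
    "ThermoCurves",
    "AdsorptionSeries",
    "AdsorptionThermo",
    "fit_pade",
    "thermo_curves",
    "adsorption_energy",
    "adsorption_entropy",
]


@dataclass
class ThermoSeries:
    """Tabulated values over an ascending temperature grid.

    Units are mJ/m^2 for surface energies and kJ/mol per molecule for
    adsorption energies; ``sigma`` optionally weights the fit.
    """

    T: np.ndarray
    u: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.T.ndim != 1 or self.T.shape != self.u.shape:
            raise ValidationError("T and u must be 1D arrays of equal length")
        if np.any(self.T < 0) or np.any(np.diff(self.T) <= 0):
            raise ValidationError("temperatures must be non-negative and ascending")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.T.shape or np.any(self.sigma <= 0):
                raise ValidationError("sigma must be positive and match T in length")


@dataclass
class PadeModel:
    """Constrained [2/1] Pade interpolant u(T) = u0 + alpha T^2 / (1 + f T)."""

    u0: float
    alpha: float
    f: float
    residual_norm: float = 0.0
    T_max: float = float("inf")

    # numerator / denominator coefficients of (b + cT + dT^2) / (e + fT), e = 1
    @property
    def b(self) -> float:
        return self.u0

    @property
    def c(self) -> float:
        return self.u0 * self.f

    @property
    def d(self) -> float:
        return self.alpha

    @property
    def e(self) -> float:
        return 1.0

    def __call__(self, T):
        T = np.asarray(T, dtype=float)
        return self.u0 + self.alpha * T**2 / (1.0 + self.f * T)

    def specific_heat(self, T):
        """c_s = du/dT, analytic from the rational form."""
        T = np.asarray(T, dtype=float)
        den = 1.0 + self.f * T
        return self.alpha * T * (2.0 + self.f * T) / den**2

    def _entropy_integrand(self, t: float) -> float:
        if t == 0.0:
            return 2.0 * self.alpha  # c_s / T -> 2 alpha as T -> 0
        return float(self.specific_heat(t)) / t

    def entropy(self, T):
        """s_s(T) = int_0^T c_s(T')/T' dT', adaptive quadrature, s_s(0) = 0."""
        T = np.atleast_1d(np.asarray(T, dtype=float))
        order = np.argsort(T)
        s = np.zeros_like(T)
        acc, t_prev = 0.0, 0.0
        for idx in order:
            t = T[idx]
            if t < 0:
                raise ValidationError("entropy requires T >= 0")
            if t > t_prev:
                val, _ = integrate.quad(self._entropy_integrand, t_prev, t, limit=200)
                acc += val
                t_prev = t
            s[idx] = acc
        return s if s.size > 1 else float(s[0])

    def free_energy(self, T):
        """gamma(T) = u(T) - T s_s(T)."""
        T = np.asarray(T, dtype=float)
        return self(T) - T * self.entropy(T)

    def summary(self) -> str:
        return (
            f"u(T) = {self.u0:.6g} + {self.alpha:.6g} T^2 / (1 + {self.f:.6g} T)  "
            f"[b={self.b:.6g}, c={self.c:.6g}, d={self.d:.6g}, f={self.f:.6g}; "
            f"residual norm {self.residual_norm:.3g}]"
        )


def fit_pade(series: ThermoSeries) -> PadeModel:
    """Weighted least-squares fit of the constrained Pade form.

    Requires at least 6 points with T[0] = 0.  The fit is rejected when the
    fitted denominator 1 + f T has a root inside [0, T_max].
    """
    T, u = series.T, series.u
    if len(T) < 6:
        raise FitError(f"need at least 6 points to fit 3 parameters, got {len(T)}")
    if T[0] != 0.0:
        raise FitError("temperature grid must start at T = 0 K")
    w = 1.0 / series.sigma if series.sigma is not None else np.ones_like(u)
    T_max = float(T[-1])

    # initial guess: value at 0, low-T curvature, small denominator slope
    u0_0 = float(u[0])
    nlow = max(3, len(T) // 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = (u[1:nlow] - u0_0) / T[1:nlow] ** 2
    alpha_0 = float(np.nanmedian(curv)) if np.all(np.isfinite(curv)) else 0.0

    def residuals(p):
        u0, alpha, f = p
        return (u0 + alpha * T**2 / (1.0 + f * T) - u) * w

    f_min = -0.99 / T_max
    best = None
    for f0 in (0.0, 1e-3, 1e-2):
        res = optimize.least_squares(
            residuals,
            x0=[u0_0, alpha_0, f0],
            bounds=([-np.inf, -np.inf, f_min], [np.inf, np.inf, np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res
    u0, alpha, f = best.x
    dense = np.linspace(0.0, T_max, 512)
    if np.any(1.0 + f * dense <= 0.0):
        raise FitError(
            f"fitted denominator 1 + ({f:.4g}) T has a root inside [0, {T_max:.0f}] K; "
            "fit rejected"
        )
    return PadeModel(
        u0=float(u0), alpha=float(alpha), f=float(f),
        residual_norm=float(np.linalg.norm(residuals(best.x))), T_max=T_max,
    )


@dataclass
class ThermoCurves:
    """Specific heat, entropy and free energy derived from a Pade model."""

    T: np.ndarray
    c_s: np.ndarray
    s_s: np.ndarray
    gamma: np.ndarray
    model: PadeModel

    def summary(self) -> str:
        i300 = int(np.argmin(np.abs(self.T - 300.0)))
        return (
            f"u0 = {self.model.u0:.4g}; at T = {self.T[i300]:.0f} K: "
            f"c_s = {self.c_s[i300]:.4g}, s_s = {self.s_s[i300]:.4g}, "
            f"gamma = {self.gamma[i300]:.4g}"
        )


def thermo_curves(model: PadeModel, T_grid: Sequence[float]) -> ThermoCurves:
    """Evaluate c_s, s_s and gamma on a grid (warns beyond 110% of fit range)."""
    T = np.asarray(T_grid, dtype=float)
    if np.isfinite(model.T_max) and T.max() > 1.1 * model.T_max:
        warnings.warn(
            f"grid extends to {T.max():.0f} K, beyond 110% of the fitted "
            f"range [0, {model.T_max:.0f}] K",
            stacklevel=2,
        )
    return ThermoCurves(
        T=T,
        c_s=model.specific_heat(T),
        s_s=np.atleast_1d(model.entropy(T)),
        gamma=np.atleast_1d(model.free_energy(T)),
        model=model,
    )


def adsorption_energy(
    E_composite: float,
    E_bare_slab: float,
    E_isolated_molecule: float,
    n_molecules_total: int,
) -> float:
    """Adsorption energy per molecule, positive for attraction.

    U_A = [E_bare_slab + n E_isolated_molecule - E_composite] / n, where n
    counts all adsorbed molecules (a slab exposing two surfaces with one
    molecule on each has n = 2).
    """
    if n_molecules_total < 1:
        raise ValidationError("n_molecules_total must be at least 1")
    n = n_molecules_total
    return (E_bare_slab + n * E_isolated_molecule - E_composite) / n


@dataclass
class AdsorptionSeries:
    """Adsorption energy per molecule over an ascending T grid starting at 0."""

    T: np.ndarray
    U_A: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.U_A = np.asarray(self.U_A, dtype=float)
        if self.T.shape != self.U_A.shape:
            raise ValidationError("T and U_A must have equal length")

    @classmethod
    def from_energies(
        cls,
        T: Sequence[float],
        E_composite: Sequence[float],
        E_bare_slab: Sequence[float],
        E_isolated_molecule: Sequence[float],
        n_molecules_total: int,
    ) -> "AdsorptionSeries":
        U = [
            adsorption_energy(ec, eb, em, n_molecules_total)
            for ec, eb, em in zip(E_composite, E_bare_slab, E_isolated_molecule)
        ]
        return cls(T=np.asarray(T, dtype=float), U_A=np.asarray(U))


@dataclass
class AdsorptionThermo:
    T: np.ndarray
    S_A: np.ndarray            # kJ/(mol K) per molecule
    minus_T_S_A: np.ndarray    # kJ/mol per molecule
    model: PadeModel

    def summary(self) -> str:
        i = int(np.argmin(np.abs(self.T - 300.0)))
        return (
            f"-T S_A = {self.minus_T_S_A[i]:.4g} kJ/mol per molecule "
            f"at T = {self.T[i]:.0f} K"
        )


def adsorption_entropy(series: AdsorptionSeries) -> AdsorptionThermo:
    """Entropy contribution to the adsorption free energy.

    Fits the Pade form to U_A(T) and integrates its temperature derivative
    over T, exactly as for the surface entropy; returns S_A and -T S_A.
    """
    model = fit_pade(ThermoSeries(T=series.T, u=series.U_A))
    S = np.atleast_1d(model.entropy(series.T))
    return AdsorptionThermo(
        T=series.T, S_A=S, minus_T_S_A=-series.T * S, model=model
    )
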