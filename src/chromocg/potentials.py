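"""Coarse-grained potential forms and fits to a free-energy profile.

Three effective pair potentials for one-bead-per-nucleosome models:

* harmonic bond,       V(d) = ½·k·(d − d0)²           — linked nucleosomes
* exponential wall,    V(d) = exp(−(α·d − β))          — stacked-nucleosome repulsion
* shifted Coulomb,     V(d) = A / (d − B)              — same repulsion, alternative form

The exponential is stored under the sign convention exp(β − α·d): with
kcal/mol-scale parameters this gives a repulsive wall of a few kcal/mol
over 55–90 Å, whereas exp(−α·d − β) would be vanishingly small
everywhere.  The shifted Coulomb reads B as a distance shift (Å) placing
the singularity at d = B, the only dimensionally consistent reading.
Both conventions are recorded on the model and can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .constants import DA_TO_KG, KCAL_TO_DA_A2_PS2, N_AVOGADRO
from .errors import ConfigurationError, ConvergenceError, DomainError, FitDomainError
from .wham import PMFProfile

__all__ = [
    "HarmonicModel",
    "ExponentialModel",
    "ShiftedCoulombModel",
    "FitReport",
    "fit_harmonic",
    "fit_exponential",
    "fit_shifted_coulomb",
    "vibrational_frequency",
    "model_consistency",
]


@dataclass(frozen=True)
class HarmonicModel:
    """V(d) = ½·k·(d − d0)², k in kcal/mol/Å², d0 in Å."""

    k: float
    d0: float

    def __post_init__(self):
        if self.k <= 0:
            raise ConfigurationError(f"harmonic curvature must be > 0, got {self.k}")

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        return 0.5 * self.k * (d - self.d0) ** 2

    def derivative(self, d):
        return self.k * (np.asarray(d, dtype=float) - self.d0)


@dataclass(frozen=True)
class ExponentialModel:
    """Exponential repulsion, default convention V(d) = exp(β − α·d).

    ``sign_convention`` records the adopted algebraic reading:
    ``"exp(beta - alpha*d)"`` (default) or ``"exp(-alpha*d - beta)"``.
    """

    alpha: float  # 1/Å
    beta: float  # dimensionless
    sign_convention: str = "exp(beta - alpha*d)"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ConfigurationError(f"decay constant must be > 0, got {self.alpha}")
        if self.sign_convention not in ("exp(beta - alpha*d)", "exp(-alpha*d - beta)"):
            raise ConfigurationError(f"unknown sign convention {self.sign_convention!r}")

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        if self.sign_convention == "exp(beta - alpha*d)":
            return np.exp(self.beta - self.alpha * d)
        return np.exp(-self.alpha * d - self.beta)

    def derivative(self, d):
        return -self.alpha * self(d)


@dataclass(frozen=True)
class ShiftedCoulombModel:
    """V(d) = A / (d − B), A in kcal/mol·Å, B in Å; valid for d > B."""

    A: float
    B: float

    def __post_init__(self):
        if self.A <= 0:
            raise ConfigurationError(f"strength A must be > 0, got {self.A}")

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        if np.any(d <= self.B):
            raise DomainError(f"shifted Coulomb undefined at d <= B = {self.B}")
        return self.A / (d - self.B)

    def derivative(self, d):
        d = np.asarray(d, dtype=float)
        if np.any(d <= self.B):
            raise DomainError(f"shifted Coulomb undefined at d <= B = {self.B}")
        return -self.A / (d - self.B) ** 2


@dataclass
class FitReport:
    model: object
    fit_window: tuple
    rms_residual: float
    param_se: dict = field(default_factory=dict)
    n_points: int = 0

    def __post_init__(self):
        if self.rms_residual < 0:
            raise ConfigurationError("residual RMS cannot be negative")

    def summary(self) -> str:
        name = type(self.model).__name__
        params = ", ".join(
            f"{k}={v:.6g}" for k, v in vars(self.model).items() if isinstance(v, float)
        )
        lo, hi = self.fit_window
        return (
            f"{name}: {params}  [window {lo:.6g}-{hi:.6g} Å, n={self.n_points}, "
            f"RMS {self.rms_residual:.4g} kcal/mol]"
        )


def _window_data(pmf: PMFProfile, fit_window):
    lo, hi = fit_window
    sel = pmf.occupied & (pmf.centers >= lo) & (pmf.centers <= hi)
    d = pmf.centers[sel]
    F = pmf.F[sel]
    sigma = None
    if pmf.F_err is not None:
        sigma = pmf.F_err[sel]
        if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
            sigma = None  # fall back to unweighted when errors are unusable
    return d, F, sigma


def _auto_harmonic_window(pmf: PMFProfile, depth: float = 2.0):
    """Occupied bins within `depth` kcal/mol of the profile minimum."""
    occ = pmf.occupied
    if not occ.any():
        raise FitDomainError("profile has no occupied bins")
    Fmin = np.nanmin(pmf.F[occ])
    sel = occ & (pmf.F <= Fmin + depth)
    d = pmf.centers[sel]
    if d.size < 5:
        raise FitDomainError("fewer than 5 bins within the auto fit window")
    return float(d.min()), float(d.max())


def fit_harmonic(pmf: PMFProfile, fit_window=None, depth: float = 2.0):
    """Weighted least squares of ½k(d−d0)² + c against F(d).

    ``fit_window`` defaults to the occupied bins within ``depth`` kcal/mol
    of the minimum.  The additive constant c absorbs the anchoring
    convention, so results are invariant to shifting the input profile.
    The window must bracket an interior minimum.
    """
    if fit_window is None:
        fit_window = _auto_harmonic_window(pmf, depth)
    d, F, sigma = _window_data(pmf, fit_window)
    if d.size < 5:
        raise FitDomainError("harmonic fit needs >= 5 occupied bins in the window")
    imin = int(np.argmin(F))
    if imin == 0 or imin == d.size - 1:
        raise FitDomainError("fit window does not bracket an interior minimum")

    w = np.ones_like(F) if sigma is None else 1.0 / sigma
    # quadratic regression F = a d^2 + b d + c  ->  k = 2a, d0 = -b / 2a
    X = np.stack([d**2, d, np.ones_like(d)], axis=1)
    Xw = X * w[:, None]
    coef, *_ = np.linalg.lstsq(Xw, F * w, rcond=None)
    a, b, _c = coef
    if a <= 0:
        raise FitDomainError("fit window is not convex; no harmonic minimum")
    model = HarmonicModel(k=2.0 * a, d0=-b / (2.0 * a))

    resid = F - X @ coef
    dof = max(1, d.size - 3)
    cov = np.linalg.inv(Xw.T @ Xw) * float(resid @ (resid * w**2)) / dof
    se_a, se_b = np.sqrt(np.diag(cov))[:2]
    se = {
        "k": 2.0 * se_a,
        "d0": abs(model.d0) * np.hypot(se_b / max(abs(b), 1e-300), se_a / a),
    }
    report = FitReport(
        model=model,
        fit_window=tuple(fit_window),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        param_se=se,
        n_points=d.size,
    )
    return model, report


def fit_exponential(pmf: PMFProfile, fit_window,
                    sign_convention: str = "exp(beta - alpha*d)",
                    with_offset: bool = False):
    """Nonlinear least squares of the exponential wall against F(d).

    Requires F > 0 over the window (anchor the tail near zero first).
    Initial parameters come from the log-linear regression ln F = β − α·d.
    ``with_offset`` adds a free additive constant absorbing the arbitrary
    anchoring gauge of the profile (only α, β are reported).
    """
    d, F, sigma = _window_data(pmf, fit_window)
    if d.size < 3 + with_offset:
        raise FitDomainError("exponential fit needs >= 3 occupied bins")
    if not with_offset and np.any(F <= 0):
        raise FitDomainError("exponential fit requires strictly positive F in the window")

    Fpos = F - (F.min() - 1e-3) if with_offset else F
    slope, intercept = np.polyfit(d, np.log(np.maximum(Fpos, 1e-10)), 1)
    p0 = (max(1e-6, -slope), intercept)

    if with_offset:
        def form(x, alpha, beta, c):
            return np.exp(beta - alpha * x) + c

        p0 = (*p0, 0.0)
    else:
        def form(x, alpha, beta):
            return np.exp(beta - alpha * x)

    try:
        popt, pcov = curve_fit(
            form, d, F, p0=p0, sigma=sigma, absolute_sigma=sigma is not None, maxfev=20_000
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"exponential fit did not converge: {exc}") from exc
    model = ExponentialModel(alpha=float(popt[0]), beta=float(popt[1]),
                             sign_convention=sign_convention)
    resid = F - form(d, *popt)
    se = dict(zip(("alpha", "beta", "offset"), np.sqrt(np.diag(pcov))))
    report = FitReport(
        model=model,
        fit_window=tuple(fit_window),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        param_se=se,
        n_points=d.size,
    )
    return model, report


def fit_shifted_coulomb(pmf: PMFProfile, fit_window, with_offset: bool = False):
    """Nonlinear least squares of V(d) = A/(d − B) against F(d).

    B is constrained below the smallest window distance (the form is
    singular at d = B).  Initialized from the exact two-point solution at
    the window ends.  ``with_offset`` adds a free additive constant
    absorbing the profile's anchoring gauge — important here because the
    1/(d − B) tail decays slowly, so the gauge is never negligible over a
    finite window; only A and B are reported.
    """
    d, F, sigma = _window_data(pmf, fit_window)
    if d.size < 3 + with_offset:
        raise FitDomainError("shifted-Coulomb fit needs >= 3 occupied bins")
    if not with_offset and np.any(F <= 0):
        raise FitDomainError("shifted-Coulomb fit requires strictly positive F")

    d1, d2 = d[0], d[-1]
    F1, F2 = F[0], F[-1]
    # two-point closed form: F1 (d1 - B) = F2 (d2 - B)
    B0 = (F1 * d1 - F2 * d2) / (F1 - F2) if abs(F1 - F2) > 1e-12 else d1 - 1.0
    B_hi = d.min() - 1e-6
    B0 = min(B0, B_hi - 1e-3)
    A0 = max(1e-6, F1 * (d1 - B0))

    if with_offset:
        def form(x, A, B, C):
            return A / (x - B) + C

        p0 = (A0, B0, 0.0)
        bounds = ([1e-12, -np.inf, -np.inf], [np.inf, B_hi, np.inf])
    else:
        def form(x, A, B):
            return A / (x - B)

        p0 = (A0, B0)
        bounds = ([1e-12, -np.inf], [np.inf, B_hi])

    try:
        popt, pcov = curve_fit(
            form,
            d,
            F,
            p0=p0,
            sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=bounds,
            maxfev=20_000,
        )
    except RuntimeError as exc:
        raise ConvergenceError(f"shifted-Coulomb fit did not converge: {exc}") from exc
    model = ShiftedCoulombModel(A=float(popt[0]), B=float(popt[1]))
    resid = F - form(d, *popt)
    se = dict(zip(("A", "B", "offset"), np.sqrt(np.diag(pcov))))
    report = FitReport(
        model=model,
        fit_window=tuple(fit_window),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        param_se=se,
        n_points=d.size,
    )
    return model, report


def vibrational_frequency(model: HarmonicModel, reduced_mass: float) -> float:
    """Harmonic vibrational frequency ν = (1/2π)·sqrt(k/μ) in s⁻¹.

    ``reduced_mass`` in Da.  The curvature is converted to SI per molecule
    (kcal/mol/Å² → J/m²) before taking the square root.
    """
    if reduced_mass <= 0:
        raise ConfigurationError("reduced mass must be > 0")
    k_si = model.k * 4184.0 / N_AVOGADRO * 1e20  # J/m^2 per molecule
    mu_si = reduced_mass * DA_TO_KG
    return math.sqrt(k_si / mu_si) / (2.0 * math.pi)


def implied_reduced_mass(k: float, frequency: float) -> float:
    """Invert ν = (1/2π)·sqrt(k/μ) for μ (Da), given k in kcal/mol/Å² and ν in s⁻¹."""
    k_si = k * 4184.0 / N_AVOGADRO * 1e20
    return k_si / (2.0 * math.pi * frequency) ** 2 / DA_TO_KG


def model_consistency(m1, m2, range, n_grid: int = 201) -> float:
    """RMS discrepancy between two potential models on a uniform grid (kcal/mol)."""
    lo, hi = range
    if lo >= hi:
        raise ConfigurationError("consistency range must satisfy lo < hi")
    d = np.linspace(lo, hi, n_grid)
    v1, v2 = m1(d), m2(d)  # models raise DomainError on singular evaluation
    return float(np.sqrt(np.mean((v1 - v2) ** 2)))
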