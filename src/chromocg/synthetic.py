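"""Synthetic biased reaction-coordinate trajectories.

Generates the statistical raw material the WHAM analysis assumes —
stationary, autocorrelated, Boltzmann-distributed samples of a scalar
coordinate d under (reference landscape + harmonic window bias) — by
overdamped Langevin (Euler–Maruyama) dynamics on a known 1D reference
free-energy curve with reflecting domain boundaries:

    x' = x − (D / kBT) · V′(x) · dt + sqrt(2 · D · dt) · ξ,   ξ ~ N(0, 1)

Only the stationary distribution matters for validating the estimator, so
the simplest consistent integrator suffices.  Two shipped reference
presets mimic the shapes of the two nucleosome-pair free-energy profiles:
``LN-like`` (a harmonic well at large separation, as for nucleosomes
joined by linker DNA) and ``ULN-like`` (a steep repulsive wall with a
flat tail, as for tail-less stacked nucleosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kBT as thermal_energy
from .errors import ConfigurationError, DomainError, InvalidReferenceError
from .umbrella import BiasSpec, WindowSchedule
from .wham import BiasedTrajectory

__all__ = [
    "ReferencePMF",
    "LangevinParams",
    "reference_pmf",
    "sample_biased_trajectory",
    "generate_campaign",
]

_FD_H = 0.01  # Å, central-difference step for gradient-free references


@dataclass(frozen=True)
class ReferencePMF:
    """A known 1D free-energy landscape F(d) on a finite domain [d_lo, d_hi].

    ``fn`` maps distance (Å) to free energy (kcal/mol) and must be finite
    on the domain; ``grad`` is the analytic derivative when available,
    otherwise a central finite difference (h = 0.01 Å) is used.
    """

    fn: Callable
    d_lo: float
    d_hi: float
    grad: Optional[Callable] = None
    name: str = "custom"

    def __post_init__(self):
        if not self.d_lo < self.d_hi:
            raise ConfigurationError("reference domain must satisfy d_lo < d_hi")

    def __call__(self, d):
        return self.fn(np.asarray(d, dtype=float))

    def derivative(self, d):
        d = np.asarray(d, dtype=float)
        if self.grad is not None:
            return self.grad(d)
        return (self.fn(d + _FD_H) - self.fn(d - _FD_H)) / (2.0 * _FD_H)

    def validate(self, n_grid: int = 512):
        grid = np.linspace(self.d_lo, self.d_hi, n_grid)
        if not np.all(np.isfinite(self.fn(grid))):
            raise InvalidReferenceError(
                f"reference {self.name!r} is non-finite on [{self.d_lo}, {self.d_hi}]"
            )


# Preset parameters: the LN-like well mirrors the fitted harmonic bond term
# (k = 0.01 kcal/mol/Å² around 225 Å); the ULN-like wall mirrors the fitted
# exponential repulsion (alpha = 0.1213 1/Å, beta = 9.2086).
_LN_K, _LN_D0 = 0.01, 225.0
_ULN_ALPHA, _ULN_BETA = 0.1213, 9.2086


def reference_pmf(name: str) -> ReferencePMF:
    """Named reference presets: ``"LN-like"``, ``"ULN-like"`` or ``"flat"``."""
    if name == "LN-like":
        return ReferencePMF(
            fn=lambda d: 0.5 * _LN_K * (d - _LN_D0) ** 2,
            grad=lambda d: _LN_K * (d - _LN_D0),
            d_lo=160.0,
            d_hi=290.0,
            name="LN-like",
        )
    if name == "ULN-like":
        return ReferencePMF(
            fn=lambda d: np.exp(_ULN_BETA - _ULN_ALPHA * d),
            grad=lambda d: -_ULN_ALPHA * np.exp(_ULN_BETA - _ULN_ALPHA * d),
            d_lo=50.0,
            d_hi=110.0,
            name="ULN-like",
        )
    if name == "flat":
        return ReferencePMF(
            fn=lambda d: np.zeros_like(np.asarray(d, dtype=float)),
            grad=lambda d: np.zeros_like(np.asarray(d, dtype=float)),
            d_lo=0.0,
            d_hi=1000.0,
            name="flat",
        )
    raise ConfigurationError(f"unknown reference preset {name!r}")


@dataclass(frozen=True)
class LangevinParams:
    """Overdamped 1D Langevin sampling parameters.

    diffusion D in Å²/ps, dt in ps.  ``n_steps`` production steps per
    chain, samples saved every ``save_stride`` steps after ``n_equil``
    unrecorded equilibration steps.  ``n_chains`` independent chains are
    propagated in parallel and concatenated chain-by-chain.
    """

    temperature: float = DEFAULT_TEMPERATURE
    diffusion: float = 1.0
    dt: float = 0.05
    n_steps: int = 10_000
    save_stride: int = 10
    seed: int = 0
    n_equil: int = 1_000
    n_chains: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.diffusion <= 0:
            raise ConfigurationError("diffusion coefficient must be > 0")
        if self.n_steps < self.save_stride or self.save_stride < 1:
            raise ConfigurationError("need n_steps >= save_stride >= 1")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions back into [lo, hi] by specular reflection."""
    span = hi - lo
    y = np.mod(x - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def _start_position(ref: ReferencePMF, bias: BiasSpec) -> float:
    grid = np.linspace(ref.d_lo, ref.d_hi, 2001)
    v = ref(grid) + bias.energy(grid)
    if not np.all(np.isfinite(v)):
        raise InvalidReferenceError(f"reference {ref.name!r} non-finite on its domain")
    if np.ptp(v) < 1e-12:  # flat combined landscape: start mid-domain
        return 0.5 * (ref.d_lo + ref.d_hi)
    return float(grid[np.argmin(v)])


def sample_biased_trajectory(
    ref: ReferencePMF,
    bias: BiasSpec,
    params: LangevinParams,
    window_id: str = "w0",
) -> BiasedTrajectory:
    """Overdamped Langevin sampling of d under V(d) = ref(d) + bias(d).

    The chain starts at the minimum of the combined potential (mid-domain
    when flat), equilibrates for ``n_equil`` steps, then records every
    ``save_stride``-th position.  Reflecting boundaries keep all samples
    inside the reference domain and preserve Boltzmann stationarity
    ∝ exp(−V/kBT) there.  Identical params and seed give identical output.
    """
    if not (ref.d_lo <= bias.d0 <= ref.d_hi):
        raise DomainError(
            f"bias center {bias.d0} outside reference domain [{ref.d_lo}, {ref.d_hi}]"
        )
    x0 = _start_position(ref, bias)
    rng = np.random.default_rng(params.seed)
    kT = thermal_energy(params.temperature)
    mob = params.diffusion / kT  # mobility, Å²/ps per (kcal/mol)
    noise_scale = np.sqrt(2.0 * params.diffusion * params.dt)

    x = np.full(params.n_chains, x0)
    if params.n_chains > 1:  # decorrelate chain starts slightly
        x = _reflect(x + 0.1 * rng.standard_normal(params.n_chains), ref.d_lo, ref.d_hi)

    def vprime(pos):
        return ref.derivative(pos) + bias.k * (pos - bias.d0)

    for _ in range(params.n_equil):
        x = x - mob * vprime(x) * params.dt + noise_scale * rng.standard_normal(x.shape)
        x = _reflect(x, ref.d_lo, ref.d_hi)

    n_saved = params.n_steps // params.save_stride
    out = np.empty((params.n_chains, n_saved))
    step = 0
    for j in range(n_saved):
        for _ in range(params.save_stride):
            x = x - mob * vprime(x) * params.dt + noise_scale * rng.standard_normal(x.shape)
            x = _reflect(x, ref.d_lo, ref.d_hi)
            step += 1
        out[:, j] = x
    if not np.all(np.isfinite(out)):
        raise InvalidReferenceError("non-finite positions generated; check the reference")
    return BiasedTrajectory(
        window_id=window_id,
        bias=bias,
        samples=out.reshape(-1),
        dt_sample=params.dt * params.save_stride,
        n_chains=params.n_chains,
    )


def generate_campaign(
    ref: ReferencePMF,
    schedule: WindowSchedule,
    params: LangevinParams,
    out_dir=None,
) -> list:
    """One biased trajectory per window of the schedule.

    Per-window seeds derive deterministically from ``params.seed`` and the
    window index, so campaigns are reproducible and windows independent.
    With ``out_dir``, writes one COLVAR-style file per window plus a
    plain-text window manifest (see :mod:`chromocg.io`).
    """
    if len(schedule) == 0:
        raise ConfigurationError("empty window schedule")
    for w in schedule:
        if not (ref.d_lo <= w.d0 <= ref.d_hi):
            raise DomainError(
                f"window center {w.d0} outside reference domain "
                f"[{ref.d_lo}, {ref.d_hi}]"
            )
    trajs = []
    for i, w in enumerate(schedule):
        # derive a plain integer per-window seed so LangevinParams stays a simple record
        ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(i,))
        p_i = replace(params, seed=int(ss.generate_state(1)[0] % (2**31)))
        trajs.append(
            sample_biased_trajectory(ref, w, p_i, window_id=f"{schedule.label or 'w'}{i:03d}")
        )
    if out_dir is not None:
        from .io import write_campaign

        write_campaign(out_dir, trajs)
    return trajs
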