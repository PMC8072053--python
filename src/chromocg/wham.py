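"""Weighted histogram analysis method (WHAM) with bootstrap uncertainties.

Combines harmonically biased window histograms of the inter-nucleosome
distance d into a single unbiased potential of mean force F(d).  The
estimator solves the standard self-consistent equations

    P(x_b) = Σ_i n_ib / Σ_i N_i exp[(f_i − w_i(x_b)) / kBT]
    f_i    = −kBT ln Σ_b P(x_b) exp[−w_i(x_b) / kBT]

by direct iteration until the largest change of any window free energy
f_i falls below a tolerance; F(x_b) = −kBT ln P(x_b), anchored so that
the occupied-bin minimum is zero.  Per-bin statistical uncertainties come
from Monte-Carlo bootstrap over decorrelated samples (effective sample
counts N_i / g_i, with g the statistical inefficiency of each window's
time series).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np


from .constants import kBT as thermal_energy
from .constants import DEFAULT_TEMPERATURE
from .errors import ConfigurationError, ConvergenceError, EmptyAnalysisError
from .umbrella import BiasSpec, bias_energy

__all__ = [
    "BiasedTrajectory",
    "HistogramSet",
    "PMFProfile",
    "build_histograms",
    "wham_solve",
    "bootstrap_pmf",
    "overlap_matrix",
    "jacobian_correction",
    "statistical_inefficiency",
]


@dataclass
class BiasedTrajectory:
    """Scalar reaction-coordinate time series from one umbrella window."""

    window_id: str
    bias: BiasSpec
    samples: np.ndarray
    dt_sample: float = 1.0  # ps between saved samples
    n_chains: int = 1  # independent chains concatenated in `samples`

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise ConfigurationError(f"window {self.window_id}: empty trajectory")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError(f"window {self.window_id}: non-finite samples")

    def __len__(self):
        return self.samples.size

    def chains(self) -> np.ndarray:
        """Samples reshaped to (n_chains, n_per_chain)."""
        return self.samples.reshape(self.n_chains, -1)


@dataclass
class HistogramSet:
    """Per-window counts on a shared bin grid."""

    edges: np.ndarray  # (B+1,)
    counts: np.ndarray  # (K, B)
    n_samples: np.ndarray  # (K,) in-range counts
    n_out_of_range: np.ndarray  # (K,)
    biases: tuple  # (K,) BiasSpec
    window_ids: tuple

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]


@dataclass
class PMFProfile:
    """Binned free-energy profile F(d) with optional per-bin uncertainty.

    ``occupied`` masks bins with data; F is NaN elsewhere.  By convention
    the minimum over occupied bins is anchored at zero.
    """

    centers: np.ndarray
    F: np.ndarray
    temperature: float
    F_err: np.ndarray = None
    occupied: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.occupied is None:
            self.occupied = np.isfinite(self.F)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.F_err is not None:
            self.F_err = np.asarray(self.F_err, dtype=float)

    def anchored(self) -> "PMFProfile":
        """Copy with min-over-occupied-bins = 0."""
        F = self.F.copy()
        if self.occupied.any():
            F[self.occupied] -= np.nanmin(F[self.occupied])
        return replace(self, F=F)


def build_histograms(trajs, bin_width: float = 0.5, range=None) -> HistogramSet:
    """Bin every window's samples on one shared grid.

    ``range`` defaults to the span of all samples, snapped outward to the
    bin grid.  Out-of-range samples are counted and reported in the result,
    never silently dropped.
    """
    trajs = list(trajs)
    if not trajs:
        raise ConfigurationError("no trajectories to histogram")
    if bin_width <= 0:
        raise ConfigurationError(f"bin width must be > 0, got {bin_width}")
    if range is None:
        lo = min(t.samples.min() for t in trajs)
        hi = max(t.samples.max() for t in trajs)
    else:
        lo, hi = range
        if lo >= hi:
            raise ConfigurationError("histogram range must satisfy lo < hi")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    edges = lo + bin_width * np.arange(n_bins + 1)

    counts = np.zeros((len(trajs), n_bins))
    n_in = np.zeros(len(trajs), dtype=int)
    n_out = np.zeros(len(trajs), dtype=int)
    for i, t in enumerate(trajs):
        c, _ = np.histogram(t.samples, bins=edges)
        counts[i] = c
        n_in[i] = int(c.sum())
        n_out[i] = t.samples.size - n_in[i]
    if n_in.sum() == 0:
        raise EmptyAnalysisError("all samples fall outside the histogram range")
    return HistogramSet(
        edges=edges,
        counts=counts,
        n_samples=n_in,
        n_out_of_range=n_out,
        biases=tuple(t.bias for t in trajs),
        window_ids=tuple(t.window_id for t in trajs),
    )


def _bias_matrix(hists: HistogramSet, biases) -> np.ndarray:
    centers = hists.centers
    return np.stack([bias_energy(centers, b) for b in biases])  # (K, B)


def _check_support_connected(occupied: np.ndarray, counts: np.ndarray):
    """Warn on islands of occupied bins no single window chain bridges."""
    occ_idx = np.flatnonzero(occupied)
    if occ_idx.size and np.any(np.diff(occ_idx) > 1):
        warnings.warn(
            "histogram support is disconnected; the free-energy offset between "
            "islands is not determined by the data",
            stacklevel=3,
        )


def wham_solve(
    hists: HistogramSet,
    biases=None,
    T: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-8,
    max_iter: int = 100_000,
    f_init: np.ndarray = None,
) -> PMFProfile:
    """Self-consistent WHAM solution on a shared histogram grid.

    Returns the anchored profile; ``meta`` carries the window free energies
    ``f``, ``iterations``, the final ``residual`` (max |Δf_i| per iteration,
    kcal/mol) and the trailing ``residual_history``.

    Raises :class:`ConvergenceError` (carrying the best iterate) if the
    residual does not reach ``tol`` within ``max_iter`` iterations.
    """
    if biases is None:
        biases = hists.biases
    if len(biases) != hists.n_windows:
        raise ConfigurationError("bias list does not align with histogram windows")
    kT = thermal_energy(T)
    w = _bias_matrix(hists, biases)  # (K, B)
    counts = hists.counts
    occupied = counts.sum(axis=0) > 0
    _check_support_connected(occupied, counts)

    n_tot = counts.sum(axis=0)[occupied]  # (Bo,)
    N = hists.n_samples.astype(float)  # (K,)
    w_occ = w[:, occupied]  # (K, Bo)
    # Boltzmann factors of the biases are iteration-independent; underflow
    # of exp(-w/kBT) to exactly 0 for far-off bins is harmless here.
    E = np.exp(-w_occ / kT)  # (K, Bo)

    f = np.zeros(hists.n_windows) if f_init is None else np.array(f_init, dtype=float)
    residual_history = []
    log_P = None
    for it in range(1, max_iter + 1):
        a = N * np.exp((f - f.max()) / kT)  # (K,), shift-stabilized
        D = a @ E  # (Bo,) denominator per occupied bin (x const gauge factor)
        P = n_tot / D
        P /= P.sum()  # fix the normalization gauge each sweep
        f_new = -kT * np.log(E @ P)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f))) if hists.n_windows > 1 else 0.0
        residual_history.append(residual)
        f = f_new
        if residual < tol:
            log_P = np.log(P)
            break
    else:
        P = n_tot / ((N * np.exp((f - f.max()) / kT)) @ E)
        log_P = np.log(P / P.sum())
        it = max_iter
        residual = residual_history[-1]
        prof = _profile_from_logP(hists, log_P, occupied, T, f, it, residual, residual_history)
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3e})",
            result=prof,
            residual=residual,
        )
    return _profile_from_logP(
        hists, log_P, occupied, T, f, it, residual_history[-1], residual_history
    )


def _profile_from_logP(hists, log_P, occupied, T, f, iterations, residual, history):
    kT = thermal_energy(T)
    F = np.full(occupied.size, np.nan)
    F[occupied] = -kT * log_P
    F[occupied] -= F[occupied].min()
    return PMFProfile(
        centers=hists.centers,
        F=F,
        temperature=T,
        occupied=occupied,
        meta={
            "f": f,
            "iterations": iterations,
            "residual": residual,
            "residual_history": history[-50:],
        },
    )


def statistical_inefficiency(x: np.ndarray, mintime: int = 3) -> float:
    """g = 1 + 2·τ_int of a scalar series, by summing the normalized
    autocorrelation function until it first drops below zero.

    Returns 1.0 for constant or very short series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        return 1.0
    dx = x - x.mean()
    var = np.dot(dx, dx) / n
    if var <= 0:
        return 1.0
    g = 1.0
    for t in range(1, n - 1):
        c = np.dot(dx[: n - t], dx[t:]) / ((n - t) * var)
        if c <= 0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(1.0, g)


def bootstrap_pmf(
    trajs,
    biases=None,
    T: float = DEFAULT_TEMPERATURE,
    n_boot: int = 50,
    seed: int = 0,
    g="auto",
    bin_width: float = 0.5,
    hist_range=None,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> PMFProfile:
    """WHAM profile with Monte-Carlo bootstrap uncertainties.

    Each replicate redraws every window's histogram with ``N_i / g_i``
    effective multinomial draws (g_i = statistical inefficiency of the
    window series, or the given per-window values), re-solves WHAM
    warm-started from the full-data window free energies, and re-anchors
    at its own minimum.  The per-bin uncertainty is the standard deviation
    of F across replicates; bins occupied in fewer than two replicates get
    NaN uncertainty.
    """
    if n_boot < 2:
        raise ConfigurationError("bootstrap needs n_boot >= 2")
    trajs = list(trajs)
    hists = build_histograms(trajs, bin_width=bin_width, range=hist_range)
    if biases is None:
        biases = hists.biases
    base = wham_solve(hists, biases, T=T, tol=tol, max_iter=max_iter)

    if g == "auto":
        g_vals = []
        for t in trajs:
            per_chain = [statistical_inefficiency(c) for c in t.chains() if c.size >= 10]
            g_vals.append(float(np.mean(per_chain)) if per_chain else 1.0)
        g_vals = np.array(g_vals)
    else:
        g_vals = np.broadcast_to(np.asarray(g, dtype=float), (len(trajs),)).copy()
    n_eff = np.maximum(2, (hists.n_samples / g_vals).astype(int))

    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        p = hists.counts / hists.counts.sum(axis=1, keepdims=True)
    replicates = []
    n_failed = 0
    for _ in range(n_boot):
        counts_b = np.stack([rng.multinomial(n_eff[i], p[i]) for i in range(len(trajs))])
        hists_b = replace(
            hists,
            counts=counts_b.astype(float),
            n_samples=counts_b.sum(axis=1),
        )
        try:
            prof_b = wham_solve(
                hists_b, biases, T=T, tol=tol, max_iter=max_iter, f_init=base.meta["f"]
            )
        except ConvergenceError:
            n_failed += 1
            continue
        replicates.append(prof_b.F)
    if not replicates:
        raise ConvergenceError("every bootstrap replicate failed to converge")
    if n_failed:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap replicates did not converge")

    stack = np.stack(replicates)  # (R, B), NaN where unoccupied
    n_occ = np.sum(np.isfinite(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        err = np.nanstd(stack, axis=0, ddof=1)
    err[n_occ < 2] = np.nan
    return replace(
        base,
        F_err=err,
        meta={**base.meta, "n_boot": len(replicates), "g": g_vals, "n_eff": n_eff},
    )


def overlap_matrix(hists: HistogramSet) -> np.ndarray:
    """Pairwise histogram overlap O_ij = Σ_b min(p_ib, p_jb) in [0, 1]."""
    if hists.n_windows < 2:
        raise ConfigurationError("overlap diagnostics need >= 2 windows")
    with np.errstate(invalid="ignore"):
        p = hists.counts / hists.counts.sum(axis=1, keepdims=True)
    p = np.nan_to_num(p)
    K = hists.n_windows
    O = np.empty((K, K))
    for i in range(K):
        O[i] = np.minimum(p[i], p).sum(axis=1)
    return O


def adjacent_overlap_report(hists: HistogramSet, threshold: float = 0.05):
    """Overlap of each window with its neighbor in restraint-center order;
    returns (pairs, overlaps, flagged) where flagged marks overlap < threshold."""
    O = overlap_matrix(hists)
    order = np.argsort([b.d0 for b in hists.biases])
    pairs = list(zip(order[:-1], order[1:]))
    overlaps = np.array([O[i, j] for i, j in pairs])
    return pairs, overlaps, overlaps < threshold


def jacobian_correction(pmf: PMFProfile, mode: str = "none") -> PMFProfile:
    """Optional entropic correction of the radial distance coordinate.

    ``radial`` adds 2·kBT·ln d (removing the d² shell volume), re-anchored;
    ``none`` is the identity.
    """
    if mode == "none":
        return pmf
    if mode != "radial":
        raise ConfigurationError(f"unknown jacobian mode {mode!r}")
    if np.any(pmf.centers[pmf.occupied] <= 0):
        raise ConfigurationError("radial correction needs positive bin centers")
    kT = thermal_energy(pmf.temperature)
    F = pmf.F + 2.0 * kT * np.log(pmf.centers)
    out = replace(pmf, F=F)
    return out.anchored()
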