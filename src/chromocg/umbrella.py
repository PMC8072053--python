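"""Umbrella-sampling window construction and reaction-coordinate observables.

The reaction coordinate is the distance d between the centers of two
nucleosomes (center of mass of the DNA phosphorus atoms, or of the
histone-core Cα atoms).  Each umbrella window restrains d with a harmonic
bias ½·k·(d − d0)².  Window schedules are unions of inclusive arithmetic
ranges of restraint centers; the two shipped presets reproduce the
127-window linked-nucleosome (LN) ladder and the 68-window unlinked,
stacked-nucleosome (ULN) ladder.

A second, monitored (not biased) observable is the angle between the two
nucleosomes' superhelical axes — each axis being the normal of the
best-fit disc plane of the nucleosomal point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import kj_to_kcal
from .errors import ConfigurationError, DegenerateGeometryError, SelectionError

__all__ = [
    "BiasSpec",
    "WindowSchedule",
    "PointSet",
    "make_window_schedule",
    "ln_schedule",
    "uln_schedule",
    "bias_energy",
    "com_distance",
    "superhelical_angle",
    "read_structure_points",
]

_MERGE_TOL = 1e-6  # Å; centers closer than this are duplicates


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic restraint of one umbrella window.

    Parameters
    ----------
    d0 : float
        Restraint center, Å.  Must be positive.
    k : float
        Force constant, kcal/mol/Å².  Must be non-negative.
    offset : float
        Constant energy shift, kcal/mol.  A pure gauge term: it changes
        the window free energy but never the estimated profile.
    """

    d0: float
    k: float
    offset: float = 0.0

    def __post_init__(self):
        if self.k < 0:
            raise ConfigurationError(f"force constant must be >= 0, got {self.k}")
        if self.d0 <= 0:
            raise ConfigurationError(f"restraint center must be > 0, got {self.d0}")

    @classmethod
    def from_kj(cls, d0: float, k_kj_per_a2: float, offset: float = 0.0) -> "BiasSpec":
        """Build from a force constant quoted in kJ/mol/Å²."""
        return cls(d0=d0, k=kj_to_kcal(k_kj_per_a2), offset=offset)

    def energy(self, d):
        return bias_energy(d, self)


@dataclass(frozen=True)
class WindowSchedule:
    """Ordered ladder of umbrella windows (strictly increasing centers)."""

    windows: tuple
    label: str = ""

    def __post_init__(self):
        centers = self.centers
        if len(centers) == 0:
            raise ConfigurationError("a window schedule needs at least one window")
        if np.any(np.diff(centers) <= _MERGE_TOL):
            raise ConfigurationError("window centers must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.d0 for w in self.windows])

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]


def _inclusive_range(lo: float, hi: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ConfigurationError(f"range step must be > 0, got {step}")
    if lo > hi:
        raise ConfigurationError(f"range lower bound {lo} exceeds upper bound {hi}")
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def make_window_schedule(
    primary_range: tuple,
    extra_ranges: Sequence[tuple] = (),
    k_spec=5.0,
    label: str = "",
) -> WindowSchedule:
    """Build a window ladder from inclusive arithmetic ranges of centers.

    Parameters
    ----------
    primary_range, extra_ranges
        ``(lo, hi, step)`` triples in Å.  Endpoints are inclusive; the
        union of all ranges is sorted and duplicates (within 1e-6 Å)
        are merged.
    k_spec
        Force-constant assignment, in kJ/mol/Å² (converted internally):
        a scalar for a uniform constant; ``("alternating", k_even, k_odd)``
        to alternate by sorted window index (even indices get ``k_even``);
        or a callable ``(index, d0) -> k_kj`` for arbitrary per-window
        overrides.
    """
    centers = _inclusive_range(*primary_range)
    for rng in extra_ranges:
        centers = np.concatenate([centers, _inclusive_range(*rng)])
    centers = np.sort(centers)
    keep = np.concatenate([[True], np.diff(centers) > _MERGE_TOL])
    centers = centers[keep]

    if callable(k_spec):
        k_of = k_spec
    elif isinstance(k_spec, tuple) and len(k_spec) == 3 and k_spec[0] == "alternating":
        _, k_even, k_odd = k_spec

        def k_of(i, d0):
            return k_even if i % 2 == 0 else k_odd

    else:
        k_uniform = float(k_spec)

        def k_of(i, d0):
            return k_uniform

    windows = tuple(
        BiasSpec.from_kj(d0=float(d0), k_kj_per_a2=float(k_of(i, d0)))
        for i, d0 in enumerate(centers)
    )
    return WindowSchedule(windows=windows, label=label)


def ln_schedule() -> WindowSchedule:
    """Linked-nucleosome ladder: 175–250 Å step 1 plus 187.5–237.5 Å step 1,
    uniform k = 5 kJ/mol/Å² (127 windows)."""
    return make_window_schedule(
        (175.0, 250.0, 1.0), [(187.5, 237.5, 1.0)], k_spec=5.0, label="LN"
    )


def uln_schedule(alternating: bool = True) -> WindowSchedule:
    """Unlinked (stacked) nucleosome ladder: 60–91 Å step 0.5 plus
    55–59 Å step 1 (68 windows).

    The stiffer 10 kJ/mol/Å² constant is applied to alternating windows
    (even sorted indices), the rest keep 5 kJ/mol/Å²; ``alternating=False``
    applies 10 kJ/mol/Å² uniformly instead.  Arbitrary per-window values
    can be set through :func:`make_window_schedule`'s callable ``k_spec``.
    """
    k_spec = ("alternating", 10.0, 5.0) if alternating else 10.0
    return make_window_schedule(
        (60.0, 91.0, 0.5), [(55.0, 59.0, 1.0)], k_spec=k_spec, label="ULN"
    )


def bias_energy(d, bias: BiasSpec):
    """Harmonic window bias ½·k·(d − d0)² (+ gauge offset), kcal/mol."""
    d = np.asarray(d, dtype=float)
    out = 0.5 * bias.k * (d - bias.d0) ** 2 + bias.offset
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Geometric observables
# ---------------------------------------------------------------------------


@dataclass
class PointSet:
    """Weighted 3D point cloud (coordinates in Å, weights = masses or 1)."""

    coords: np.ndarray
    weights: np.ndarray = None

    def __post_init__(self):
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3:
            raise ConfigurationError("PointSet coordinates must be N x 3")
        if self.weights is None:
            self.weights = np.ones(len(self.coords))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.coords),):
            raise ConfigurationError("weights must match the number of points")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise DegenerateGeometryError("weights must be >= 0 with positive total")

    def __len__(self):
        return len(self.coords)

    @property
    def centroid(self) -> np.ndarray:
        return np.average(self.coords, axis=0, weights=self.weights)


def com_distance(a: PointSet, b: PointSet) -> float:
    """Distance between the weighted centroids of two point sets, Å."""
    return float(np.linalg.norm(a.centroid - b.centroid))


def _disc_normal(ps: PointSet) -> np.ndarray:
    """Smallest-variance principal axis of a weighted point cloud.

    For a disc-like cloud (a nucleosomal DNA superhelix) this is the disc
    normal, i.e. the superhelical axis.  The sign is fixed by orienting the
    largest-magnitude component positive.
    """
    if len(ps) < 3:
        raise DegenerateGeometryError("axis estimation needs >= 3 points")
    x = ps.coords - ps.centroid
    w = ps.weights / ps.weights.sum()
    cov = (x * w[:, None]).T @ x
    evals, evecs = np.linalg.eigh(cov)  # ascending
    # collinear cloud: two vanishing variances -> plane (and normal) undefined
    if evals[1] <= 1e-10 * max(evals[2], 1e-300):
        raise DegenerateGeometryError("points are (nearly) collinear; axis undefined")
    n = evecs[:, 0]
    pivot = np.argmax(np.abs(n))
    return n if n[pivot] >= 0 else -n


def superhelical_angle(a: PointSet, b: PointSet, fold: bool = True) -> float:
    """Angle between the superhelical axes of two nucleosomal point clouds.

    Each axis is the normal of the best-fit disc plane (smallest principal
    axis of the centered, weighted cloud).  Plane normals carry no intrinsic
    sign, so by default the angle is folded to [0°, 90°]; ``fold=False``
    returns the raw angle in [0°, 180°] under the deterministic sign
    convention of the axis estimator.
    """
    na, nb = _disc_normal(a), _disc_normal(b)
    c = float(np.clip(np.dot(na, nb), -1.0, 1.0))
    if fold:
        c = abs(c)
    return float(np.degrees(np.arccos(c)))


def read_structure_points(path, selection: str) -> PointSet:
    """Load a weighted point set from a PDB file.

    ``selection`` uses the MDAnalysis selection language, e.g. ``"name P"``
    (DNA phosphorus atoms) or ``"name CA and segid A"`` (histone-core Cα of
    one chain).  Coordinates are taken from the first model, in Å, with
    atomic masses as weights.
    """
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path))
        try:
            group = u.select_atoms(selection)
        except Exception as exc:  # bad selection syntax
            raise SelectionError(f"cannot interpret selection {selection!r}: {exc}") from exc
    if len(group) == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms in {path}")
    masses = np.asarray(group.masses, dtype=float)
    if not np.all(masses > 0):
        masses = np.ones(len(group))
    return PointSet(coords=np.asarray(group.positions, dtype=float), weights=masses)
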