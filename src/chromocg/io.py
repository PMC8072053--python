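"""Plain-text input/output: COLVAR time series, window manifests,
PMF tables, fiber trajectories and observable logs.

All floating-point text is written with 17 significant digits so that
byte-identical reruns are checkable with file checksums.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .umbrella import BiasSpec
from .wham import BiasedTrajectory, PMFProfile

__all__ = [
    "write_colvar",
    "read_colvar",
    "write_manifest",
    "read_manifest",
    "write_campaign",
    "read_campaign",
    "write_pmf",
    "read_pmf",
    "write_overlap",
    "write_xyz",
    "write_observables",
    "file_sha256",
]

_FMT = "%.17g"


def write_colvar(path, times, values) -> None:
    """COLVAR-style two-column file: '#! FIELDS time dist' header, then
    time (ps) and distance (Å)."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ConfigurationError("times and values must have equal length")
    with open(path, "w") as fh:
        fh.write("#! FIELDS time dist\n")
        for t, v in zip(times, values):
            fh.write(f"{t:.17g} {v:.17g}\n")


def read_colvar(path):
    """Returns (times, values) from a COLVAR-style file."""
    data = np.loadtxt(path, comments=("#", "#!"))
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two whitespace-separated columns")
    return data[:, 0], data[:, 1]


def write_manifest(path, window_ids, biases) -> None:
    """Window manifest: one 'window_id d0 k_kcal' line per window."""
    with open(path, "w") as fh:
        fh.write("# window_id d0 k_kcal\n")
        for wid, b in zip(window_ids, biases):
            fh.write(f"{wid} {b.d0:.17g} {b.k:.17g}\n")


def read_manifest(path):
    """Returns (window_ids, biases) from a manifest file."""
    ids, biases = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        wid, d0, k = line.split()
        ids.append(wid)
        biases.append(BiasSpec(d0=float(d0), k=float(k)))
    if not ids:
        raise ConfigurationError(f"{path}: empty window manifest")
    return ids, biases


def write_campaign(out_dir, trajs) -> list:
    """Write one COLVAR file per window plus 'windows.manifest'; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in trajs:
        p = out / f"{t.window_id}.colvar"
        times = t.dt_sample * np.arange(len(t.samples))
        write_colvar(p, times, t.samples)
        paths.append(p)
    mpath = out / "windows.manifest"
    write_manifest(mpath, [t.window_id for t in trajs], [t.bias for t in trajs])
    paths.append(mpath)
    return paths


def read_campaign(manifest_path, colvar_dir=None) -> list:
    """Load a campaign from its manifest; COLVAR files are looked up as
    '<window_id>.colvar' beside the manifest (or in ``colvar_dir``)."""
    manifest_path = Path(manifest_path)
    base = Path(colvar_dir) if colvar_dir else manifest_path.parent
    ids, biases = read_manifest(manifest_path)
    trajs = []
    for wid, bias in zip(ids, biases):
        times, values = read_colvar(base / f"{wid}.colvar")
        dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
        trajs.append(
            BiasedTrajectory(window_id=wid, bias=bias, samples=values, dt_sample=dt)
        )
    return trajs


def write_pmf(path, pmf: PMFProfile) -> None:
    """PMF table: '# d_center F F_err n_eff' header, NaN for masked bins."""
    err = pmf.F_err if pmf.F_err is not None else np.full_like(pmf.F, np.nan)
    n_eff = pmf.meta.get("n_eff_bins", np.where(pmf.occupied, 1.0, 0.0))
    with open(path, "w") as fh:
        fh.write(f"# d_center F F_err n_eff (T = {pmf.temperature:.17g} K)\n")
        for c, F, e, n in zip(pmf.centers, pmf.F, err, np.broadcast_to(n_eff, pmf.F.shape)):
            fh.write(f"{c:.17g} {F:.17g} {e:.17g} {n:.17g}\n")


def read_pmf(path, temperature: float = None) -> PMFProfile:
    text = Path(path).read_text().splitlines()
    T = None
    for line in text:
        if line.startswith("#") and "T =" in line:
            T = float(line.split("T =")[1].split("K")[0])
            break
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    F = data[:, 1]
    err = data[:, 2] if data.shape[1] > 2 else None
    if err is not None and np.all(np.isnan(err)):
        err = None
    return PMFProfile(
        centers=data[:, 0],
        F=F,
        temperature=temperature if temperature is not None else (T or 303.15),
        F_err=err,
        occupied=np.isfinite(F),
    )


def write_overlap(path, overlap: np.ndarray, window_ids=None) -> None:
    """Pairwise overlap matrix as TSV."""
    ids = window_ids or [f"w{i}" for i in range(len(overlap))]
    df = pd.DataFrame(overlap, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_xyz(path, trajectory, element: str = "C") -> None:
    """Fiber trajectory in XYZ format, one pseudo-atom per bead; the comment
    line carries the frame time in ps."""
    with open(path, "w") as fh:
        for t, frame in zip(trajectory.times, trajectory.positions):
            fh.write(f"{len(frame)}\n")
            fh.write(f"t = {t:.17g} ps\n")
            for x, y, z in frame:
                fh.write(f"{element} {x:.17g} {y:.17g} {z:.17g}\n")


def write_observables(path, trajectory) -> None:
    """Per-frame observable log: time, energies, Rg, contact count."""
    from .fiber import stability_report

    rep = stability_report(trajectory)
    df = pd.DataFrame(
        {
            "time_ps": trajectory.times,
            "E_bond": trajectory.e_bond,
            "E_nb": trajectory.e_nonbonded,
            "E_attr": trajectory.e_attraction,
            "E_kin": trajectory.e_kinetic,
            "Rg": rep.rg_series,
            "n_contacts": rep.contact_counts,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
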