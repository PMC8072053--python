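"""End-to-end pipeline driver: synthetic umbrella campaign → WHAM →
potential fits → coarse-grained fiber simulation.

A single configuration (nested dict, loadable from YAML/JSON) with
per-stage blocks drives the whole workflow; a completed run writes every
stage's standard outputs plus ``manifest.json`` listing each artifact
with a SHA-256 content checksum, so a run is reproducible — and checkably
so — from config + seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as cio
from .errors import ChromoCGError, ConfigurationError
from .fiber import (
    ForceField,
    SimConfig,
    build_ring_fiber,
    run_langevin,
    stability_report,
)
from .potentials import fit_exponential, fit_harmonic, fit_shifted_coulomb
from .synthetic import LangevinParams, generate_campaign, reference_pmf
from .umbrella import ln_schedule, make_window_schedule, uln_schedule
from .wham import adjacent_overlap_report, bootstrap_pmf, build_histograms, overlap_matrix

__all__ = ["PipelineConfig", "default_config", "validate_config", "run_pipeline"]

_PRESETS = ("LN", "ULN", "custom")

_DEFAULTS = {
    "preset": "LN",
    "out_dir": "pipeline_out",
    "seed": 0,
    "stages": ["windows", "synthetic", "wham", "fit"],
    "windows": {  # used only for preset == "custom"
        "primary_range": None,
        "extra_ranges": [],
        "k_kj_per_a2": 5.0,
    },
    "sampling": {
        "temperature": 303.15,
        "diffusion": 1.0,
        "dt": 0.05,
        "n_steps": 2000,
        "save_stride": 20,
        "n_equil": 1000,
        "n_chains": 20,
    },
    "wham": {
        "bin_width": 0.5,
        "tol": 1e-8,
        "max_iter": 100000,
        "n_boot": 20,
        "jacobian": "none",
    },
    "fit": {
        "forms": None,  # default: by preset (LN -> harmonic; ULN -> both repulsive)
        "window": None,  # lo-hi in Å; default: occupied range / auto
    },
    "cgsim": {
        "n_beads": 100,
        "geometry": "stacked-zigzag",
        "bond_length": 225.0,
        "stack_distance": 60.0,
        "mass": 2.0e5,
        "dt": 10.0,
        "n_steps": 2000,
        "save_stride": 20,
        "friction": 1.0,
        "temperature": 303.15,
        "attraction": {"enabled": True, "epsilon": 1.0, "r0": 60.0, "width": 5.0},
        "nonbonded": "exponential",
        "cutoff": 400.0,
        "contact_distance": 70.0,
    },
}

_KNOWN_STAGES = ("windows", "synthetic", "wham", "fit", "cgsim")


@dataclass
class PipelineConfig:
    """Validated nested pipeline configuration (see ``default_config``)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(_DEFAULTS))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        return cls.from_dict(user)

    @classmethod
    def from_dict(cls, user: dict) -> "PipelineConfig":
        data = copy.deepcopy(_DEFAULTS)
        _deep_update(data, user)
        return cls(data=data)

    def __getitem__(self, key):
        return self.data[key]


def _deep_update(base: dict, other: dict):
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def default_config(preset: str = "LN") -> PipelineConfig:
    return PipelineConfig.from_dict({"preset": preset})


def validate_config(config: PipelineConfig) -> list:
    """All problems with the configuration; an empty list means valid."""
    problems = []
    d = config.data
    if d["preset"] not in _PRESETS:
        problems.append(
            f"preset: unknown value {d['preset']!r}; valid presets are {', '.join(_PRESETS)}"
        )
    stages = d.get("stages") or []
    if not stages:
        problems.append("stages: no stages enabled")
    for s in stages:
        if s not in _KNOWN_STAGES:
            problems.append(f"stages: unknown stage {s!r}")
    if d["preset"] == "custom" and "windows" in stages:
        if not d["windows"].get("primary_range"):
            problems.append("windows.primary_range: required for the custom preset")
    stochastic = {"synthetic", "wham", "cgsim"} & set(stages)
    if stochastic and d.get("seed") is None:
        problems.append(f"seed: required when stochastic stages {sorted(stochastic)} run")
    if d["wham"]["bin_width"] <= 0:
        problems.append("wham.bin_width: must be > 0")
    if d["wham"]["n_boot"] < 0:
        problems.append("wham.n_boot: must be >= 0")
    for key in ("dt", "n_steps", "save_stride"):
        if d["sampling"][key] <= 0:
            problems.append(f"sampling.{key}: must be > 0")
    if d["cgsim"]["dt"] <= 0:
        problems.append("cgsim.dt: must be > 0")
    if d["cgsim"]["attraction"]["epsilon"] < 0:
        problems.append("cgsim.attraction.epsilon: must be >= 0")
    return problems


def _schedule_for(config: PipelineConfig):
    preset = config["preset"]
    if preset == "LN":
        return ln_schedule()
    if preset == "ULN":
        return uln_schedule()
    w = config["windows"]
    return make_window_schedule(
        tuple(w["primary_range"]),
        [tuple(r) for r in w["extra_ranges"]],
        k_spec=w["k_kj_per_a2"],
        label="custom",
    )


def _reference_for(config: PipelineConfig):
    return reference_pmf("ULN-like" if config["preset"] == "ULN" else "LN-like")


def run_pipeline(config: PipelineConfig, out_dir=None):
    """Execute the enabled stages in order; returns (status, manifest).

    status 0 on success; on a stage failure the partial manifest is still
    written and a nonzero status returned.  Identical config + seed give
    byte-identical artifacts (checkable through the manifest checksums).
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("invalid pipeline config: " + "; ".join(problems))
    d = config.data
    out = Path(out_dir if out_dir is not None else d["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = d["stages"]
    manifest = {"config": d, "artifacts": {}, "stages_completed": []}
    status = 0

    def register(path):
        manifest["artifacts"][str(Path(path).name)] = cio.file_sha256(path)

    try:
        schedule = None
        trajs = None
        pmf = None
        if "windows" in stages:
            schedule = _schedule_for(config)
            mpath = out / "windows.manifest"
            cio.write_manifest(
                mpath, [f"{schedule.label}{i:03d}" for i in range(len(schedule))], list(schedule)
            )
            register(mpath)
            manifest["n_windows"] = len(schedule)
            manifest["stages_completed"].append("windows")

        if "synthetic" in stages:
            schedule = schedule or _schedule_for(config)
            sp = d["sampling"]
            params = LangevinParams(
                temperature=sp["temperature"],
                diffusion=sp["diffusion"],
                dt=sp["dt"],
                n_steps=sp["n_steps"],
                save_stride=sp["save_stride"],
                n_equil=sp["n_equil"],
                n_chains=sp["n_chains"],
                seed=d["seed"],
            )
            trajs = generate_campaign(_reference_for(config), schedule, params)
            for p in cio.write_campaign(out, trajs):
                register(p)
            manifest["stages_completed"].append("synthetic")

        if "wham" in stages:
            if trajs is None:
                trajs = cio.read_campaign(out / "windows.manifest")
            wp = d["wham"]
            # bins restricted to the restrained span: bins reachable only by
            # the sparse tails beyond the outermost windows corrupt the anchor
            centers = [t.bias.d0 for t in trajs]
            span = (min(centers) - 1.0, max(centers) + 1.0)
            if wp["n_boot"] >= 2:
                pmf = bootstrap_pmf(
                    trajs,
                    T=d["sampling"]["temperature"],
                    n_boot=wp["n_boot"],
                    seed=d["seed"],
                    bin_width=wp["bin_width"],
                    hist_range=span,
                    tol=wp["tol"],
                    max_iter=wp["max_iter"],
                )
            else:
                from .wham import wham_solve

                hists = build_histograms(trajs, bin_width=wp["bin_width"], range=span)
                pmf = wham_solve(
                    hists, T=d["sampling"]["temperature"], tol=wp["tol"], max_iter=wp["max_iter"]
                )
            ppath = out / "pmf.tsv"
            cio.write_pmf(ppath, pmf)
            register(ppath)
            hists = build_histograms(trajs, bin_width=wp["bin_width"], range=span)
            opath = out / "overlap.tsv"
            cio.write_overlap(opath, overlap_matrix(hists), list(hists.window_ids))
            register(opath)
            _, overlaps, flagged = adjacent_overlap_report(hists)
            manifest["min_adjacent_overlap"] = float(overlaps.min())
            manifest["n_low_overlap_pairs"] = int(flagged.sum())
            manifest["stages_completed"].append("wham")

        if "fit" in stages:
            if pmf is None:
                pmf = cio.read_pmf(out / "pmf.tsv")
            forms = d["fit"]["forms"]
            if forms is None:
                forms = ["harmonic"] if d["preset"] != "ULN" else [
                    "exponential",
                    "shifted-coulomb",
                ]
            window = d["fit"]["window"]
            if window is None and d["preset"] == "ULN":
                # repulsive fits need F > 0: take the contiguous positive run
                # upward from the wall, capped at the 90 Å ladder span
                sel = pmf.occupied & (pmf.centers <= 90.0) & (pmf.F > 0)
                idx = np.flatnonzero(sel)
                stop = np.flatnonzero(np.diff(idx) > 1)
                if stop.size:
                    idx = idx[: stop[0] + 1]
                if idx.size < 3:
                    raise ConfigurationError(
                        "too few strictly positive bins below 90 Å for a repulsive fit"
                    )
                window = (float(pmf.centers[idx[0]]), float(pmf.centers[idx[-1]]))
            lines = []
            manifest["fits"] = {}
            for form in forms:
                if form == "harmonic":
                    model, rep = fit_harmonic(pmf, fit_window=window)
                elif form == "exponential":
                    model, rep = fit_exponential(pmf, fit_window=window)
                elif form == "shifted-coulomb":
                    model, rep = fit_shifted_coulomb(pmf, fit_window=window)
                else:
                    raise ConfigurationError(f"unknown fit form {form!r}")
                lines.append(rep.summary())
                manifest["fits"][form] = {
                    k: v for k, v in vars(model).items() if isinstance(v, float)
                }
            fpath = out / "fits.txt"
            fpath.write_text("\n".join(lines) + "\n")
            register(fpath)
            manifest["stages_completed"].append("fit")

        if "cgsim" in stages:
            cg = d["cgsim"]
            bond = None
            if manifest.get("fits", {}).get("harmonic"):
                from .potentials import HarmonicModel

                hf = manifest["fits"]["harmonic"]
                bond = HarmonicModel(k=hf["k"], d0=hf["d0"])
            else:
                from .potentials import HarmonicModel

                bond = HarmonicModel(k=0.01, d0=cg["bond_length"])
            from .potentials import ExponentialModel, ShiftedCoulombModel

            if cg["nonbonded"] == "exponential":
                nb = ExponentialModel(alpha=0.1213, beta=9.2086)
            else:
                nb = ShiftedCoulombModel(A=39.53, B=52.82)
            attraction = None
            if cg["attraction"]["enabled"]:
                a = cg["attraction"]
                attraction = (a["epsilon"], a["r0"], a["width"])
            ff = ForceField(bond=bond, nonbonded=nb, attraction=attraction, cutoff=cg["cutoff"])
            topo, state = build_ring_fiber(
                cg["n_beads"],
                bond_length=cg["bond_length"],
                geometry=cg["geometry"],
                seed=d["seed"],
                stack_distance=cg["stack_distance"],
                temperature=cg["temperature"],
                mass=cg["mass"],
            )
            sim = SimConfig(
                temperature=cg["temperature"],
                friction=cg["friction"],
                dt=cg["dt"],
                n_steps=cg["n_steps"],
                save_stride=cg["save_stride"],
                seed=d["seed"],
            )
            traj = run_langevin(state, topo, ff, sim)
            xpath = out / "fiber.xyz"
            cio.write_xyz(xpath, traj)
            register(xpath)
            obspath = out / "fiber_observables.tsv"
            cio.write_observables(obspath, traj)
            register(obspath)
            rep = stability_report(traj, topo, sim, contact_distance=cg["contact_distance"])
            manifest["fiber"] = {
                "crashed": rep.crashed,
                "contact_retention": rep.initial_contact_retention,
                "summary": rep.summary(),
            }
            manifest["stages_completed"].append("cgsim")
    except ChromoCGError as exc:
        manifest["error"] = str(exc)
        status = 1

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(_jsonable(manifest), indent=2, sort_keys=True) + "\n")
    return status, manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
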