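"""Minimal figures: PMF with error band, fiber observable traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_pmf(pmf, path, truth=None, models=(), title=None):
    """PMF with bootstrap error band; optional generating curve and fitted
    potential models overlaid."""
    fig, ax = plt.subplots(figsize=(5.2, 3.4))
    occ = pmf.occupied
    d, F = pmf.centers[occ], pmf.F[occ]
    ax.plot(d, F, "k-", lw=1.2, label="WHAM estimate")
    if pmf.F_err is not None:
        err = pmf.F_err[occ]
        good = np.isfinite(err)
        ax.fill_between(d[good], (F - err)[good], (F + err)[good],
                        color="0.7", alpha=0.6, lw=0, label="bootstrap ±1σ")
    if truth is not None:
        t = truth(d)
        ax.plot(d, t - t.min() + F.min(), "b--", lw=1.0, label="generating")
    for model, style, name in models:
        v = model(d)
        ax.plot(d, v, style, lw=1.0, label=name)
    ax.set_xlabel("d (Å)")
    ax.set_ylabel("F (kcal/mol)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_observables(trajectory, path):
    """Energy components, radius of gyration and contact count vs time."""
    from .fiber import stability_report

    rep = stability_report(trajectory)
    fig, axes = plt.subplots(3, 1, figsize=(5.2, 6.0), sharex=True)
    t = trajectory.times / 1000.0  # ns
    axes[0].plot(t, trajectory.e_bond, label="bond")
    axes[0].plot(t, trajectory.e_nonbonded, label="repulsion")
    axes[0].plot(t, trajectory.e_attraction, label="attraction")
    axes[0].set_ylabel("E (kcal/mol)")
    axes[0].legend(frameon=False, fontsize=8)
    axes[1].plot(t, rep.rg_series, "k-")
    axes[1].set_ylabel("Rg (Å)")
    axes[2].plot(t, rep.contact_counts, "k-")
    axes[2].set_ylabel("stacked contacts")
    axes[2].set_xlabel("t (ns)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
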