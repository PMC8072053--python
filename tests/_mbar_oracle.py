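"""Independent multistate-reweighting (MBAR) reference estimator.

Test-only oracle for cross-checking the package's binned self-consistent
WHAM solver.  Works sample-wise (no histogram approximation in the window
free energies): solves the MBAR self-consistency

    f_k = -ln Σ_n exp(-u_k(x_n)) / Σ_l N_l exp(f_l - u_l(x_n))

over all pooled samples by damped fixed-point iteration in log space,
then bins the per-sample unbiased weights into a free-energy profile.
Deliberately shares no code with chromocg.wham.
"""

import numpy as np
from scipy.special import logsumexp

from chromocg.constants import KB_KCAL


def mbar_window_free_energies(trajs, temperature):
    """Reduced window free energies by minimizing the convex MBAR objective

        kappa(f) = sum_n ln sum_k N_k exp(f_k - u_kn) - sum_k N_k f_k

    over f_1..f_{K-1} with the f_0 = 0 gauge."""
    from scipy.optimize import minimize

    kT = KB_KCAL * temperature
    x = np.concatenate([t.samples for t in trajs])
    N = np.array([len(t) for t in trajs], dtype=float)
    u = np.stack(
        [(0.5 * t.bias.k * (x - t.bias.d0) ** 2 + t.bias.offset) / kT for t in trajs]
    )  # (K, Ntot) reduced bias energies
    logN = np.log(N)

    def full(f_rest):
        return np.concatenate([[0.0], f_rest])

    def objective(f_rest):
        f = full(f_rest)
        z = logN[:, None] + f[:, None] - u  # (K, Ntot)
        kappa = logsumexp(z, axis=0).sum() - float(N @ f)
        w = np.exp(z - logsumexp(z, axis=0))  # softmax over windows per sample
        grad = w.sum(axis=1) - N
        return kappa, grad[1:]

    res = minimize(objective, np.zeros(len(trajs) - 1), jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    return full(res.x), x, u, logN


def mbar_pmf(trajs, temperature, edges):
    """Free-energy profile on the given bin edges, anchored at its minimum,
    in kcal/mol.  NaN for empty bins."""
    kT = KB_KCAL * temperature
    f, x, u, logN = mbar_window_free_energies(trajs, temperature)
    log_denom = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
    log_w = -log_denom  # unnormalized log weight of each sample in the unbiased state
    idx = np.digitize(x, edges) - 1
    B = len(edges) - 1
    F = np.full(B, np.nan)
    for b in range(B):
        sel = idx == b
        if np.any(sel):
            F[b] = -kT * logsumexp(log_w[sel])
    F -= np.nanmin(F)
    return F
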