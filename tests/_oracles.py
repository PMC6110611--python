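"""Independent reference implementations used as test oracles.

Deliberately built from different numerical routes than the package:
forward-map tabulation + linear interpolation instead of Newton
inversion, plain trapezoid sums instead of Gauss-Legendre, and pure
grid-argmin minimization instead of bracketed refinement.
"""

import numpy as np
from scipy import special


def oracle_kappa_of_j(J_values):
    """Invert J = kappa I1/I0 by interpolating the tabulated forward map."""
    kgrid = np.concatenate(([0.0], np.logspace(-8, 8, 4000)))
    jgrid = kgrid * special.i1e(kgrid) / np.where(kgrid > 0, special.i0e(kgrid), 1.0)
    return np.interp(J_values, jgrid, kgrid)


def oracle_expected_cost_fn(cost_fn, n_eps=4097, n_kappa=2000):
    """Tabulate E[cost | kappa] by trapezoid quadrature; return interpolator."""
    eps = np.linspace(-np.pi, np.pi, n_eps)
    cvals = cost_fn(eps)
    kgrid = np.concatenate(([0.0], np.logspace(-8, 8, n_kappa)))
    dens = np.exp(kgrid[:, None] * (np.cos(eps)[None, :] - 1.0)) \
        / (2.0 * np.pi * special.i0e(kgrid)[:, None])
    table = np.trapezoid(cvals[None, :] * dens, eps, axis=1)

    def interp(kappa):
        return np.interp(kappa, kgrid, table)

    return interp, table[0]  # (interpolator, uniform-circle value)


def oracle_cbar_fn(cost_fn, tau, n_bins=50):
    """Expected behavioral cost as a function of J_bar (vectorized)."""
    ecost, uniform_val = oracle_expected_cost_fn(cost_fn)
    if tau < 1e-6:
        def cbar(J_bar):
            return ecost(oracle_kappa_of_j(np.asarray(J_bar, dtype=float)))
        return cbar, uniform_val
    levels = (np.arange(n_bins) + 0.5) / n_bins
    shape_grid = np.logspace(-9, 10, 3000)
    logq = np.empty((shape_grid.size, n_bins))
    for j, lev in enumerate(levels):
        with np.errstate(divide="ignore"):
            logq[:, j] = np.maximum(np.log(special.gammaincinv(shape_grid, lev)), -745.0)

    def cbar(J_bar):
        J_bar = np.asarray(J_bar, dtype=float)
        ls = np.log(np.maximum(J_bar, 1e-300) / tau)
        out = np.zeros_like(J_bar)
        acc = np.zeros_like(J_bar)
        for j in range(n_bins):
            q = tau * np.exp(np.interp(ls, np.log(shape_grid), logq[:, j]))
            acc += ecost(oracle_kappa_of_j(q))
        out = acc / n_bins
        out[J_bar == 0.0] = uniform_val
        return out

    return cbar, uniform_val


def brute_force_optimal_resource(p, lam, tau, cost_fn, n_grid=100_000):
    """argmin over a dense log grid of p*cbar(J) + lam*J, with the J = 0
    boundary compared explicitly.  Returns (J_opt, objective)."""
    grid = np.logspace(-6, 5, n_grid)
    cbar, uniform_val = oracle_cbar_fn(cost_fn, tau)
    f = p * cbar(grid) + lam * grid
    i = int(np.argmin(f))
    f0 = p * uniform_val
    if f0 <= f[i]:
        return 0.0, f0
    return float(grid[i]), float(f[i])
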