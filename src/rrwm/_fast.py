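"""Vectorized fast paths shared by the allocator and the fitting code.

Model fitting evaluates the expected behavioral cost cbar(J_bar; tau) many
thousands of times.  Two precomputed tables remove the per-call cost:

* :class:`CostKappaTable` -- E[c(eps) | kappa] as a monotone interpolant
  over log kappa, built once per cost specification from the exact
  quadrature in :mod:`rrwm.costs`.
* a global table of log gamma quantiles as a function of log shape, which
  replaces per-call ``gammaincinv`` evaluations in the equal-probability
  discretization (the discretization levels (i - 1/2)/n_bins are fixed,
  and the quantile of a gamma with mean J_bar and scale tau is
  tau * q(shape) with shape = J_bar / tau).

Both tables are accurate to ~1e-6 relative, far below the statistical
resolution of any fit; the public functions in :mod:`rrwm.costs` remain
the exact reference implementations.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
from scipy import special
from scipy.interpolate import PchipInterpolator

from .circdist import TAU_FLOOR, j_to_kappa
from .costs import CostSpec, expected_cost_kappa, behavioral_cost

_KAPPA_MIN = 1e-8
_KAPPA_MAX = 1e8
_N_KAPPA = 320

_LOG_UNDERFLOW = -745.0  # exp() underflows to 0.0 below this


class CostKappaTable:
    """Interpolant of the expected pointwise cost under VM(kappa)."""

    def __init__(self, spec: CostSpec, n_eps: int = 256):
        self.spec = spec
        grid = np.logspace(np.log10(_KAPPA_MIN), np.log10(_KAPPA_MAX), _N_KAPPA)
        vals = expected_cost_kappa(grid, spec, n_eps=n_eps, method="gauss")
        self._log_grid = np.log(grid)
        self._interp = PchipInterpolator(self._log_grid, vals, extrapolate=False)
        # limits: kappa -> 0 is the uniform circle, kappa -> inf pins the
        # error at 0
        self.uniform_cost = float(expected_cost_kappa(np.array([0.0]), spec)[0])
        self.zero_error_cost = float(behavioral_cost(0.0, spec))

    def __call__(self, kappa):
        kappa = np.asarray(kappa, dtype=float)
        out = np.empty_like(kappa)
        lo = kappa < _KAPPA_MIN
        hi = kappa > _KAPPA_MAX
        mid = ~(lo | hi)
        out[lo] = self.uniform_cost
        out[hi] = self.zero_error_cost
        if np.any(mid):
            out[mid] = self._interp(np.log(kappa[mid]))
        return out


_cost_tables: OrderedDict = OrderedDict()
_COST_TABLE_CACHE = 128


def cost_table(spec: CostSpec) -> CostKappaTable:
    key = spec.cache_key()
    tab = _cost_tables.get(key)
    if tab is None:
        tab = CostKappaTable(spec)
        _cost_tables[key] = tab
        while len(_cost_tables) > _COST_TABLE_CACHE:
            _cost_tables.popitem(last=False)
    else:
        _cost_tables.move_to_end(key)
    return tab


class _GammaQuantileTable:
    """log central-bin quantiles of a unit-scale gamma vs log shape."""

    def __init__(self, n_bins: int, n_shape: int = 700):
        self.levels = (np.arange(n_bins) + 0.5) / n_bins
        self.log_shape = np.linspace(np.log(1e-9), np.log(1e12), n_shape)
        shapes = np.exp(self.log_shape)
        q = special.gammaincinv(shapes[:, None], self.levels[None, :])
        with np.errstate(divide="ignore"):
            self.log_q = np.maximum(np.log(q), _LOG_UNDERFLOW)

    def bin_centers(self, J_bar, tau: float):
        """Quantile matrix (len(J_bar), n_bins) of gamma(mean J_bar, scale tau)."""
        J_bar = np.asarray(J_bar, dtype=float)
        log_shape = np.log(np.maximum(J_bar, 1e-300) / tau)
        out = np.empty((J_bar.size, self.levels.size))
        for j in range(self.levels.size):
            out[:, j] = np.interp(log_shape, self.log_shape, self.log_q[:, j])
        centers = tau * np.exp(out)
        centers[J_bar == 0.0, :] = 0.0
        return centers


_quantile_tables: dict[int, _GammaQuantileTable] = {}


def gamma_quantile_table(n_bins: int) -> _GammaQuantileTable:
    tab = _quantile_tables.get(n_bins)
    if tab is None:
        tab = _GammaQuantileTable(n_bins)
        _quantile_tables[n_bins] = tab
    return tab


class _KappaTable:
    """Interpolant of the J -> kappa inversion on a log-log grid.

    Outside the tabulated range the exact asymptotics are used
    (kappa ~ sqrt(2 J) for small J, kappa ~ J + 1/2 for large J).
    """

    def __init__(self, n: int = 1600):
        self.log_j = np.linspace(np.log(1e-12), np.log(1e8), n)
        self.log_k = np.log(j_to_kappa(np.exp(self.log_j)))

    def __call__(self, J):
        J = np.asarray(J, dtype=float)
        out = np.empty_like(J)
        zero = J <= 0
        lo = (J < 1e-12) & ~zero
        hi = J > 1e8
        mid = ~(zero | lo | hi)
        out[zero] = 0.0
        out[lo] = np.sqrt(2.0 * J[lo])
        out[hi] = J[hi] + 0.5
        if np.any(mid):
            out[mid] = np.exp(np.interp(np.log(J[mid]), self.log_j, self.log_k))
        return out


_kappa_table: list = []


def fast_j_to_kappa(J):
    if not _kappa_table:
        _kappa_table.append(_KappaTable())
    return _kappa_table[0](J)


def bin_kappas(J_bar, tau: float, n_bins: int = 50):
    """Von Mises concentrations of the precision bins for each J_bar.

    Returns an array of shape (len(J_bar), n_bins) -- or (len(J_bar), 1)
    on the equal-precision branch (tau below the point-mass floor).
    """
    J_bar = np.atleast_1d(np.asarray(J_bar, dtype=float))
    if tau < TAU_FLOOR:
        centers = J_bar[:, None]
    else:
        centers = gamma_quantile_table(n_bins).bin_centers(J_bar, tau)
    return fast_j_to_kappa(centers)


def cbar_values(J_bar, tau: float, table: CostKappaTable, n_bins: int = 50):
    """Expected behavioral cost for a vector of J_bar values (fast path)."""
    kappas = bin_kappas(J_bar, tau, n_bins)
    return table(kappas).mean(axis=1)
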