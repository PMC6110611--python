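"""Optimal resource allocation.

The resource-rational policy invests, for each item with probing
probability (or, more generally, relevance) ``p``, the mean precision

    J_opt(p) = argmin_{J >= 0}  p * cbar(J; tau) + lambda * J,

where ``cbar`` is the expected behavioral cost and ``lambda`` weights the
linear neural cost.  Because the display objective separates over items,
each element of the optimal allocation is a one-dimensional problem.

The probing-probability axis splits into up to three regimes: below a
threshold ``p0`` the optimum is J = 0 (not encoding at all), between
``p0`` and ``p_inf`` it is finite and increasing in p, and above ``p_inf``
the objective decreases without bound (only possible in extreme cases
such as lambda = 0).  ``p0 = lambda / |cbar'(0)|`` and
``p_inf = lambda / |cbar'(inf)|`` follow from the first-order condition
at the boundaries; both are cross-checkable by bisection on p of the
indicator that the optimizer returns a strictly positive (resp. bounded)
resource.

Alternative allocation policies compared against the rational one:
a fixed total divided equally (``fixed_equal``), a power law in set size
(``power_law``, J1 * N**(-a)), allocation proportional to probing
probability (``emrich_proportional``), optimal division of a *fixed*
total (``bays_fixed_total``, solved by water-filling on the equalized
marginal benefit), and a free resource value per condition
(``nonparametric``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from . import _fast
from .costs import CostSpec, expected_behavioral_cost, expected_cost_derivative

__all__ = [
    "ModelParams",
    "AllocationPolicy",
    "Thresholds",
    "TotalResourceCurve",
    "J_GRID_LO",
    "J_GRID_HI",
    "optimal_resource",
    "optimal_resource_many",
    "thresholds",
    "p0_bisect",
    "allocate_display",
    "total_resource_curve",
]

# search window for the per-item optimum; the upper bound doubles as the
# "unbounded" sentinel (objective still decreasing there)
J_GRID_LO = 1e-6
J_GRID_HI = 1e5
_N_GRID = 200
_J_GRID = np.concatenate(([0.0], np.logspace(np.log10(J_GRID_LO), np.log10(J_GRID_HI), _N_GRID)))
_LOG_J_GRID = np.log(_J_GRID[1:])

POLICY_KINDS = (
    "rational",
    "bays_fixed_total",
    "emrich_proportional",
    "fixed_equal",
    "power_law",
    "nonparametric",
)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the rational model: neural weight, variability, cost."""

    lambda_: float
    tau: float
    cost: CostSpec = field(default_factory=CostSpec)
    alpha: float = 1.0

    def __post_init__(self):
        if self.lambda_ < 0 or self.tau < 0:
            raise ValueError("lambda_ and tau must be >= 0")


@dataclass(frozen=True)
class AllocationPolicy:
    """Which allocation rule produces the per-item mean precisions."""

    kind: str = "rational"
    J_total: float | None = None      # bays / emrich / fixed_equal
    J1: float | None = None           # power_law: J_bar(N) = J1 * N**(-a)
    a: float | None = None
    table: tuple | None = None        # nonparametric: ((key, J_bar), ...)
    table_by: str = "p"               # nonparametric keys: "p" or "set_size"

    def __post_init__(self):
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")

    def lookup(self, key) -> float:
        if self.table is None:
            raise ValueError("nonparametric policy has no table")
        for k, v in self.table:
            if np.isclose(k, key, rtol=1e-9, atol=1e-12):
                return float(v)
        raise KeyError(f"no table entry for condition {key!r}")


@dataclass(frozen=True)
class Thresholds:
    """Regime boundaries on the probing-probability axis."""

    p0: float
    p_inf: float


@dataclass(frozen=True)
class TotalResourceCurve:
    """Total invested resource along a set-size or probing-probability grid."""

    index: np.ndarray          # set sizes or probing probabilities
    per_item: np.ndarray       # J_opt for a single item
    total: np.ndarray          # summed over the display
    by: str                    # "set_size" or "p"

    @property
    def peak(self) -> float:
        """Grid location of the maximum total resource (N_peak or p_peak)."""
        return float(self.index[int(np.argmax(self.total))])


def _uniform_cost(params: ModelParams) -> float:
    return _fast.cost_table(params.cost).uniform_cost


def _grid_objective(p: float, params: ModelParams, cbar_grid: np.ndarray) -> np.ndarray:
    return p * cbar_grid + params.lambda_ * params.alpha * _J_GRID


def _refine_exact(p: float, params: ModelParams, lo: float, hi: float) -> float:
    lam = params.lambda_ * params.alpha

    def f(t):
        J = np.exp(t)
        return p * expected_behavioral_cost(J, params.tau, params.cost) + lam * J

    res = minimize_scalar(f, bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-9})
    return float(np.exp(res.x))


def _refine_parabolic(i: int, f: np.ndarray) -> float:
    """Vertex of the parabola through three neighbouring log-grid points."""
    t = _LOG_J_GRID[i - 1:i + 2]
    y = f[i:i + 3]  # f includes the J = 0 entry at index 0
    denom = (y[0] - 2.0 * y[1] + y[2])
    if denom <= 0:
        return float(np.exp(t[1]))
    vertex = t[1] - 0.5 * (y[2] - y[0]) / denom * (t[2] - t[1])
    return float(np.exp(np.clip(vertex, t[0], t[2])))


def optimal_resource_many(ps, params: ModelParams, refine: str = "exact"):
    """J_opt for several probing probabilities, sharing the grid scan.

    ``refine="exact"`` polishes the grid minimum with a bounded search on
    the exact expected-cost quadrature; ``refine="grid"`` uses a parabolic
    interpolation of the grid values (the fast path used while fitting).
    Returns ``np.inf`` where the objective is still decreasing at the
    upper end of the search window (the unbounded regime).
    """
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("probing probabilities must lie in [0, 1]")
    lam = params.lambda_ * params.alpha
    out = np.zeros(ps.shape)
    if lam == 0.0:
        out[ps > 0] = np.inf
        return out
    table = _fast.cost_table(params.cost)
    cbar_grid = np.empty_like(_J_GRID)
    cbar_grid[0] = table.uniform_cost
    cbar_grid[1:] = _fast.cbar_values(_J_GRID[1:], params.tau, table)
    for k, p in np.ndenumerate(ps):
        if p == 0.0:
            continue
        f = _grid_objective(p, params, cbar_grid)
        i = int(np.argmin(f[1:]))  # interior candidate (index into log grid)
        if i == _N_GRID - 1 and f[-1] < f[-2]:
            out[k] = np.inf
            continue
        if refine == "exact":
            lo = _J_GRID[1:][max(i - 1, 0)]
            hi = _J_GRID[1:][min(i + 1, _N_GRID - 1)]
            if i == 0:
                lo = J_GRID_LO * 1e-3
            J_star = _refine_exact(p, params, lo, hi)
            f_star = (p * expected_behavioral_cost(J_star, params.tau, params.cost)
                      + lam * J_star)
        elif refine == "grid":
            if 0 < i < _N_GRID - 1:
                J_star = _refine_parabolic(i, f)
                f_star = (p * float(_fast.cbar_values(np.array([J_star]), params.tau, table)[0])
                          + lam * J_star)
                if f_star > f[1 + i]:
                    J_star, f_star = _J_GRID[1 + i], f[1 + i]
            else:
                J_star, f_star = _J_GRID[1 + i], f[1 + i]
        else:
            raise ValueError(f"unknown refine mode {refine!r}")
        # explicit comparison against the J = 0 boundary; ties go to 0
        if f[0] <= f_star:
            out[k] = 0.0
        else:
            out[k] = J_star
    return out


def optimal_resource(p: float, params: ModelParams, refine: str = "exact") -> float:
    """Per-item optimal mean precision J_opt(p); inf flags the unbounded regime."""
    return float(optimal_resource_many(np.array([p]), params, refine=refine)[0])


_DERIV_VANISH = 1e-12


def thresholds(params: ModelParams) -> Thresholds:
    """Regime thresholds p0 and p_inf from the boundary derivatives of cbar.

    p0 = lambda / |cbar'(0)| (zero when the derivative diverges) and
    p_inf = lambda / |cbar'(inf)| (infinite when the derivative vanishes
    at large J, which holds for every bounded cost family here).
    """
    lam = params.lambda_ * params.alpha
    if lam == 0.0:
        return Thresholds(p0=0.0, p_inf=0.0)
    d0 = expected_cost_derivative(0.0, params.tau, params.cost)
    if np.isinf(d0):
        p0 = 0.0
    elif abs(d0) < _DERIV_VANISH:
        p0 = np.inf
    else:
        p0 = lam / abs(d0)
    d_inf = expected_cost_derivative(J_GRID_HI, params.tau, params.cost)
    p_inf = np.inf if abs(d_inf) < _DERIV_VANISH else lam / abs(d_inf)
    return Thresholds(p0=float(p0), p_inf=float(p_inf))


def p0_bisect(params: ModelParams, p_lo: float = 1e-6, p_hi: float = 1.0,
              tol: float = 1e-6, refine: str = "exact") -> float:
    """Encode-nothing threshold by bisection on [J_opt(p) > 0].

    Returns the infimum probing probability at which the optimizer invests
    a strictly positive resource, resolved to ``tol``; returns ``p_lo``
    when even the smallest probed probability already warrants encoding,
    and ``p_hi`` when no probability in the bracket does.
    """
    def encodes(p):
        return optimal_resource(p, params, refine=refine) > 0.0

    if encodes(p_lo):
        return float(p_lo)
    if not encodes(p_hi):
        return float(p_hi)
    lo, hi = p_lo, p_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if encodes(mid):
            hi = mid
        else:
            lo = mid
    return float(0.5 * (lo + hi))


def _bays_water_filling(r: np.ndarray, J_total: float, params: ModelParams) -> np.ndarray:
    """Minimize sum_i r_i cbar(J_i) subject to sum_i J_i = J_total, J_i >= 0.

    KKT: items receiving resource equalize the marginal benefit
    r_i |cbar'(J_i)| at a shared multiplier mu; items whose marginal
    benefit at J = 0 is below mu receive nothing.  The shared multiplier
    is found by bisection, with the per-item inversion of |cbar'| done on
    a dense log grid.
    """
    table = _fast.cost_table(params.cost)
    J_hi = max(2.0 * J_total, 10.0)
    grid = np.logspace(np.log10(1e-8), np.log10(J_hi), 600)
    cb = _fast.cbar_values(grid, params.tau, table)
    g_raw = np.maximum(-np.gradient(cb, grid), 0.0)   # marginal benefit |cbar'(J)|
    # with precision variability the marginal benefit first rises (the
    # onset region near J = 0) and only then diminishes; the KKT inversion
    # lives on the decreasing branch past the peak, and allocations below
    # the onset are never part of an optimum
    ipeak = int(np.argmax(g_raw))
    grid = grid[ipeak:]
    g = np.maximum(np.minimum.accumulate(g_raw[ipeak:]), 1e-300)

    def alloc(mu):
        # J_i = g^{-1}(mu / r_i) for active items, on the grid inverse
        out = np.zeros_like(r)
        active = r > 0
        targets = mu / r[active]
        # g is decreasing: invert by interpolating on reversed arrays
        out[active] = np.interp(targets, g[::-1], grid[::-1],
                                left=grid[-1], right=0.0)
        return out

    mu_lo, mu_hi = 1e-12, float(np.max(r) * g[0] if np.max(r) > 0 else 1.0)
    if not np.isfinite(mu_hi):
        mu_hi = 1e12
    for _ in range(200):
        mu = np.sqrt(mu_lo * mu_hi)
        total = alloc(mu).sum()
        if total > J_total:
            mu_lo = mu
        else:
            mu_hi = mu
        if mu_hi / mu_lo < 1.0 + 1e-12:
            break
    J = alloc(np.sqrt(mu_lo * mu_hi))
    s = J.sum()
    if s > 0:
        J = J * (J_total / s)               # close the constraint exactly
    elif J_total > 0 and np.any(r > 0):
        raise RuntimeError("bays water-filling failed to place any resource")
    return J


def allocate_display(p_vector, policy: AllocationPolicy, params: ModelParams,
                     weights=None, refine: str = "exact") -> np.ndarray:
    """Per-item mean precisions for one display under a given policy.

    ``weights`` are optional incentive multipliers u_i; the rational and
    bays policies act on the item relevances r_i = u_i * p_i.
    """
    p = np.asarray(p_vector, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probing probabilities must lie in [0, 1]")
    N = p.size
    u = np.ones(N) if weights is None else np.asarray(weights, dtype=float)
    if np.any(u < 0):
        raise ValueError("incentive weights must be >= 0")
    r = u * p
    kind = policy.kind
    if kind == "rational":
        uniq, inv = np.unique(r, return_inverse=True)
        return optimal_resource_many(uniq, params, refine=refine)[inv]
    if kind == "fixed_equal":
        return np.full(N, policy.J_total / N)
    if kind == "emrich_proportional":
        return p * policy.J_total
    if kind == "power_law":
        return np.full(N, policy.J1 * N ** (-policy.a))
    if kind == "nonparametric":
        if policy.table_by == "set_size":
            return np.full(N, policy.lookup(N))
        return np.array([policy.lookup(pi) for pi in p])
    if kind == "bays_fixed_total":
        return _bays_water_filling(r, policy.J_total, params)
    raise AssertionError(kind)


def total_resource_curve(params: ModelParams, set_sizes=None, p_grid=None,
                         refine: str = "exact") -> TotalResourceCurve:
    """Total invested resource versus set size (at p = 1/N) or versus p.

    Along set size, J_total(N) = N * J_opt(1/N); along probing
    probability, J_total(p) = J_opt(p) / p (the total a subject would
    spend on a display filled with items of identical probability p).
    The two parameterizations coincide at p = 1/N.
    """
    if (set_sizes is None) == (p_grid is None):
        raise ValueError("provide exactly one of set_sizes or p_grid")
    if set_sizes is not None:
        N = np.asarray(set_sizes, dtype=float)
        per_item = optimal_resource_many(1.0 / N, params, refine=refine)
        return TotalResourceCurve(index=N, per_item=per_item,
                                  total=N * per_item, by="set_size")
    p = np.asarray(p_grid, dtype=float)
    if np.any(p <= 0):
        raise ValueError("p_grid entries must be > 0")
    per_item = optimal_resource_many(p, params, refine=refine)
    return TotalResourceCurve(index=p, per_item=per_item,
                              total=per_item / p, by="p")
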