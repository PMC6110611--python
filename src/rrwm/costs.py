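"""Behavioral and neural cost functions.

A behavioral cost function maps a circular estimation error ``epsilon`` to
a scalar cost.  Implemented families:

``power``
    |eps|**beta with free exponent beta > 0 (the default model family).
``abs``, ``squared``, ``neg_cosine``
    The parameter-free alternatives |eps|, eps**2 and -cos(eps).
``saturating_two_param``
    A two-parameter saturating map c(eps; s, gamma) = 1 - exp(-(|eps|/s)**gamma),
    which rises like a power law for small errors and saturates at 1 for
    large ones (params = (s, gamma)).
``binary_threshold``
    Binary feedback: cost 0 for |eps| < theta_fb, cost 1 otherwise
    (params = (theta_fb,)).

The *expected* behavioral cost at mean precision ``J_bar`` integrates the
pointwise cost against the predicted error distribution (Von Mises
marginalized over gamma-variable precision).  The expected neural cost of
a display is linear in the total invested precision, alpha * sum(J_bar_i),
independent of the precision variability tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .circdist import (
    TAU_FLOOR,
    PrecisionDistribution,
    discretize_precision,
    j_to_kappa,
    vm_pdf_kappa,
)

__all__ = [
    "COST_FAMILIES",
    "CostSpec",
    "NeuralCostSpec",
    "behavioral_cost",
    "expected_behavioral_cost",
    "expected_cost_kappa",
    "expected_cost_derivative",
    "display_neural_cost",
]

COST_FAMILIES = (
    "power",
    "abs",
    "squared",
    "neg_cosine",
    "saturating_two_param",
    "binary_threshold",
)

#: Number of points of the composite trapezoid rule on [0, pi]; doubled by
#: symmetry this is the periodic trapezoid rule on the full circle, which
#: converges spectrally for smooth periodic integrands.
N_EPS_QUAD = 2000


@dataclass(frozen=True)
class CostSpec:
    """Which behavioral cost family, plus its parameters."""

    family: str = "power"
    beta: float | None = 2.0
    params: tuple = field(default=())

    def __post_init__(self):
        if self.family not in COST_FAMILIES:
            raise ValueError(f"unknown cost family {self.family!r}")
        if self.family == "power":
            if self.beta is None or self.beta <= 0:
                raise ValueError("power family requires beta > 0")
        if self.family == "saturating_two_param":
            if len(self.params) != 2 or min(self.params) <= 0:
                raise ValueError("saturating family requires params = (s, gamma), both > 0")
        if self.family == "binary_threshold":
            if len(self.params) != 1 or not (0 < self.params[0] <= np.pi):
                raise ValueError("binary_threshold requires params = (theta_fb,) in (0, pi]")

    def with_beta(self, beta: float) -> "CostSpec":
        return CostSpec(self.family, beta=beta, params=self.params)

    def cache_key(self):
        return (self.family, self.beta, self.params)


@dataclass(frozen=True)
class NeuralCostSpec:
    """Linear neural cost: alpha per unit of invested precision (alpha = 1)."""

    alpha: float = 1.0


def behavioral_cost(epsilon, spec: CostSpec):
    """Pointwise cost of an error; even in epsilon; vectorized."""
    a = np.abs(np.asarray(epsilon, dtype=float))
    if spec.family == "power":
        return a ** spec.beta
    if spec.family == "abs":
        return a
    if spec.family == "squared":
        return a ** 2
    if spec.family == "neg_cosine":
        return -np.cos(a)
    if spec.family == "saturating_two_param":
        s, gamma = spec.params
        return 1.0 - np.exp(-((a / s) ** gamma))
    if spec.family == "binary_threshold":
        theta = spec.params[0]
        return (a >= theta).astype(float)
    raise AssertionError(spec.family)


def _vm_tail_prob(theta: float, kappa):
    """P(|eps| >= theta) under a zero-mean Von Mises with concentration kappa."""
    kappa = np.asarray(kappa, dtype=float)
    out = np.empty_like(kappa)
    tiny = kappa < 1e-12
    out[tiny] = 1.0 - theta / np.pi
    if np.any(~tiny):
        k = kappa[~tiny]
        out[~tiny] = 1.0 - (stats.vonmises.cdf(theta, k) - stats.vonmises.cdf(-theta, k))
    return out


@lru_cache(maxsize=8)
def _gauss_nodes(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * np.pi * (x + 1.0), 0.5 * np.pi * w


def expected_cost_kappa(kappa, spec: CostSpec, n_eps: int = N_EPS_QUAD,
                        method: str = "trapezoid"):
    """Expected cost under a single Von Mises component, E[c(eps) | kappa].

    Default quadrature is the trapezoid rule on [0, pi] doubled by
    symmetry (the periodic trapezoid rule on the circle);
    ``method="gauss"`` uses Gauss-Legendre on [0, pi], which reaches the
    same accuracy with far fewer nodes and backs the cached fast tables.
    The binary-threshold family is evaluated exactly through the Von
    Mises CDF, so the discontinuity costs no quadrature error.
    """
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    if spec.family == "binary_threshold":
        return _vm_tail_prob(spec.params[0], kappa)
    if method == "gauss":
        eps, w = _gauss_nodes(n_eps)
        dens = vm_pdf_kappa(eps[None, :], kappa[:, None])
        return 2.0 * (dens @ (behavioral_cost(eps, spec) * w))
    eps = np.linspace(0.0, np.pi, n_eps)
    cvals = behavioral_cost(eps, spec)
    dens = vm_pdf_kappa(eps[None, :], kappa[:, None])
    return 2.0 * np.trapezoid(cvals[None, :] * dens, eps, axis=1)


def expected_behavioral_cost(J_bar: float, tau: float, spec: CostSpec,
                             n_bins: int = 50) -> float:
    """Expected behavioral cost at mean precision J_bar and variability tau.

    Averages E[c | kappa] over the equal-probability discretization of the
    gamma distribution of precision.  Monotonically non-increasing in
    J_bar for all families whose cost increases with |eps|.
    """
    centers, masses = discretize_precision(
        PrecisionDistribution(J_bar=float(J_bar), tau=float(tau), n_bins=n_bins))
    kappas = np.atleast_1d(j_to_kappa(centers))
    return float(expected_cost_kappa(kappas, spec) @ masses)


#: A derivative whose magnitude keeps growing by at least this factor per
#: decade of step shrinkage (or exceeds DERIV_DIVERGENCE_CAP outright) is
#: reported as divergent (-inf).  The canonical divergent case, the
#: tau -> 0 branch at J_bar = 0, has slope ~ 1/sqrt(step), i.e. growth
#: factor sqrt(10) ~ 3.16 per decade.
DERIV_GROWTH_FACTOR = 2.0
DERIV_DIVERGENCE_CAP = 1e8


def _cost_derivative_at_zero_gamma(tau: float, spec: CostSpec, n_nodes: int = 96) -> float:
    """Exact boundary derivative of the *continuous* gamma mixture at J_bar = 0.

    For a gamma with mean J_bar and scale tau the shape J_bar/tau tends to
    0 with J_bar, and the density tends to (J_bar/tau) e^(-J/tau) / J, so

        cbar'(0) = (1/tau) * int_0^inf (E[c|J] - c_uniform) e^(-J/tau) dJ / J.

    Substituting J = tau x and pulling out the integrable x**(-1/2)
    behaviour of the integrand near 0 makes this a generalized
    Gauss-Laguerre quadrature (weight x**(-1/2) e^(-x)).  Finite
    differences of the 50-bin discretized cbar cannot recover this limit:
    every equal-probability quantile of a gamma with shape -> 0 collapses
    to 0, so the discretized cbar is artificially flat at the origin.
    """
    nodes, w = special.roots_genlaguerre(n_nodes, -0.5)
    c0 = float(expected_cost_kappa(np.array([0.0]), spec)[0])
    vals = expected_cost_kappa(np.atleast_1d(j_to_kappa(tau * nodes)), spec)
    h = (vals - c0) / np.sqrt(nodes)
    return float((w @ h) / tau)


def expected_cost_derivative(J_bar: float, tau: float, spec: CostSpec,
                             n_bins: int = 50) -> float:
    """d cbar / d J_bar by finite differences, with divergence detection.

    Central differences away from 0, one-sided at J_bar = 0.  If the slope
    magnitude keeps growing as the step shrinks (or exceeds a hard cap),
    the derivative is reported as -inf (the cost families here are
    non-increasing in J_bar, so a divergence is always towards -inf).
    At J_bar = 0 with variable precision the analytic continuous-gamma
    limit is used instead (see :func:`_cost_derivative_at_zero_gamma`).
    """
    J_bar = float(J_bar)
    if J_bar == 0.0 and tau >= TAU_FLOOR:
        return _cost_derivative_at_zero_gamma(tau, spec)
    steps = (1e-4, 1e-5, 1e-6)
    slopes = []
    for h in steps:
        if J_bar < h:
            s = (expected_behavioral_cost(J_bar + h, tau, spec, n_bins)
                 - expected_behavioral_cost(J_bar, tau, spec, n_bins)) / h
        else:
            s = (expected_behavioral_cost(J_bar + h, tau, spec, n_bins)
                 - expected_behavioral_cost(J_bar - h, tau, spec, n_bins)) / (2.0 * h)
        slopes.append(s)
    mags = np.abs(slopes)
    if mags[-1] > DERIV_DIVERGENCE_CAP or (
            mags[-1] > DERIV_GROWTH_FACTOR * mags[-2] > DERIV_GROWTH_FACTOR ** 2 * mags[-3]
            and mags[-1] > 1.0):
        return float("-inf") if slopes[-1] < 0 else float("inf")
    return float(slopes[-1])


def display_neural_cost(J_bar_vector, spec: NeuralCostSpec = NeuralCostSpec()) -> float:
    """Expected neural cost of a display: alpha * sum_i J_bar_i."""
    J = np.asarray(J_bar_vector, dtype=float)
    if np.any(J < 0):
        raise ValueError("J_bar entries must be >= 0")
    return float(spec.alpha * J.sum())
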