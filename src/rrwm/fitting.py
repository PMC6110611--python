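"""Maximum-likelihood fitting and model comparison for trial-level data.

A dataset is a flat table with one row per trial: subject id, set size N,
probing probability of the probed item, the circular estimation error in
radians, and a free-form condition tag.  The likelihood of a trial is the
predicted error density at the probed item's mean precision J_bar, which
each model variant resolves from the trial's condition:

* ``rational``          -- J_bar = argmin_J p * cbar(J; tau) + lambda * J
* ``power_law``         -- J_bar = J1 * N**(-a)  (the descriptive VP-A form)
* ``fixed_equal``       -- J_bar = J_total / N
* ``emrich_proportional`` -- J_bar = p * J_total
* ``bays_fixed_total``  -- optimal division of a fixed total J_total over
  the display (requires the display's probing-probability vector, passed
  through the model's ``displays`` map keyed by condition tag)
* ``nonparametric``     -- J_bar is a free parameter for every condition

Fitting maximizes the summed log likelihood with a coarse log-space grid
search followed by Nelder-Mead from the best grid points (positive
parameters are fitted in log space).  Model comparison uses AIC
(2 k - 2 log L) and interleaved five-fold cross-validation: fold k holds
out trials k, k+5, k+10, ... in presentation order, the model is refit on
the remaining 80%, and the held-out log likelihoods are summed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from . import _fast
from .allocator import (
    AllocationPolicy,
    J_GRID_HI,
    ModelParams,
    allocate_display,
    optimal_resource_many,
)
from .circdist import wrap_angle
from .costs import CostSpec

__all__ = [
    "TRIAL_COLUMNS",
    "TrialRecord",
    "ModelSpec",
    "FitOptions",
    "FitResult",
    "model_spec",
    "read_trials",
    "write_trials",
    "trial_loglik",
    "dataset_loglik",
    "fit_mle",
    "crossval_5fold",
    "aic_compare",
]

TRIAL_COLUMNS = ("subject", "set_size", "p_probe", "error_rad", "condition_tag")

_DENSITY_FLOOR = 1e-300

MODEL_NAMES = (
    "rational",
    "power_law",
    "fixed_equal",
    "emrich_proportional",
    "bays_fixed_total",
    "nonparametric",
)

# log-space fitting bounds for the positive parameters
_BOUNDS = {
    "beta": (1e-3, 10.0),
    "lambda": (1e-6, 1.0),
    "tau": (1e-3, 1e2),
    "J1": (1e-2, 1e4),
    "J_total": (1e-2, 1e4),
    "s": (1e-2, np.pi),
    "gamma": (0.2, 10.0),
}
_LINEAR_PARAMS = {"a": (-1.0, 3.0)}  # power-law exponent may be any sign

_DEFAULT_GRID = {
    "beta": np.logspace(-2, 0.8, 5),
    "lambda": np.logspace(-5, -0.5, 6),
    "tau": np.logspace(-2, 1.8, 4),
    "J1": np.logspace(-0.5, 2.5, 6),
    "J_total": np.logspace(-0.5, 2.5, 6),
    "a": np.array([0.0, 0.5, 1.0, 1.5]),
    "s": np.array([0.3, 1.0, 2.0]),
    "gamma": np.array([0.7, 2.0]),
}


@dataclass(frozen=True)
class TrialRecord:
    """One behavioral trial of a delayed-estimation experiment."""

    subject: str
    set_size: int
    p_probe: float
    error: float
    condition_tag: str = ""

    def __post_init__(self):
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")
        if not 0.0 < self.p_probe <= 1.0:
            raise ValueError("p_probe must lie in (0, 1]")


@dataclass(frozen=True)
class ModelSpec:
    """A model variant: allocation policy, cost family, fixed parameters."""

    name: str
    policy_kind: str
    cost_family: str = "power"
    cost_params: tuple = ()
    fix_tau: float | None = None
    displays: tuple = ()          # ((tag, p_vector), ...), for bays_fixed_total

    @property
    def free_params(self) -> tuple:
        ps: list[str] = []
        uses_cost = self.policy_kind in ("rational", "bays_fixed_total")
        if uses_cost and self.cost_family == "power":
            ps.append("beta")
        if uses_cost and self.cost_family == "saturating_two_param":
            ps += ["s", "gamma"]
        if self.policy_kind == "rational":
            ps.append("lambda")
        if self.policy_kind in ("fixed_equal", "emrich_proportional", "bays_fixed_total"):
            ps.append("J_total")
        if self.policy_kind == "power_law":
            ps += ["J1", "a"]
        if self.fix_tau is None:
            ps.append("tau")
        return tuple(ps)

    def n_params(self, data: pd.DataFrame | None = None) -> int:
        if self.policy_kind == "nonparametric":
            if data is None:
                raise ValueError("nonparametric parameter count depends on the data")
            n_cond = len(_conditions(data))
            return n_cond + (0 if self.fix_tau is not None else 1)
        return len(self.free_params)

    def cost_spec(self, theta: dict) -> CostSpec:
        if self.cost_family == "power":
            return CostSpec("power", beta=float(theta["beta"]))
        if self.cost_family == "saturating_two_param":
            return CostSpec("saturating_two_param", beta=None,
                            params=(float(theta["s"]), float(theta["gamma"])))
        return CostSpec(self.cost_family, beta=None, params=self.cost_params)

    def tau_of(self, theta: dict) -> float:
        return float(self.fix_tau if self.fix_tau is not None else theta["tau"])


def model_spec(name: str, cost_family: str = "power", cost_params: tuple = (),
               fix_tau: float | None = None, displays=None) -> ModelSpec:
    """Construct a :class:`ModelSpec` by variant name (see module docstring)."""
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}")
    disp = tuple((tag, tuple(p)) for tag, p in (displays or {}).items())
    return ModelSpec(name=name, policy_kind=name, cost_family=cost_family,
                     cost_params=tuple(cost_params), fix_tau=fix_tau, displays=disp)


@dataclass(frozen=True)
class FitOptions:
    """Search effort knobs for the grid-seeded maximum-likelihood fit."""

    n_starts: int = 3
    maxfev: int = 300
    xatol: float = 1e-3
    fatol: float = 1e-3
    n_bins: int = 50
    grid: dict = field(default_factory=dict)   # per-parameter override values

    def grid_for(self, name: str):
        return np.asarray(self.grid.get(name, _DEFAULT_GRID[name]), dtype=float)


#: lighter search used inside recovery sweeps and cross-validation folds
FAST_OPTIONS = FitOptions(n_starts=1, maxfev=160)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit summary for one subject and one model."""

    model: ModelSpec
    theta: dict
    loglik: float
    n_params: int
    n_trials: int
    seed: int
    cv_loglik: float | None = None
    cv_fold_logliks: tuple | None = None

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


# ---------------------------------------------------------------------------
# trial tables

def read_trials(path) -> pd.DataFrame:
    """Read a tab-separated trial table (header: subject, set_size, p_probe,
    error_rad, condition_tag); errors are wrapped to [-pi, pi)."""
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "condition_tag": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    df["condition_tag"] = df["condition_tag"].fillna("")
    df["error_rad"] = wrap_angle(df["error_rad"].to_numpy(float))
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(TRIAL_COLUMNS))


def _conditions(data: pd.DataFrame) -> list[tuple]:
    """Unique (set_size, p_probe, condition_tag) triples, in sorted order."""
    trips = (data[["set_size", "p_probe", "condition_tag"]]
             .drop_duplicates().sort_values(["set_size", "p_probe", "condition_tag"]))
    return list(trips.itertuples(index=False, name=None))


# ---------------------------------------------------------------------------
# likelihood

def _condition_jbars(spec: ModelSpec, theta: dict, conds: list[tuple],
                     n_bins: int = 50) -> np.ndarray:
    """Resolve the probed item's mean precision for every condition."""
    N = np.array([c[0] for c in conds], dtype=float)
    p = np.array([c[1] for c in conds], dtype=float)
    kind = spec.policy_kind
    if kind == "rational":
        params = ModelParams(lambda_=float(theta["lambda"]), tau=spec.tau_of(theta),
                             cost=spec.cost_spec(theta))
        uniq, inv = np.unique(p, return_inverse=True)
        J = optimal_resource_many(uniq, params, refine="grid")[inv]
        return np.minimum(J, J_GRID_HI)   # unbounded regime capped at the window edge
    if kind == "power_law":
        return float(theta["J1"]) * N ** (-float(theta["a"]))
    if kind == "fixed_equal":
        return float(theta["J_total"]) / N
    if kind == "emrich_proportional":
        return p * float(theta["J_total"])
    if kind == "nonparametric":
        return np.array([float(theta[f"J_{i}"]) for i in range(len(conds))])
    if kind == "bays_fixed_total":
        disp = dict(spec.displays)
        params = ModelParams(lambda_=0.0, tau=spec.tau_of(theta),
                             cost=spec.cost_spec(theta))
        policy = AllocationPolicy("bays_fixed_total", J_total=float(theta["J_total"]))
        out = np.empty(len(conds))
        cache: dict = {}
        for i, (n_i, p_i, tag) in enumerate(conds):
            if tag not in disp:
                raise KeyError(f"bays_fixed_total needs a display vector for tag {tag!r}")
            pv = np.asarray(disp[tag], dtype=float)
            if tag not in cache:
                cache[tag] = allocate_display(pv, policy, params)
            j = int(np.argmin(np.abs(pv - p_i)))
            out[i] = cache[tag][j]
        return out
    raise AssertionError(kind)


def _cond_logpdf(errors: np.ndarray, J_bar: float, tau: float, n_bins: int) -> np.ndarray:
    kappas = _fast.bin_kappas(np.array([J_bar]), tau, n_bins)[0]
    from .circdist import vm_pdf_kappa
    dens = vm_pdf_kappa(errors[:, None], kappas[None, :]).mean(axis=1)
    return np.log(np.maximum(dens, _DENSITY_FLOOR))


@dataclass(frozen=True)
class _PreparedData:
    """Trial table grouped by condition once, for repeated likelihood evals."""

    conds: tuple
    errors: tuple   # one error array per condition, aligned with conds
    n: int


def _prepare(data: pd.DataFrame) -> _PreparedData:
    conds = _conditions(data)
    index = {c: i for i, c in enumerate(conds)}
    keys = np.array([index[k] for k in zip(data["set_size"], data["p_probe"],
                                           data["condition_tag"])])
    errors = data["error_rad"].to_numpy(float)
    groups = tuple(errors[keys == i] for i in range(len(conds)))
    return _PreparedData(conds=tuple(conds), errors=groups, n=len(data))


def _loglik_prepared(prep: _PreparedData, spec: ModelSpec, theta: dict,
                     n_bins: int) -> float:
    from .circdist import vm_pdf_kappa
    jbars = _condition_jbars(spec, theta, list(prep.conds), n_bins)
    tau = spec.tau_of(theta)
    kappas = _fast.bin_kappas(jbars, tau, n_bins)   # one batched inversion
    total = 0.0
    for i, errs in enumerate(prep.errors):
        if errs.size == 0:
            continue
        dens = vm_pdf_kappa(errs[:, None], kappas[i][None, :]).mean(axis=1)
        total += float(np.log(np.maximum(dens, _DENSITY_FLOOR)).sum())
    return total


def dataset_loglik(data: pd.DataFrame, spec: ModelSpec, theta: dict,
                   n_bins: int = 50) -> float:
    """Summed log likelihood of a trial table under one parameter vector."""
    return _loglik_prepared(_prepare(data), spec, theta, n_bins)


def trial_loglik(trial: TrialRecord, spec: ModelSpec, theta: dict,
                 n_bins: int = 50) -> float:
    """Log likelihood of a single trial (see :func:`dataset_loglik`)."""
    conds = [(trial.set_size, trial.p_probe, trial.condition_tag)]
    jbar = float(_condition_jbars(spec, theta, conds, n_bins)[0])
    return float(_cond_logpdf(np.array([wrap_angle(trial.error)]), jbar,
                              spec.tau_of(theta), n_bins)[0])


# ---------------------------------------------------------------------------
# MLE

def _to_vector(theta: dict, names: tuple) -> np.ndarray:
    out = []
    for n in names:
        v = float(theta[n])
        out.append(v if n in _LINEAR_PARAMS else math.log(v))
    return np.array(out)


def _from_vector(x: np.ndarray, names: tuple) -> dict:
    theta = {}
    for v, n in zip(x, names):
        if n in _LINEAR_PARAMS:
            lo, hi = _LINEAR_PARAMS[n]
            theta[n] = float(np.clip(v, lo, hi))
        else:
            lo, hi = _BOUNDS[n]
            theta[n] = float(np.clip(math.exp(v), lo, hi))
    return theta


def fit_mle(data: pd.DataFrame, spec: ModelSpec, seed: int = 0,
            options: FitOptions = FitOptions(),
            extra_starts: list[dict] | None = None) -> FitResult:
    """Grid-seeded maximum-likelihood fit of one model to one subject.

    A coarse log-space grid over the free parameters seeds Nelder-Mead
    from the best ``options.n_starts`` grid points (plus any
    ``extra_starts``); the best local optimum is returned.  Deterministic
    for a given seed and data ordering.
    """
    if len(data) < 1:
        raise ValueError("need at least one trial")
    if spec.policy_kind == "nonparametric":
        return _fit_nonparametric(data, spec, seed, options)
    names = spec.free_params
    prep = _prepare(data)
    grids = [options.grid_for(n) for n in names]
    best: list[tuple[float, dict]] = []
    for combo in itertools.product(*grids):
        theta = {n: float(v) for n, v in zip(names, combo)}
        ll = _loglik_prepared(prep, spec, theta, options.n_bins)
        best.append((ll, theta))
    best.sort(key=lambda t: -t[0])
    starts = [th for _, th in best[:options.n_starts]]
    starts += list(extra_starts or [])

    def nll(x):
        return -_loglik_prepared(prep, spec, _from_vector(x, names), options.n_bins)

    results = []
    for theta0 in starts:
        res = minimize(nll, _to_vector(theta0, names), method="Nelder-Mead",
                       options={"maxfev": options.maxfev, "xatol": options.xatol,
                                "fatol": options.fatol})
        results.append((-res.fun, _from_vector(res.x, names)))
    if not results:
        raise RuntimeError("all optimization starts failed")
    ll, theta_hat = max(results, key=lambda t: t[0])
    return FitResult(model=spec, theta=theta_hat, loglik=float(ll),
                     n_params=spec.n_params(data), n_trials=len(data), seed=seed)


def _fit_nonparametric(data: pd.DataFrame, spec: ModelSpec, seed: int,
                       options: FitOptions) -> FitResult:
    """Free J_bar per condition; conditions decouple given tau, so the fit
    is an outer one-dimensional search over tau with exact inner fits."""
    conds = _conditions(data)
    keys = {c: i for i, c in enumerate(conds)}
    idx = np.array([keys[(n, p, t)] for n, p, t in
                    zip(data["set_size"], data["p_probe"], data["condition_tag"])])
    errors = data["error_rad"].to_numpy(float)
    groups = [errors[idx == i] for i in range(len(conds))]
    j_lo, j_hi = 1e-4, 1e4

    def fit_given_tau(tau: float):
        total, jhat = 0.0, []
        for errs in groups:
            def neg(logj, errs=errs):
                return -float(_cond_logpdf(errs, math.exp(logj), tau, options.n_bins).sum())
            res = minimize_scalar(neg, bounds=(math.log(j_lo), math.log(j_hi)),
                                  method="bounded", options={"xatol": 1e-4})
            ll_j = -res.fun
            ll_0 = float(_cond_logpdf(errs, 0.0, tau, options.n_bins).sum())
            if ll_0 >= ll_j:
                jhat.append(0.0)
                total += ll_0
            else:
                jhat.append(math.exp(res.x))
                total += ll_j
        return total, jhat

    if spec.fix_tau is not None:
        taus = [spec.fix_tau]
    else:
        taus = list(np.logspace(-2, 1.8, 8))
    evals = {t: fit_given_tau(t)[0] for t in taus}
    t_best = max(evals, key=evals.get)
    if spec.fix_tau is None:
        res = minimize_scalar(lambda lt: -fit_given_tau(math.exp(lt))[0],
                              bounds=(math.log(1e-3), math.log(1e2)), method="bounded",
                              options={"xatol": 5e-3})
        if -res.fun > evals[t_best]:
            t_best = math.exp(res.x)
    ll, jhat = fit_given_tau(t_best)
    theta = {f"J_{i}": j for i, j in enumerate(jhat)}
    theta["tau"] = float(t_best)
    theta["conditions"] = tuple(conds)
    return FitResult(model=spec, theta=theta, loglik=float(ll),
                     n_params=spec.n_params(data), n_trials=len(data), seed=seed)


# ---------------------------------------------------------------------------
# cross-validation and AIC comparison

def crossval_5fold(data: pd.DataFrame, spec: ModelSpec, seed: int = 0,
                   options: FitOptions = FitOptions(),
                   full_fit: FitResult | None = None) -> FitResult:
    """Interleaved five-fold cross-validation.

    Fold k (k = 1..5) holds out trials k, k+5, k+10, ... in presentation
    order (1-based), the model is refit on the remaining 80% (with the
    full-data estimate added as an extra optimization start), and the
    held-out log likelihoods are summed over folds.
    """
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 trials for 5-fold cross-validation")
    if full_fit is None:
        full_fit = fit_mle(data, spec, seed=seed, options=options)
    order = np.arange(n)  # 0-based presentation index
    fold_ll = []
    extra = None
    if spec.policy_kind != "nonparametric":
        extra = [full_fit.theta]
    for k in range(5):
        held = order % 5 == k
        train, test = data.iloc[~held], data.iloc[held]
        fit_k = fit_mle(train, spec, seed=seed, options=options, extra_starts=extra) \
            if spec.policy_kind != "nonparametric" else _fit_nonparametric(
                train, spec, seed, options)
        fold_ll.append(dataset_loglik(test, spec, fit_k.theta, options.n_bins)
                       if spec.policy_kind != "nonparametric"
                       else _nonparametric_heldout_ll(test, spec, fit_k, options))
    return replace(full_fit, cv_loglik=float(sum(fold_ll)),
                   cv_fold_logliks=tuple(float(v) for v in fold_ll))


def _nonparametric_heldout_ll(test: pd.DataFrame, spec: ModelSpec,
                              fit_k: FitResult, options: FitOptions) -> float:
    conds = list(fit_k.theta["conditions"])
    tau = spec.tau_of(fit_k.theta)
    total = 0.0
    for (n_i, p_i, tag), grp in test.groupby(["set_size", "p_probe", "condition_tag"]):
        key = (n_i, p_i, tag)
        if key not in conds:   # condition absent from the training fold
            jb = 0.0
        else:
            jb = float(fit_k.theta[f"J_{conds.index(key)}"])
        total += float(_cond_logpdf(grp["error_rad"].to_numpy(float), jb, tau,
                                    options.n_bins).sum())
    return total


def aic_compare(fits_by_model: dict, main: str) -> pd.DataFrame:
    """Pairwise model comparison against a reference model.

    ``fits_by_model`` maps model name -> list of :class:`FitResult`, one
    per subject, aligned across models on the same data.  Returns one row
    per alternative model with the subject-mean and s.e.m. of
    ``AIC_main - AIC_alt`` (negative favors the reference model) and of
    ``cv_main - cv_alt`` (positive favors the reference model) when
    cross-validated log likelihoods are present.
    """
    if main not in fits_by_model:
        raise ValueError(f"no fits for reference model {main!r}")
    ref = fits_by_model[main]
    rows = []
    for name, fits in fits_by_model.items():
        if name == main:
            continue
        if len(fits) != len(ref):
            raise ValueError(f"model {name!r} fitted to a different number of subjects")
        for a, b in zip(ref, fits):
            if a.n_trials != b.n_trials:
                raise ValueError("fits do not share the underlying data")
        d_aic = np.array([a.aic - b.aic for a, b in zip(ref, fits)])
        row = {"model": name,
               "delta_aic_mean": d_aic.mean(),
               "delta_aic_sem": d_aic.std(ddof=1) / np.sqrt(len(d_aic)) if len(d_aic) > 1 else 0.0}
        if all(f.cv_loglik is not None for f in ref + fits):
            d_cv = np.array([a.cv_loglik - b.cv_loglik for a, b in zip(ref, fits)])
            row["delta_cv_mean"] = d_cv.mean()
            row["delta_cv_sem"] = d_cv.std(ddof=1) / np.sqrt(len(d_cv)) if len(d_cv) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
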