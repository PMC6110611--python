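"""Synthetic delayed-estimation datasets.

Generates trial tables with the statistical structure the model assumes:
per display, an allocation policy assigns each item a mean precision
J_bar; on each trial one item is probed (with probability proportional to
its probing probability; items with p = 0 are never probed), a precision
J is drawn from a gamma with mean J_bar and scale tau, and the estimation
error is drawn from a Von Mises with the concentration mapped from J.

Nine built-in designs mirror the layouts of widely used delayed-estimation
experiments:

====  ===========  ==========================================================
name  set sizes    probing probabilities
====  ===========  ==========================================================
E1    1, 2, 4, 8   equal (1/N)
E2    1, 2, 3, 6   equal
E3    1, 2, 4, 6   equal
E4    1-8          equal (orientation)
E5    1-8          equal (color wheel)
E6    1-8          equal (color scroll)
E7    2, 4, 8      one cued item 3x more probable: (3/4, 1/4), (1/2, 1/6),
                   (3/10, 1/10)
E8    4            cue-validity conditions; probed-item p in
                   {0, 1/6, 2/9, 1/4, 1/3, 1/2, 1}
E9    6            probed-item p in {0, 1/12, 1/10, 2/15, 1/6, 1/3, 1/2, 1}
====  ===========  ==========================================================

For the cue-validity designs (E8/E9) conditions are generated directly
from the unique probed-item probabilities: the likelihood of a trial
depends only on the probed item's p, so the full block structure is not
reconstructed (p = 0 items are listed in the design but never probed,
hence generate no trials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .allocator import AllocationPolicy, J_GRID_HI, ModelParams, allocate_display, \
    optimal_resource
from .circdist import TAU_FLOOR, j_to_kappa, wrap_angle
from .costs import CostSpec
from .fitting import FitOptions, ModelSpec, fit_mle

__all__ = [
    "Condition",
    "DisplayDesign",
    "GeneratorSpec",
    "builtin_design",
    "generate",
    "policy_and_params",
    "parameter_recovery",
    "model_recovery",
    "recovery_harness",
    "RecoveryReport",
]


@dataclass(frozen=True)
class Condition:
    """One display condition: either a full probing-probability vector
    (one entry per item) or a directly specified probed-item probability."""

    set_size: int
    p_vector: tuple = ()
    probed_p: float | None = None

    def __post_init__(self):
        if self.p_vector and len(self.p_vector) != self.set_size:
            raise ValueError("p_vector length must equal set_size")
        if self.p_vector and not np.all([(0 <= p <= 1) for p in self.p_vector]):
            raise ValueError("probing probabilities must lie in [0, 1]")
        if not self.p_vector and self.probed_p is None:
            raise ValueError("need either p_vector or probed_p")

    @property
    def tag(self) -> str:
        if self.probed_p is not None:
            return f"N{self.set_size}_p{self.probed_p:.6g}"
        return f"N{self.set_size}"


@dataclass(frozen=True)
class DisplayDesign:
    """A named list of display conditions with a per-condition trial count."""

    name: str
    conditions: tuple
    trials_per_condition: int = 100
    all_p_values: tuple = ()   # unique probed-item probabilities incl. any p = 0


def _equal(name: str, set_sizes) -> DisplayDesign:
    conds = tuple(Condition(int(n), tuple([1.0 / n] * int(n))) for n in set_sizes)
    return DisplayDesign(name=name, conditions=conds,
                         all_p_values=tuple(sorted({1.0 / n for n in set_sizes})))


_E7_VECTORS = {2: (3 / 4, 1 / 4), 4: (1 / 2, 1 / 6, 1 / 6, 1 / 6),
               8: (3 / 10,) + (1 / 10,) * 7}
_E8_PS = (0.0, 1 / 6, 2 / 9, 1 / 4, 1 / 3, 1 / 2, 1.0)
_E9_PS = (0.0, 1 / 12, 1 / 10, 2 / 15, 1 / 6, 1 / 3, 1 / 2, 1.0)


def builtin_design(name: str, trials_per_condition: int = 100) -> DisplayDesign:
    """One of the built-in experiment layouts "E1" .. "E9"."""
    equal_sets = {"E1": (1, 2, 4, 8), "E2": (1, 2, 3, 6), "E3": (1, 2, 4, 6),
                  "E4": range(1, 9), "E5": range(1, 9), "E6": range(1, 9)}
    if name in equal_sets:
        d = _equal(name, equal_sets[name])
    elif name == "E7":
        d = DisplayDesign(name="E7",
                          conditions=tuple(Condition(n, _E7_VECTORS[n]) for n in (2, 4, 8)),
                          all_p_values=(1 / 10, 1 / 6, 1 / 4, 3 / 10, 1 / 2, 3 / 4))
    elif name in ("E8", "E9"):
        N = 4 if name == "E8" else 6
        ps = _E8_PS if name == "E8" else _E9_PS
        conds = tuple(Condition(N, probed_p=p) for p in ps if p > 0)
        d = DisplayDesign(name=name, conditions=conds, all_p_values=ps)
    else:
        raise ValueError(f"unknown design {name!r}")
    if trials_per_condition != d.trials_per_condition:
        d = DisplayDesign(name=d.name, conditions=d.conditions,
                          trials_per_condition=trials_per_condition,
                          all_p_values=d.all_p_values)
    return d


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to reproduce a synthetic dataset exactly."""

    design: DisplayDesign
    params: ModelParams
    policy: AllocationPolicy
    seed: int
    subject: str = "S1"


def policy_and_params(spec: ModelSpec, theta: dict) -> tuple[AllocationPolicy, ModelParams]:
    """Translate a fitted model's parameter vector into generator objects."""
    tau = spec.tau_of(theta)
    cost = spec.cost_spec(theta) if spec.policy_kind in ("rational", "bays_fixed_total") \
        else CostSpec("power", beta=2.0)
    lam = float(theta.get("lambda", 0.0))
    params = ModelParams(lambda_=lam, tau=tau, cost=cost)
    kind = spec.policy_kind
    if kind == "rational":
        policy = AllocationPolicy("rational")
    elif kind == "power_law":
        policy = AllocationPolicy("power_law", J1=float(theta["J1"]), a=float(theta["a"]))
    elif kind in ("fixed_equal", "emrich_proportional", "bays_fixed_total"):
        policy = AllocationPolicy(kind, J_total=float(theta["J_total"]))
    else:
        raise ValueError(f"cannot generate from policy {kind!r}")
    return policy, params


def _probed_jbar_direct(cond: Condition, policy: AllocationPolicy,
                        params: ModelParams) -> float:
    """Probed item's mean precision for a direct-probed-p condition."""
    p, N = cond.probed_p, cond.set_size
    if policy.kind == "rational":
        return optimal_resource(p, params)
    if policy.kind == "fixed_equal":
        return policy.J_total / N
    if policy.kind == "emrich_proportional":
        return p * policy.J_total
    if policy.kind == "power_law":
        return policy.J1 * N ** (-policy.a)
    if policy.kind == "nonparametric":
        return policy.lookup(p)
    raise ValueError(f"policy {policy.kind!r} needs the full display vector")


def generate(spec: GeneratorSpec, trials_per_condition: int | None = None) -> pd.DataFrame:
    """Draw a synthetic trial table; identical specs give identical tables."""
    rng = np.random.default_rng(spec.seed)
    n_per = trials_per_condition or spec.design.trials_per_condition
    rows = []
    for cond in spec.design.conditions:
        if cond.probed_p is not None:
            if cond.probed_p == 0.0:
                continue   # never probed: contributes no trials
            p_probe = np.full(n_per, cond.probed_p)
            jbar = np.full(n_per, _probed_jbar_direct(cond, spec.policy, spec.params))
        else:
            pv = np.asarray(cond.p_vector, dtype=float)
            jb_items = allocate_display(pv, spec.policy, spec.params)
            probs = pv / pv.sum()
            idx = rng.choice(len(pv), size=n_per, p=probs)
            p_probe = pv[idx]
            jbar = jb_items[idx]
        jbar = np.minimum(jbar, J_GRID_HI)
        if spec.params.tau < TAU_FLOOR:
            J = jbar.copy()
        else:
            shape = jbar / spec.params.tau
            J = np.where(shape > 0,
                         rng.gamma(np.maximum(shape, 1e-300), spec.params.tau), 0.0)
        kappa = j_to_kappa(np.minimum(J, 1e7))
        eps = wrap_angle(rng.vonmises(0.0, np.maximum(kappa, 1e-12)))
        for k in range(n_per):
            rows.append((spec.subject, cond.set_size, p_probe[k], eps[k], cond.tag))
    return pd.DataFrame(rows, columns=["subject", "set_size", "p_probe",
                                       "error_rad", "condition_tag"])


# ---------------------------------------------------------------------------
# recovery harness

@dataclass(frozen=True)
class RecoveryReport:
    """True-vs-recovered parameter table and model-confusion matrix."""

    params_table: pd.DataFrame | None = None
    confusion: pd.DataFrame | None = None
    details: pd.DataFrame | None = None


def parameter_recovery(design: DisplayDesign, model: ModelSpec, true_theta: dict,
                       n_seeds: int, seed0: int = 0,
                       trials_per_condition: int | None = None,
                       options: FitOptions = FitOptions()) -> pd.DataFrame:
    """Generate-from / fit-with the same model across seeds.

    Returns one row per (seed, parameter) with the true value, the
    recovered value, and the relative error.
    """
    policy, params = policy_and_params(model, true_theta)
    rows = []
    for s in range(n_seeds):
        gspec = GeneratorSpec(design=design, params=params, policy=policy,
                              seed=seed0 + s, subject=f"S{s + 1}")
        data = generate(gspec, trials_per_condition)
        fit = fit_mle(data, model, seed=seed0 + s, options=options)
        for name in model.free_params:
            true_v = float(true_theta[name])
            hat = float(fit.theta[name])
            rel = abs(hat - true_v) / abs(true_v) if true_v != 0 else np.nan
            rows.append({"seed": seed0 + s, "param": name, "true": true_v,
                         "recovered": hat, "rel_error": rel})
    return pd.DataFrame(rows)


def model_recovery(design: DisplayDesign, generators: dict, fit_models: dict,
                   n_subjects: int, seed0: int = 0,
                   trials_per_condition: int | None = None,
                   options: FitOptions = FitOptions()) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AIC-based confusion matrix across simulated subjects.

    ``generators`` maps name -> (ModelSpec, theta); ``fit_models`` maps
    name -> ModelSpec.  Each simulated subject generated under one model
    is fit by every candidate; the winner is the lowest AIC.  Returns
    (confusion matrix of win fractions, per-subject detail table).
    """
    names = list(fit_models)
    counts = {g: {m: 0 for m in names} for g in generators}
    detail = []
    for g_i, (g_name, (g_spec, g_theta)) in enumerate(generators.items()):
        policy, params = policy_and_params(g_spec, g_theta)
        for s in range(n_subjects):
            seed = seed0 + 1000 * g_i + s
            data = generate(GeneratorSpec(design=design, params=params, policy=policy,
                                          seed=seed, subject=f"{g_name}-S{s + 1}"),
                            trials_per_condition)
            aics = {}
            for m_name, m_spec in fit_models.items():
                fit = fit_mle(data, m_spec, seed=seed, options=options)
                aics[m_name] = fit.aic
            winner = min(aics, key=aics.get)
            counts[g_name][winner] += 1
            detail.append({"generator": g_name, "seed": seed, "winner": winner, **aics})
    conf = pd.DataFrame(counts).T[names] / n_subjects
    conf.index.name = "generator"
    return conf, pd.DataFrame(detail)


def recovery_harness(design: DisplayDesign, model: ModelSpec, true_theta: dict,
                     fit_models: dict | None = None, n_seeds: int = 10,
                     seed0: int = 0, trials_per_condition: int | None = None,
                     options: FitOptions = FitOptions()) -> RecoveryReport:
    """Parameter recovery for one generator, plus (optionally) a model-
    recovery confusion matrix; deterministic given the seed list."""
    ptab = parameter_recovery(design, model, true_theta, n_seeds, seed0,
                              trials_per_condition, options)
    conf = details = None
    if fit_models:
        generators = {model.name: (model, true_theta)}
        conf, details = model_recovery(design, generators, fit_models, n_seeds,
                                       seed0, trials_per_condition, options)
    return RecoveryReport(params_table=ptab, confusion=conf, details=details)
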