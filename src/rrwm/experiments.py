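"""Command-line entry points and scripted analyses.

Thin wrappers over the library: every command reads its settings from
flags (or a YAML manifest), writes flat tab-separated tables, and drops a
``manifest.yaml`` into the output directory from which the run can be
reproduced exactly.  Conventions used throughout: errors are radians in
[-pi, pi); cross-validation fold indices are 1-based in presentation
order; probing probabilities are written as decimals.

Commands::

    rrwm simulate          synthetic trial tables for a built-in design
    rrwm fit               maximum-likelihood fits (+ optional 5-fold CV)
                           and a model-comparison table
    rrwm theory-curves     J_opt versus p and N, total-resource curves,
                           binary-feedback threshold sweeps
    rrwm change-detection  reward / set-size regime sweeps of the global task
    rrwm recover           parameter-recovery sweep for one model
"""

from __future__ import annotations

import pathlib

import click
import numpy as np
import pandas as pd
import yaml

from .allocator import ModelParams, total_resource_curve, optimal_resource
from .change_detection import ChangeDetectionConfig, regime_sweep, set_size_sweep
from .costs import CostSpec, expected_behavioral_cost
from .fitting import (
    FAST_OPTIONS,
    FitOptions,
    aic_compare,
    crossval_5fold,
    fit_mle,
    model_spec,
    read_trials,
    write_trials,
)
from .synthetic_data import (
    GeneratorSpec,
    builtin_design,
    generate,
    parameter_recovery,
    policy_and_params,
)

_THETA_KEYS = ("beta", "lambda", "tau", "J_total", "J1", "a")


def _write_manifest(out_dir: pathlib.Path, command: str, options: dict) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"command": command, "options": options}
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_manifest(path) -> dict:
    return yaml.safe_load(pathlib.Path(path).read_text())


def _theta_from_options(opts: dict) -> dict:
    return {k: float(opts[k]) for k in _THETA_KEYS if opts.get(k) is not None}


@click.group()
def cli():
    """Resource-rational working-memory modelling toolbox."""


def _simulate_run(opts: dict) -> pd.DataFrame:
    design = builtin_design(opts["design"], trials_per_condition=int(opts["trials_per_condition"]))
    spec = model_spec(opts["model"])
    theta = _theta_from_options(opts)
    policy, params = policy_and_params(spec, theta)
    gspec = GeneratorSpec(design=design, params=params, policy=policy,
                          seed=int(opts["seed"]), subject=str(opts["subject"]))
    return generate(gspec)


@cli.command()
@click.option("--design", default="E5", show_default=True)
@click.option("--model", default="rational", show_default=True)
@click.option("--beta", type=float, default=None)
@click.option("--lambda", "lambda_", type=float, default=None)
@click.option("--tau", type=float, default=None)
@click.option("--j-total", "J_total", type=float, default=None)
@click.option("--j1", "J1", type=float, default=None)
@click.option("-a", "--power-exponent", "a", type=float, default=None)
@click.option("--trials-per-condition", type=int, default=100, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--subject", default="S1", show_default=True)
@click.option("--out-dir", type=click.Path(path_type=pathlib.Path), default="out_simulate")
@click.option("--manifest", type=click.Path(exists=True), default=None,
              help="Reproduce a previous run from its manifest.yaml.")
def simulate(manifest, out_dir, **opts):
    """Generate a synthetic trial table for a built-in design."""
    if manifest is not None:
        opts = load_manifest(manifest)["options"]
    opts.setdefault("lambda", opts.pop("lambda_", None))
    df = _simulate_run(opts)
    out_dir = pathlib.Path(out_dir)
    _write_manifest(out_dir, "simulate", opts)
    path = out_dir / f"{opts['design']}_{opts['subject']}.tsv"
    write_trials(df, path)
    click.echo(f"wrote {len(df)} trials to {path}")


@cli.command()
@click.option("--data", type=click.Path(exists=True), required=True)
@click.option("--models", default="rational,power_law,fixed_equal", show_default=True,
              help="Comma-separated model variant names; the first is the reference.")
@click.option("--cv", is_flag=True, help="Add interleaved 5-fold cross-validation columns.")
@click.option("--fast", is_flag=True, help="Lighter optimizer settings.")
@click.option("--fix-tau", type=float, default=None,
              help="Fit equal-precision variants with tau fixed to this value.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=pathlib.Path), default="out_fit")
def fit(data, models, cv, fast, fix_tau, seed, out_dir):
    """Fit one or more model variants per subject; write fit and comparison tables."""
    df = read_trials(data)
    names = [m.strip() for m in models.split(",") if m.strip()]
    if not names:
        raise click.UsageError("no models given")
    options = FAST_OPTIONS if fast else FitOptions()
    rows, fits_by_model = [], {m: [] for m in names}
    for subject, sub in df.groupby("subject", sort=True):
        sub = sub.reset_index(drop=True)
        for name in names:
            spec = model_spec(name, fix_tau=fix_tau)
            res = fit_mle(sub, spec, seed=seed, options=options)
            if cv:
                res = crossval_5fold(sub, spec, seed=seed, options=options, full_fit=res)
            theta = {k: v for k, v in res.theta.items() if k != "conditions"}
            rows.append({"subject": subject, "model": name, "loglik": res.loglik,
                         "n_params": res.n_params, "aic": res.aic,
                         "cv_loglik": res.cv_loglik,
                         **{f"theta_{k}": v for k, v in theta.items()}})
            fits_by_model[name].append(res)
    out_dir = pathlib.Path(out_dir)
    _write_manifest(out_dir, "fit", {"data": str(data), "models": names, "cv": cv,
                                     "fast": fast, "fix_tau": fix_tau, "seed": seed})
    fit_table = pd.DataFrame(rows)
    fit_table.to_csv(out_dir / "fits.tsv", sep="\t", index=False)
    if len(names) > 1:
        comp = aic_compare(fits_by_model, main=names[0])
        comp.to_csv(out_dir / "comparison.tsv", sep="\t")
        click.echo(comp.to_string())
    if "nonparametric" in names:
        _write_nonparametric_totals(fits_by_model["nonparametric"], out_dir)
    click.echo(f"wrote fits for {fit_table['subject'].nunique()} subject(s) to {out_dir}")


def _write_nonparametric_totals(fits, out_dir: pathlib.Path) -> None:
    """Empirical total-resource curve J_total = J_hat / p per condition."""
    rows = []
    for s_idx, res in enumerate(fits):
        for i, (n, p, tag) in enumerate(res.theta["conditions"]):
            j = res.theta[f"J_{i}"]
            rows.append({"subject": s_idx, "set_size": n, "p_probe": p,
                         "condition_tag": tag, "J_hat": j,
                         "J_total_hat": j / p if p > 0 else np.nan})
    pd.DataFrame(rows).to_csv(out_dir / "nonparametric_totals.tsv", sep="\t", index=False)


@cli.command("theory-curves")
@click.option("--lambda", "lambda_", type=float, default=0.01, show_default=True)
@click.option("--beta", type=float, default=2.0, show_default=True)
@click.option("--tau", type=float, default=0.0, show_default=True,
              help="0 selects the equal-precision (point-mass) branch.")
@click.option("--set-sizes", default="1,2,3,4,5,6,7,8", show_default=True)
@click.option("--p-grid", default="", help="Optional comma-separated probing probabilities.")
@click.option("--feedback-sweep", is_flag=True,
              help="Binary-feedback threshold sweep (expected |error| vs threshold).")
@click.option("--cost-decomposition", is_flag=True,
              help="Per-item behavioral/neural/total expected cost versus J_bar.")
@click.option("--out-dir", type=click.Path(path_type=pathlib.Path), default="out_theory")
def theory_curves(lambda_, beta, tau, set_sizes, p_grid, feedback_sweep,
                  cost_decomposition, out_dir):
    """Optimal-allocation curves: J_opt and total resource vs set size / p."""
    if not set_sizes and not p_grid:
        raise click.UsageError("empty parameter grid")
    params = ModelParams(lambda_=lambda_, tau=tau, cost=CostSpec("power", beta=beta))
    out_dir = pathlib.Path(out_dir)
    _write_manifest(out_dir, "theory-curves",
                    {"lambda": lambda_, "beta": beta, "tau": tau, "set_sizes": set_sizes,
                     "p_grid": p_grid, "feedback_sweep": feedback_sweep,
                     "cost_decomposition": cost_decomposition})
    if cost_decomposition:
        _cost_decomposition(params, out_dir)
    if set_sizes:
        ns = [int(s) for s in set_sizes.split(",")]
        curve = total_resource_curve(params, set_sizes=ns)
        pd.DataFrame({"set_size": curve.index, "J_opt_per_item": curve.per_item,
                      "J_total": curve.total}).to_csv(out_dir / "by_set_size.tsv",
                                                      sep="\t", index=False)
        click.echo(f"N_peak = {curve.peak:g}")
    if p_grid:
        ps = [float(s) for s in p_grid.split(",")]
        curve = total_resource_curve(params, p_grid=ps)
        pd.DataFrame({"p": curve.index, "J_opt_per_item": curve.per_item,
                      "J_total": curve.total}).to_csv(out_dir / "by_p.tsv",
                                                      sep="\t", index=False)
        click.echo(f"p_peak = {curve.peak:g}")
    if feedback_sweep:
        _feedback_sweep(params, out_dir)
    click.echo(f"wrote theory curves to {out_dir}")


def _cost_decomposition(params: ModelParams, out_dir: pathlib.Path,
                        ps=(1.0, 0.5, 0.25, 0.125)) -> None:
    """Expected cost per item vs invested resource, split into the
    decreasing behavioral term p*cbar(J) and the rising neural term
    lambda*J, for several probing probabilities."""
    J = np.concatenate(([0.0], np.logspace(-2, 2.5, 60)))
    rows = []
    for j in J:
        cb = expected_behavioral_cost(j, params.tau, params.cost)
        for p in ps:
            rows.append({"p": p, "J_bar": j, "behavioral": p * cb,
                         "neural": params.lambda_ * j,
                         "total": p * cb + params.lambda_ * j})
    pd.DataFrame(rows).to_csv(out_dir / "cost_decomposition.tsv", sep="\t", index=False)


def _feedback_sweep(params: ModelParams, out_dir: pathlib.Path,
                    p_probe: float = 0.2, n_theta: int = 25) -> None:
    """Predicted expected |error| as a function of the feedback threshold."""
    thetas = np.linspace(0.02, np.pi - 0.02, n_theta)
    rows = []
    abs_cost = CostSpec("abs", beta=None)
    for th in thetas:
        pset = ModelParams(lambda_=params.lambda_, tau=params.tau,
                           cost=CostSpec("binary_threshold", beta=None, params=(float(th),)))
        j = optimal_resource(p_probe, pset)
        rows.append({"threshold": float(th), "J_opt": j,
                     "expected_abs_error": expected_behavioral_cost(j, params.tau, abs_cost)})
    pd.DataFrame(rows).to_csv(out_dir / "feedback_sweep.tsv", sep="\t", index=False)


@cli.command("change-detection")
@click.option("--n", "N", type=int, default=2, show_default=True)
@click.option("--lambda", "lambda_", type=float, default=0.01, show_default=True)
@click.option("--rewards", default="0.05,0.20,0.35", show_default=True)
@click.option("--set-sizes", default="", help="Sweep set size at --reward instead.")
@click.option("--reward", type=float, default=1.5, show_default=True)
@click.option("--mc-samples", type=int, default=200_000, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=pathlib.Path), default="out_cd")
def change_detection_cmd(N, lambda_, rewards, set_sizes, reward, mc_samples, seed, out_dir):
    """Regime sweeps of the whole-display change-detection observer."""
    out_dir = pathlib.Path(out_dir)
    _write_manifest(out_dir, "change-detection",
                    {"N": N, "lambda": lambda_, "rewards": rewards, "set_sizes": set_sizes,
                     "reward": reward, "mc_samples": mc_samples, "seed": seed})
    cfg = ChangeDetectionConfig(N=N, reward=reward, lambda_=lambda_,
                                mc_samples=mc_samples, seed=seed)
    if set_sizes:
        tab = set_size_sweep(cfg, [int(s) for s in set_sizes.split(",")])
        tab.to_csv(out_dir / "set_size_sweep.tsv", sep="\t", index=False)
    else:
        tab = regime_sweep(cfg, [float(s) for s in rewards.split(",")])
        tab.to_csv(out_dir / "reward_sweep.tsv", sep="\t", index=False)
    click.echo(tab.to_string(index=False))


@cli.command()
@click.option("--design", default="E6", show_default=True)
@click.option("--model", default="rational", show_default=True)
@click.option("--beta", type=float, default=0.61, show_default=True)
@click.option("--lambda", "lambda_", type=float, default=0.0088, show_default=True)
@click.option("--tau", type=float, default=7.4, show_default=True)
@click.option("--n-seeds", type=int, default=5, show_default=True)
@click.option("--trials-per-condition", type=int, default=200, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out-dir", type=click.Path(path_type=pathlib.Path), default="out_recover")
def recover(design, model, beta, lambda_, tau, n_seeds, trials_per_condition, seed, out_dir):
    """Parameter-recovery sweep: generate from the model, refit, report errors."""
    spec = model_spec(model)
    theta = {"beta": beta, "lambda": lambda_, "tau": tau}
    theta = {k: v for k, v in theta.items() if k in spec.free_params}
    tab = parameter_recovery(builtin_design(design), spec, theta, n_seeds=n_seeds,
                             seed0=seed, trials_per_condition=trials_per_condition,
                             options=FAST_OPTIONS)
    out_dir = pathlib.Path(out_dir)
    _write_manifest(out_dir, "recover",
                    {"design": design, "model": model, "beta": beta, "lambda": lambda_,
                     "tau": tau, "n_seeds": n_seeds,
                     "trials_per_condition": trials_per_condition, "seed": seed})
    tab.to_csv(out_dir / "recovery.tsv", sep="\t", index=False)
    med = tab.groupby("param")["rel_error"].median()
    click.echo("median relative error by parameter:")
    click.echo(med.to_string())


if __name__ == "__main__":
    cli()
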