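"""Replication harness: simulate, fit all models, tabulate recovery.

``run_study`` mirrors the shape of the simulation-study result tables: one
row per (replicate, model, parameter) carrying the posterior mean, the
equal-tailed 95% interval and a flag for whether the interval covers the
simulating ("true") value — the starred-cell convention.  Coverage is always
judged on the unrounded interval.

``sweep`` repeats a study while varying one generative parameter.  Within a
(value, replicate) cell all models are fitted to the *same* simulated
dataset, so cross-model comparisons are paired.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import MCMCConfig, Model, PriorSet, SimulationConfig
from .inference import check_convergence, fit, summarize
from .simulator import simulate_dataset

__all__ = ["run_study", "sweep", "plot_sweep", "RESULT_COLUMNS"]

RESULT_COLUMNS = [
    "replicate",
    "model",
    "parameter",
    "truth",
    "post_mean",
    "post_median",
    "q2.5",
    "q97.5",
    "rhat",
    "ess",
    "covered",
    "converged",
    "error",
]

_ALL_MODELS = (Model.MRP, Model.MRSU, Model.MB, Model.MS, Model.M0)


def _truth(cfg: SimulationConfig, parameter: str) -> float:
    return float(getattr(cfg, parameter))


def run_study(
    cfg: SimulationConfig,
    models: Sequence[Model | str] = _ALL_MODELS,
    priors: Optional[PriorSet] = None,
    mcmc: Optional[MCMCConfig] = None,
    replicates: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate ``replicates`` datasets from ``cfg`` and fit each model.

    All models within a replicate see the same dataset.  A failed fit is
    recorded in the ``error`` column of its rows rather than aborting the
    study.  Fully deterministic given ``seed``.
    """
    priors = priors or PriorSet()
    mcmc = mcmc or MCMCConfig()
    models = [Model(m) for m in models]
    master = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for r, rep_ss in enumerate(master.spawn(replicates)):
        sim_ss, fit_ss = rep_ss.spawn(2)
        rng = np.random.default_rng(sim_ss)
        dataset = simulate_dataset(cfg, rng=rng)
        for model, model_ss in zip(models, fit_ss.spawn(len(models))):
            chain_seed = int(model_ss.generate_state(1, np.uint32)[0])
            try:
                draws = fit(model, dataset, priors, replace(mcmc, seed=chain_seed))
                summary = summarize(draws)
                converged = check_convergence(summary).passed
                for name in summary.parameters:
                    row = summary[name]
                    truth = _truth(cfg, name)
                    rows.append(
                        {
                            "replicate": r,
                            "model": model.value,
                            "parameter": name,
                            "truth": truth,
                            "post_mean": row["mean"],
                            "post_median": row["median"],
                            "q2.5": row["q2.5"],
                            "q97.5": row["q97.5"],
                            "rhat": row["rhat"],
                            "ess": row["ess"],
                            "covered": bool(row["q2.5"] <= truth <= row["q97.5"]),
                            "converged": converged,
                            "error": None,
                        }
                    )
            except Exception as exc:  # record, don't abort the grid
                rows.append(
                    {
                        "replicate": r,
                        "model": model.value,
                        "parameter": None,
                        "truth": None,
                        "post_mean": None,
                        "post_median": None,
                        "q2.5": None,
                        "q97.5": None,
                        "rhat": None,
                        "ess": None,
                        "covered": None,
                        "converged": None,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def sweep(
    parameter_name: str,
    values: Iterable,
    base_cfg: SimulationConfig,
    models: Sequence[Model | str] = (Model.MRP,),
    priors: Optional[PriorSet] = None,
    mcmc: Optional[MCMCConfig] = None,
    replicates: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run a study at each value of one generative parameter.

    Returns the concatenated long-format table with ``sweep_parameter`` and
    ``sweep_value`` columns prepended.  Replicate seeds are spawned per
    value, so different values use independent datasets while models within
    a (value, replicate) cell remain paired.
    """
    if parameter_name not in SimulationConfig.field_names():
        raise ValueError(
            f"unknown simulation parameter {parameter_name!r}; "
            f"expected one of {SimulationConfig.field_names()}"
        )
    values = list(values)
    frames = []
    master = np.random.SeedSequence(seed)
    for value, value_ss in zip(values, master.spawn(max(len(values), 1))):
        cfg = replace(base_cfg, **{parameter_name: value})
        df = run_study(
            cfg,
            models=models,
            priors=priors,
            mcmc=mcmc,
            replicates=replicates,
            seed=int(value_ss.generate_state(1, np.uint32)[0]),
        )
        df.insert(0, "sweep_value", value)
        df.insert(0, "sweep_parameter", parameter_name)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["sweep_parameter", "sweep_value"] + RESULT_COLUMNS
        )
    return pd.concat(frames, ignore_index=True)


def plot_sweep(results: pd.DataFrame, parameter: str = "U", ax=None):
    """Mean ± 95% interval of one estimated parameter across sweep values.

    One errorbar per (sweep value, model, replicate); a horizontal line marks
    the simulating value.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    sub = results[(results["parameter"] == parameter) & results["error"].isna()]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for model, grp in sub.groupby("model"):
        x = grp["sweep_value"].to_numpy(float)
        x = x + 0.005 * (hash(model) % 7 - 3) * (x.max() - x.min() + 1)  # dodge
        mean = grp["post_mean"].to_numpy(float)
        lo = mean - grp["q2.5"].to_numpy(float)
        hi = grp["q97.5"].to_numpy(float) - mean
        ax.errorbar(x, mean, yerr=[lo, hi], fmt="o", capsize=3, label=model)
    if len(sub):
        ax.axhline(sub["truth"].iloc[0], color="k", lw=1, ls="--")
    ax.set_xlabel(str(sub["sweep_parameter"].iloc[0]) if len(sub) else "value")
    ax.set_ylabel(parameter)
    ax.legend()
    return ax
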