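"""Simulation-study orchestration: grids, performance measures, reports.

A grid crosses data-generating settings (truth model, optional HR(t)
scenario, sample size, censoring time) with analysis models (Bayesian
M-spline cells varying df, smoothness prior, coefficient-prior model and
treatment-effect structure; frequentist Royston-Parmar cells) and an
inference method.  Each (cell, rep) is fully determined by the master seed,
so runs are reproducible, resumable and independent of the worker count.

Performance measures follow standard simulation-study definitions:
bias = mean(est) - truth with MCSE = empSE / sqrt(n); relative bias =
100 * bias / truth (suppressed when |truth| < 0.05 years); empirical SE =
SD(est) with MCSE = empSE / sqrt(2(n-1)); mean model SD (posterior SD or
model SE) with its MCSE; coverage of nominal 95% intervals with MCSE =
sqrt(c(1-c)/n).  MCMC replicates with split-Rhat > 1.05 are excluded from
the measures and counted separately as non-converged.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import dgm as dgm_mod
from . import inference, posterior_outputs, rp_frequentist
from .hazard_model import ModelSpec, PriorSpec
from .spline_basis import place_knots

__all__ = [
    "ModelCell",
    "GridConfig",
    "default_single_arm_cells",
    "run_single_rep",
    "performance",
    "run_grid",
    "report",
]


@dataclass(frozen=True)
class ModelCell:
    """One analysis model in the grid."""

    kind: str = "bayes"              # "bayes" | "rp"
    df: int = 10                     # M-spline df (bayes) / baseline df (rp)
    sigma_prior: tuple[float, float] = (2.0, 1.0)
    coef_model: str = "random_walk"
    treatment: str = "none"          # "none" | "ph" | "nonph"
    tau_prior: tuple[float, float] = (2.0, 1.0)
    method: str = "laplace"          # bayes: "mcmc"|"laplace"; rp: "delta"|"bootstrap"
    tve_df: int = 0
    stratified: bool = False
    chains: int = 4
    iterations: int = 2000

    @property
    def name(self) -> str:
        if self.kind == "rp":
            tag = f"rp_df{self.df}_tve{self.tve_df}"
            if self.stratified:
                tag += "_strat"
            return f"{tag}_{self.method}"
        return (
            f"bayes_df{self.df}_sigma{self.sigma_prior[0]:g}-{self.sigma_prior[1]:g}"
            f"_{self.coef_model}_{self.treatment}_{self.method}"
        )


def default_single_arm_cells(method: str = "mcmc") -> list[ModelCell]:
    """The default single-arm Bayesian grid: df x sigma prior x coefficient
    model = 3 x 3 x 2 = 18 cells."""
    cells = []
    for df in (3, 6, 10):
        for rate in (1.0, 5.0, 20.0):
            for coef_model in ("random_walk", "exchangeable"):
                cells.append(
                    ModelCell(kind="bayes", df=df, sigma_prior=(2.0, rate),
                              coef_model=coef_model, treatment="none",
                              method=method)
                )
    return cells


@dataclass
class GridConfig:
    """Full description of one simulation grid."""

    dgm: str = "os_like"
    scenario: str | None = None
    n_per_arm: int = 200
    censor_time: float = 5.0
    reps: int = 1000
    horizon: float = 5.0
    seed: int = 0
    workers: int = 1
    cells: Sequence[ModelCell] = field(default_factory=lambda: default_single_arm_cells())
    dgm_config: str | None = None    # YAML with external DGM/scenario parameters

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cells_raw = raw.pop("cells", "default_single_arm")
        if cells_raw == "default_single_arm":
            cells = default_single_arm_cells(raw.pop("inference", "mcmc"))
        else:
            cells = [
                ModelCell(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in c.items()})
                for c in cells_raw
            ]
        return cls(cells=cells, **raw)

    def resolve_truth_models(self):
        registry = dgm_mod.fixture_dgms()
        if self.dgm_config:
            ext = dgm_mod.load_config(self.dgm_config)
            registry.update(ext["dgms"])
            registry.update(ext["scenarios"])
        truth = registry[self.dgm]
        scenario = registry[self.scenario] if self.scenario else None
        return truth, scenario


def _rep_rngs(config: GridConfig, cell_index: int, rep: int):
    ss = np.random.SeedSequence(
        entropy=int(config.seed), spawn_key=(cell_index, rep)
    )
    data_seed, fit_seed = ss.spawn(2)
    return np.random.default_rng(data_seed), fit_seed.generate_state(1)[0] % (2**31)


def run_single_rep(config: GridConfig, cell: ModelCell, cell_index: int, rep: int) -> dict:
    """Simulate one dataset, fit one model, compute the estimand.

    Returns a record dict; fit failures yield ``status != 'ok'`` rather
    than raising.
    """
    record: dict = {"cell": cell.name, "cell_index": cell_index, "rep": rep,
                    "status": "ok"}
    truth_model, scenario = config.resolve_truth_models()
    data_rng, fit_seed = _rep_rngs(config, cell_index, rep)
    trial = dgm_mod.simulate_trial(
        truth_model, scenario, config.n_per_arm, config.censor_time,
        seed=data_rng, rep=rep,
    )
    data = trial.data
    record["n_events"] = int(data["event"].sum())
    two_arm = scenario is not None
    try:
        if cell.kind == "bayes":
            uncensored = data.loc[data["event"] == 1, "time"].to_numpy()
            basis = place_knots(uncensored, df=cell.df, lower=0.0,
                                upper=float(data["time"].max()))
            priors = PriorSpec(sigma_prior=cell.sigma_prior,
                               coef_model=cell.coef_model,
                               tau_prior=cell.tau_prior)
            ph = ("arm",) if (two_arm and cell.treatment in ("ph", "nonph")) else ()
            nonph = ("arm",) if (two_arm and cell.treatment == "nonph") else ()
            spec = ModelSpec(basis=basis, ph_covariates=ph,
                             nonph_covariates=nonph, priors=priors)
            if cell.method == "mcmc":
                samples = inference.fit_mcmc(
                    spec, data, chains=cell.chains, iterations=cell.iterations,
                    seed=fit_seed)
            else:
                samples = inference.fit_laplace(spec, data, seed=fit_seed)
            if two_arm:
                est = posterior_outputs.rmstd(
                    samples, spec, {"arm": 1.0}, {"arm": 0.0}, config.horizon)
            else:
                est = posterior_outputs.rmst(samples, spec, None, config.horizon)
            diag = samples.diagnostics
            record.update(
                point=est.median, sd=est.sd, lo=est.ci_low, hi=est.ci_high,
                max_rhat=diag.get("max_rhat"),
                min_bulk_ess=diag.get("min_bulk_ess"),
                divergences=int(np.sum(diag.get("divergences", [0]))),
                converged=(diag.get("converged") is not False),
            )
        else:
            fit = rp_frequentist.fit_rp_mle(
                data, baseline_df=cell.df, tve_df=cell.tve_df,
                stratified=cell.stratified,
                covariate="arm" if two_arm else None, seed=fit_seed)
            if two_arm:
                res = rp_frequentist.rmstd_inference(
                    fit, config.horizon, method=cell.method, seed=fit_seed)
            else:
                res = rp_frequentist.rmst_inference(
                    fit, 0.0, config.horizon, method=cell.method, seed=fit_seed)
            record.update(
                point=res["estimate"], sd=res["se"], lo=res["ci"][0],
                hi=res["ci"][1], converged=bool(fit.converged),
                negative_hazard_flag=bool(fit.negative_hazard_flag),
            )
    except Exception as exc:  # recorded, not fatal: the grid keeps going
        record["status"] = "failed"
        record["error"] = f"{type(exc).__name__}: {exc}"
        record["trace"] = traceback.format_exc(limit=3)
    return record


def performance(records: Sequence[dict], truth: float) -> dict:
    """Aggregate one grid cell's records into performance measures."""
    ok = [r for r in records if r.get("status") == "ok"]
    usable = [r for r in ok if r.get("converged", True)]
    n = len(usable)
    row: dict = {
        "n_records": len(records),
        "n_failed": len(records) - len(ok),
        "n_nonconverged": len(ok) - n,
        "n_used": n,
        "truth": truth,
    }
    if n < 2:
        row["note"] = "fewer than 2 usable replicates"
        return row
    est = np.array([r["point"] for r in usable])
    sds = np.array([r["sd"] for r in usable])
    cover = np.array([(r["lo"] <= truth <= r["hi"]) for r in usable], dtype=float)
    emp_se = float(est.std(ddof=1))
    bias = float(est.mean() - truth)
    row.update(
        mean_est=float(est.mean()),
        bias=bias,
        bias_mcse=emp_se / np.sqrt(n),
        emp_se=emp_se,
        emp_se_mcse=emp_se / np.sqrt(2.0 * (n - 1)),
        mean_model_sd=float(sds.mean()),
        mean_model_sd_mcse=float(sds.std(ddof=1) / np.sqrt(n)),
        coverage=float(cover.mean()),
        coverage_mcse=float(np.sqrt(cover.mean() * (1 - cover.mean()) / n)),
    )
    if abs(truth) >= 0.05:
        row["rel_bias_pct"] = 100.0 * bias / truth
        row["rel_bias_pct_mcse"] = 100.0 * row["bias_mcse"] / abs(truth)
    else:
        row["rel_bias_pct"] = float("nan")
        row["note"] = "relative bias suppressed: |truth| < 0.05 years"
    return row


def _record_path(out_dir: Path, cell: ModelCell, rep: int) -> Path:
    return out_dir / "records" / f"{cell.name}_rep{rep:05d}.json"


def run_grid(
    config: GridConfig,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every (cell, rep), aggregate, and return (performance, records).

    With ``out_dir`` set, per-rep records are persisted as JSON and existing
    ones are skipped, so an interrupted run resumes to the identical table.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "records").mkdir(parents=True, exist_ok=True)
    truth_model, scenario = config.resolve_truth_models()
    truths = dgm_mod.true_estimands(truth_model, scenario, horizon=config.horizon)
    truth = truths["rmstd"] if scenario is not None else truths["rmst_control"]

    tasks = []
    done: dict[tuple[int, int], dict] = {}
    for ci, cell in enumerate(config.cells):
        for rep in range(config.reps):
            if out is not None:
                path = _record_path(out, cell, rep)
                if path.exists():
                    with open(path) as fh:
                        done[(ci, rep)] = json.load(fh)
                    continue
            tasks.append((ci, cell, rep))
    if tasks:
        results = Parallel(n_jobs=config.workers, verbose=5 if progress else 0)(
            delayed(run_single_rep)(config, cell, ci, rep)
            for ci, cell, rep in tasks
        )
        for (ci, cell, rep), rec in zip(tasks, results):
            done[(ci, rep)] = rec
            if out is not None:
                with open(_record_path(out, cell, rep), "w") as fh:
                    json.dump(rec, fh)
    records = pd.DataFrame(
        [done[(ci, rep)] for ci in range(len(config.cells))
         for rep in range(config.reps)]
    )
    rows = []
    for ci, cell in enumerate(config.cells):
        cell_records = [done[(ci, rep)] for rep in range(config.reps)]
        row = {"cell": cell.name, **performance(cell_records, truth)}
        rows.append(row)
    table = pd.DataFrame(rows)
    if out is not None:
        report(table, out)
        records.to_csv(out / "records.csv", index=False)
    return table, records


def report(
    table: pd.DataFrame,
    out_dir: str | Path,
    records: pd.DataFrame | None = None,
    plots: bool = False,
) -> None:
    """Write performance tables (wide + tidy) and optional summary plots."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "performance.csv", index=False)
    tidy = table.melt(id_vars=["cell"], var_name="measure", value_name="value")
    tidy.to_csv(out / "performance_tidy.csv", index=False)
    if plots and "bias" in table.columns:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 0.4 * len(table) + 1.5))
        ax.errorbar(table["bias"], np.arange(len(table)),
                    xerr=1.96 * table["bias_mcse"], fmt="o")
        ax.axvline(0.0, color="grey", lw=1)
        ax.set_yticks(np.arange(len(table)))
        ax.set_yticklabels(table["cell"])
        ax.set_xlabel("bias (years)")
        fig.tight_layout()
        fig.savefig(out / "bias.png", dpi=150)
        plt.close(fig)
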