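"""Figures and experiment orchestration.

The graphical vocabulary mirrors the triangulation workflow: per-method and
combined scatterplots of negative Bootstrap P value against selection
stability, the ordered (scree-style) stability profile with the detected
change point, and per-covariate forest panels comparing each method's
bootstrap coefficient interval with the reference OLS fit on the true
covariates.

:func:`run_pipeline` is the in-memory engine (simulate -> per-method
bootstrap -> combined report -> error rates); :func:`run_experiment` wraps
it with persistence of matrices, reports, figures and a machine-readable
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import matplotlib.pyplot as plt
import numpy as np

from . import simdata
from .bootstrap import BootstrapMatrix, run_bootstrap
from .selectors import CvSpec
from .synthesis import StabilityReport, combine_matrices, make_report

__all__ = [
    "ExperimentConfig",
    "DEFAULT_METHODS",
    "preset_config",
    "plot_stability_scatter",
    "plot_ordered_stability",
    "plot_coefficient_intervals",
    "run_pipeline",
    "run_experiment",
]

logger = logging.getLogger(__name__)

#: Methods carried into the combined model.  Stepwise AIC overfits too badly
#: in high dimensions to be worth bootstrapping and is excluded by default.
DEFAULT_METHODS = ("enet", "scad", "mcp", "sparsestep", "mbic")

_MARGIN_P = -0.55  # plotting position for covariates never selected (Bootstrap P undefined)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one triangulation experiment."""

    dataset: int | str | Path  # preset number or CSV path
    methods: tuple[str, ...] = DEFAULT_METHODS
    B: int = 500
    seed: int = 0
    cv_repeats: int = 1
    cv_folds: int = 5
    fast: bool = True  # reduced grids inside replicates
    window: int = 15
    output_dir: str | Path = "triboot_out"
    n_jobs: int = 1
    write_dataset: bool = False
    make_plots: bool = True

    def __post_init__(self):
        if not self.methods:
            raise ValueError("method list must be non-empty")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    def cv_spec(self, seed: int = 0) -> CvSpec:
        if self.fast:
            return dataclasses.replace(
                CvSpec.fast(seed=seed, folds=self.cv_folds), repeats=self.cv_repeats
            )
        return CvSpec(repeats=self.cv_repeats, folds=self.cv_folds, seed=seed)


#: Reduced grids for the p >> n datasets (3, 4, 6).
LARGE_P_GRIDS = {
    "alpha": (0.1, 1.0),
    "n_lambdas": 15,
    "lambda_min_ratio": 0.02,
    "lam_sparsestep": (0.125, 0.5, 2.0, 8.0),
    "screen_k": 300,
    "enet_screen_k": 1000,
}


def preset_config(name: int, seed: int = 0, fast: bool = False, **overrides) -> ExperimentConfig:
    """Experiment presets mirroring the benchmark study conditions.

    Full presets use B = 500 for the 1000 x 910 datasets and B = 100 for the
    200 x 10,010 ones, with 10 x 10-fold CV.  ``fast=True`` scales the study
    down for quick runs: B = 50 with 1 x 5-fold CV and reduced
    hyperparameter grids.
    """
    if name not in simdata.dataset_names():
        raise ValueError(f"unknown dataset preset {name}")
    large = name in (3, 4, 6)
    if fast:
        cfg = dict(B=50, cv_repeats=1, cv_folds=5, fast=True)
    else:
        cfg = dict(B=100 if large else 500, cv_repeats=10, cv_folds=10, fast=False)
    cfg.update(overrides)
    return ExperimentConfig(dataset=name, seed=seed, **cfg)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def _finish(fig, path):
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_stability_scatter(report: StabilityReport, truth=None, path="stability_scatter.png"):
    """Scatter of -Bootstrap P against selection stability.

    True covariates (when ``truth`` is given) are coloured and labelled;
    never-selected covariates (undefined Bootstrap P) sit at the axis
    margin; a vertical line marks the stability threshold when present.
    """
    stab = report.stability
    y = np.where(np.isnan(report.bootstrap_p), _MARGIN_P, -report.bootstrap_p)
    truth = np.asarray(truth, dtype=int) if truth is not None else np.array([], dtype=int)
    is_true = np.zeros(report.p, dtype=bool)
    is_true[truth] = True

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(stab[~is_true], y[~is_true], s=12, c="0.6", alpha=0.6, label="noise")
    if is_true.any():
        ax.scatter(stab[is_true], y[is_true], s=30, c="tab:blue", zorder=3, label="true")
        for j in np.flatnonzero(is_true):
            ax.annotate(
                report.covariate_names[j], (stab[j], y[j]), fontsize=7,
                textcoords="offset points", xytext=(3, 3), color="tab:blue",
            )
    if report.threshold_rank:
        s_sorted = np.sort(stab)[::-1]
        thr = report.threshold_rank
        cut = s_sorted[thr - 1]
        if thr < report.p:
            cut = 0.5 * (cut + s_sorted[thr])
        ax.axvline(cut, color="tab:red", ls="--", lw=1, label="threshold")
    ax.set_xlabel("selection stability (%)")
    ax.set_ylabel("− Bootstrap P value")
    ax.set_title(f"{report.method}: stability vs Bootstrap P")
    if is_true.any():
        ax.legend(loc="lower right", fontsize=8)
    return _finish(fig, path)


def plot_ordered_stability(report: StabilityReport, path="ordered_stability.png"):
    """Descending stability profile with the change-point threshold line."""
    s_sorted = report.stability[report.ranking]
    ranks = np.arange(1, report.p + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ranks, s_sorted, lw=1, c="0.2")
    ax.scatter(ranks[: min(50, report.p)], s_sorted[: min(50, report.p)], s=10, c="0.2")
    if report.threshold_rank:
        ax.axvline(report.threshold_rank + 0.5, color="tab:red", ls="--", lw=1)
    ax.set_xlabel("covariate rank (descending stability)")
    ax.set_ylabel("selection stability (%)")
    ax.set_xscale("log")
    ax.set_title(f"{report.method}: ordered stability")
    return _finish(fig, path)


def plot_coefficient_intervals(
    reports: dict[str, StabilityReport],
    true_fit: "simdata.TrueModelFit | None",
    truth,
    path="coefficient_intervals.png",
):
    """Forest panels: one per true covariate, one interval row per method.

    Rows are each method's bootstrap median and 95% interval of the nonzero
    coefficient values, plus a TRUE row from the reference OLS fit when
    available.
    """
    truth = np.asarray(truth, dtype=int)
    if truth.size == 0:
        raise ValueError("coefficient panels need a nonempty truth set")
    labels = list(reports)
    n_rows = len(labels) + (1 if true_fit is not None else 0)
    ncol = min(5, truth.size)
    nrow = int(np.ceil(truth.size / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.2 * ncol, 1.9 * nrow + 0.8), sharey=True, squeeze=False
    )
    any_report = next(iter(reports.values()))
    for panel, j in enumerate(truth):
        ax = axes[panel // ncol][panel % ncol]
        name = any_report.covariate_names[j]
        ypos = 0
        for label in labels:
            r = reports[label]
            ax.errorbar(
                r.coef_median[j], ypos,
                xerr=[[r.coef_median[j] - r.coef_lo95[j]], [r.coef_hi95[j] - r.coef_median[j]]],
                fmt="o", ms=3, capsize=2,
                color="tab:red" if label == "combined" else "0.3",
            )
            ypos += 1
        if true_fit is not None:
            row = true_fit.table.loc[name]
            ax.errorbar(
                row["estimate"], ypos,
                xerr=[[row["estimate"] - row["lo95"]], [row["hi95"] - row["estimate"]]],
                fmt="s", ms=3, capsize=2, color="tab:blue",
            )
        ax.axvline(0, color="0.8", lw=0.8)
        ax.set_title(name, fontsize=8)
        ax.set_yticks(range(n_rows))
        ax.set_yticklabels(labels + (["TRUE"] if true_fit is not None else []), fontsize=7)
    for k in range(truth.size, nrow * ncol):
        axes[k // ncol][k % ncol].set_visible(False)
    return _finish(fig, path)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    dataset: simdata.SimulatedDataset
    matrices: dict[str, BootstrapMatrix]
    reports: dict[str, StabilityReport]  # per-method plus "combined"
    combined_report: StabilityReport


def run_pipeline(
    ds: simdata.SimulatedDataset,
    methods=DEFAULT_METHODS,
    B: int = 50,
    seed: int = 0,
    cv: CvSpec | None = None,
    window: int = 15,
    n_jobs: int = 1,
) -> PipelineResult:
    """Bootstrap every method, combine, and report — all in memory."""
    truth = ds.true_support if len(ds.true_support) else None
    matrices: dict[str, BootstrapMatrix] = {}
    reports: dict[str, StabilityReport] = {}
    for method in methods:
        logger.info("bootstrapping %s (B=%d)", method, B)
        m = run_bootstrap(
            method, ds.X, ds.y, B=B, seed=seed, cv=cv,
            covariate_names=ds.columns, n_jobs=n_jobs,
        )
        matrices[method] = m
        reports[method] = make_report(m, window=window, true_support=truth)
    if len(matrices) >= 2:
        combined = combine_matrices(list(matrices.values()))
    else:
        combined = next(iter(matrices.values()))
    combined_report = make_report(combined, window=window, true_support=truth)
    combined_report.method = "combined"
    reports["combined"] = combined_report
    return PipelineResult(ds, matrices, reports, combined_report)


def run_experiment(cfg: ExperimentConfig) -> Path:
    """Run a full experiment and persist matrices, reports, figures and summary.

    Returns the output directory.  Everything downstream of the bootstrap is
    reproducible from the persisted matrices alone.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(cfg.dataset, (int, np.integer)):
        ds = simdata.build_dataset(int(cfg.dataset), seed=cfg.seed)
        large = int(cfg.dataset) in (3, 4, 6)
    else:
        ds = simdata.SimulatedDataset.read_csv(cfg.dataset)
        # user-supplied real data are standardized empirically before selection
        sd = ds.X.std(axis=0)
        ds.X = (ds.X - ds.X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        large = ds.p > 2000
    if cfg.write_dataset:
        ds.to_csv(out / "dataset.csv")

    cv = cfg.cv_spec(seed=cfg.seed)
    if cfg.fast and large:
        grids = dict(cv.grids or {})
        grids.update(LARGE_P_GRIDS)
        cv = dataclasses.replace(cv, grids=grids)

    result = run_pipeline(
        ds, methods=cfg.methods, B=cfg.B, seed=cfg.seed, cv=cv,
        window=cfg.window, n_jobs=cfg.n_jobs,
    )

    for method, m in result.matrices.items():
        m.save(out / f"matrix_{method}.csv")
    for label, rep in result.reports.items():
        rep.save(out / f"report_{label}.csv", out / f"report_{label}.json")

    truth = ds.true_support if len(ds.true_support) else None
    if cfg.make_plots:
        matplotlib.use("Agg", force=False)
        for label, rep in result.reports.items():
            plot_stability_scatter(rep, truth=truth, path=out / f"scatter_{label}.png")
        plot_ordered_stability(result.combined_report, path=out / "ordered_combined.png")
        if truth is not None:
            true_fit = simdata.fit_true_model(ds)
            plot_coefficient_intervals(
                result.reports, true_fit, truth, path=out / "coefficients.png"
            )

    summary = {
        "config": {
            **{k: (str(v) if isinstance(v, Path) else v) for k, v in dataclasses.asdict(cfg).items()},
            "methods": list(cfg.methods),
        },
        "dataset": {"name": ds.name, "n": ds.n, "p": ds.p, "seed": ds.seed},
        "reports": {label: rep.summary() for label, rep in result.reports.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return out
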