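"""Estimator comparison: MAE/LCor/RCor metrics, the incompleteness grid
experiment, QQ residual diagnostics and report serialization.

The comparison metrics all act on the canonical 8-entry parameter vector
(b0, b1, b2, b3, sig1, sig2, sig3, sig4): mean absolute error against the
reference vector, Pearson linear correlation (LCor) and Spearman rank
correlation (RCor).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hmc import MCMCConfig, mcmc_fit
from .incomplete import IncompletenessConfig, condition_grid, corrupt
from .model import MixedModelFit, ParameterVector, build_design, ml_fit
from .saem import StepSchedule, saem_fit
from .sem import SEMConfig, sem_fit
from .simulate import ScenarioSpec, simulate_dataset, standard_model_spec

__all__ = [
    "mae", "lcor", "rcor", "qq_residuals", "proportion_removed",
    "run_grid", "ComparisonReport", "METHODS",
]


def _canon(theta) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        return theta.canonical()
    return np.asarray(theta, dtype=float)


def mae(theta_hat, theta_ref) -> float:
    """Mean absolute error (1/n) sum |theta_hat_i - theta_ref_i|."""
    a, b = _canon(theta_hat), _canon(theta_ref)
    if a.shape != b.shape:
        raise ValueError("parameter vectors have different lengths")
    return float(np.mean(np.abs(a - b)))


def lcor(theta_hat, theta_ref) -> float:
    """Pearson linear correlation between the two parameter vectors."""
    a, b = _canon(theta_hat), _canon(theta_ref)
    if a.shape != b.shape:
        raise ValueError("parameter vectors have different lengths")
    if len(a) < 2:
        raise ValueError("need at least two components")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a parameter vector")
    return float(np.corrcoef(a, b)[0, 1])


def rcor(theta_hat, theta_ref) -> float:
    """Spearman rank correlation (average ranks on ties)."""
    a, b = _canon(theta_hat), _canon(theta_ref)
    if a.shape != b.shape:
        raise ValueError("parameter vectors have different lengths")
    return float(stats.spearmanr(a, b).statistic)


def proportion_removed(n_removed: int, n_total: int) -> float:
    """Bookkeeping percentage of removed observations, to two decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_removed / n_total, 2)


def qq_residuals(fit: MixedModelFit, standardize: bool = False):
    """Normal QQ pairs of the (mean-centered) residuals.

    Returns (theoretical, sample) quantile arrays.  The raw scale is kept by
    default so the slope of the point cloud estimates the residual SD;
    ``standardize=True`` rescales by the sample SD for the normalized
    diagnostic plot.  Plotting and CSV export are left to the caller
    (see :func:`plot_qq`).
    """
    r = np.asarray(fit.residuals, dtype=float)
    if len(r) == 0:
        raise ValueError("empty residual vector")
    sd = r.std()
    if sd == 0:
        raise ValueError("zero residual variance")
    sample = np.sort(r - r.mean())
    if standardize:
        sample = sample / sd
    k = np.arange(1, len(r) + 1)
    theoretical = stats.norm.ppf((k - 0.5) / len(r))
    return theoretical, sample


def plot_qq(fit: MixedModelFit, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    t, s = qq_residuals(fit)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(t, s, ".", ms=2)
    lim = [min(t.min(), s.min()), max(t.max(), s.max())]
    ax.plot(lim, lim, "k-", lw=0.8)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("standardized residual")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# grid experiment

METHODS = ("SEM", "SAEM", "MCMC", "KE")


def _fit_method(method, design, data, seed, settings):
    if method == "SEM":
        cfg = SEMConfig(seed=seed, **settings.get("sem", {}))
        return sem_fit(design, data, cfg).theta_hat
    if method == "SAEM":
        cfg = SEMConfig(seed=seed, **settings.get("sem", {}))
        sched = StepSchedule.make(settings.get("saem_mode", "slow_cosine"),
                                  cfg.n_iterations)
        return saem_fit(design, data, cfg, sched).theta_hat
    if method == "MCMC":
        cfg = MCMCConfig(seed=seed, **settings.get("mcmc", {}))
        return mcmc_fit(design, data, cfg).params
    if method == "KE":
        # "keep the case empty": drop unobserved rows, ML on the rest
        keep = data.observed_mask
        sub_design = settings["_subdesign"](keep)
        params, _ = ml_fit(sub_design, data.y[keep])
        return params
    raise ValueError(f"unknown method {method!r}")


@dataclass
class ComparisonReport:
    table: pd.DataFrame

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ComparisonReport":
        table = pd.read_csv(path)
        if "error" in table:
            table["error"] = table["error"].fillna("").astype(str)
        return cls(table)

    def wide(self, metric: str = "mae") -> pd.DataFrame:
        return self.table.pivot_table(
            index=["miss_rate", "cens_rate"], columns="method", values=metric
        )


def run_grid(
    scenario: ScenarioSpec,
    grid: list[IncompletenessConfig] | None = None,
    methods=("SEM",),
    settings: dict | None = None,
    master_seed: int = 0,
    reference: str = "truth",
) -> ComparisonReport:
    """Corrupt a fresh copy of the scenario data per condition, fit each
    method, and score the estimates against the reference vector.

    ``reference="truth"`` scores against the generating parameters;
    ``reference="complete_fit"`` scores against the ML fit of the uncorrupted
    dataset — the comparison a single-dataset benchmark table makes, which
    isolates method error from the dataset's own sampling noise.

    Deterministic given ``master_seed``: condition child seeds come from the
    grid construction and per-method fit seeds derive from the condition seed.
    A failing fit is recorded as a failed row and the grid continues.
    """
    if not methods:
        raise ValueError("at least one method is required")
    if reference not in ("truth", "complete_fit"):
        raise ValueError(f"unknown reference {reference!r}")
    settings = dict(settings or {})
    if grid is None:
        grid = condition_grid(base_seed=master_seed)
    sim = simulate_dataset(scenario)
    spec = standard_model_spec()
    design = build_design(spec, sim.data)
    if reference == "truth":
        truth = scenario.true_params
    else:
        truth, _ = ml_fit(design, sim.data["RT"].to_numpy())

    def subdesign(keep):
        return build_design(spec, sim.data.loc[keep])

    settings["_subdesign"] = subdesign
    rows = []
    for cond in grid:
        data = corrupt(sim.data["RT"].to_numpy(), sim.data, cond)
        for k, method in enumerate(methods):
            fit_seed = int((cond.seed + 7 * master_seed + 1000003 * (k + 1)) % 2**31)
            t0 = time.perf_counter()
            row = {
                "miss_rate": cond.miss_rate, "cens_rate": cond.cens_rate,
                "method": method, "seed": fit_seed, "error": "",
            }
            try:
                theta = _fit_method(method, design, data, fit_seed, settings)
                can = theta.canonical()
                row.update(dict(zip(theta.canonical_names(), can)))
                row["mae"] = mae(theta, truth)
                row["lcor"] = lcor(theta, truth)
                row["rcor"] = rcor(theta, truth)
            except Exception as exc:  # a failed fit must not kill the grid
                warnings.warn(f"{method} failed at {cond.miss_rate}/{cond.cens_rate}: {exc}")
                row.update({"mae": np.nan, "lcor": np.nan, "rcor": np.nan,
                            "error": str(exc)})
            row["runtime_s"] = time.perf_counter() - t0
            rows.append(row)
    return ComparisonReport(pd.DataFrame(rows))
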