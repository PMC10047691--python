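"""Stochastic EM for the mixed model under censored and missing responses.

Each outer iteration alternates

* an S-step: a truncated-normal Gibbs sampler that redraws, in order, the
  residuals of the unobserved rows (censored rows truncated at their
  thresholds, missing rows bounded by the observed response range), the
  participant random-effect block and the item block, each from its full
  conditional given the current completed response; the unobserved rows are
  then completed as X delta + Z u + e; and
* an M-step: maximization of the completed-data likelihood.  The default
  maximizes the marginal mixed-model likelihood of the completed response
  (fixed effects profiled through Henderson's system); ``mstep="moments"``
  instead uses the closed-form moment maximizer given the sampled (u, e),
  :func:`semlmm.model.complete_data_mstep`.

The estimator is the per-component arithmetic mean of the parameter trace
after a burn-in of M iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.stats import truncnorm

from .incomplete import IncompleteResponse
from .model import (
    ITEM, PARTICIPANT, DesignMatrices, ParameterVector, VarianceComponents,
    _ginv_logdet, complete_data_mstep, marginal_loglik, ml_fit,
)

__all__ = [
    "SEMConfig", "GibbsState", "FitTrace",
    "draw_truncated_normal", "gibbs_sweep", "impute_unobserved", "sem_fit",
]


@dataclass
class SEMConfig:
    """Outer iterations N, burn-in M, Gibbs sweeps per iteration G, seed."""

    n_iterations: int = 50
    burn_in: int = 10
    gibbs_sweeps: int = 100
    seed: int = 0
    mstep: str = "ml"            # "ml" (completed-data likelihood) | "moments"
    draws_per_iteration: int = 1  # m_k; > 1 gives the MCEM average
    estimate_rho: bool = False
    mstep_maxiter: int = 100

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.gibbs_sweeps < 1:
            raise ValueError("need at least one Gibbs sweep")
        if self.mstep not in ("ml", "moments"):
            raise ValueError(f"unknown mstep {self.mstep!r}")


@dataclass
class GibbsState:
    """Current latent draws: random-effect blocks, residuals, completed y."""

    u_s: np.ndarray          # S x t_S
    u_i: np.ndarray          # I x t_I
    e: np.ndarray            # length n
    y_completed: np.ndarray  # length n
    sweep: int = 0


@dataclass
class FitTrace:
    """Per-iteration parameter states and the post-burn-in average."""

    theta_by_iter: np.ndarray        # N x P
    names: list[str]
    theta_hat: ParameterVector
    burn_in: int
    loglik: np.ndarray
    aborted: bool = False
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_trace(cls, rows, names, burn_in, template: ParameterVector,
                   loglik=None, aborted=False, meta=None) -> "FitTrace":
        rows = np.asarray(rows, dtype=float)
        post = rows[burn_in:]
        if len(post) == 0:
            post = rows
        mean = post.mean(axis=0)
        n_can = len(template.canonical())
        theta_hat = ParameterVector.from_canonical(mean[:n_can], template)
        if len(names) > n_can:  # trailing correlation columns, averaged on z-scale
            extra = dict(zip(names[n_can:], np.tanh(
                np.arctanh(np.clip(post[:, n_can:], -0.999, 0.999)).mean(axis=0)
            )))
            theta_hat.vc.rho_s = float(extra.get("rho_s", theta_hat.vc.rho_s))
            theta_hat.vc.rho_i = float(extra.get("rho_i", theta_hat.vc.rho_i))
        return cls(
            theta_by_iter=rows, names=list(names), theta_hat=theta_hat,
            burn_in=burn_in,
            loglik=np.asarray(loglik if loglik is not None else []),
            aborted=aborted, meta=meta or {},
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.theta_by_iter, columns=self.names)
        df.insert(0, "iteration", np.arange(1, len(df) + 1))
        if len(self.loglik) == len(df):
            df["loglik"] = self.loglik
        return df

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# truncated-normal draws


def draw_truncated_normal(mean, sd, lower, upper, rng: np.random.Generator):
    """Draw from N(mean, sd^2) conditioned to [lower, upper] (vectorized).

    Inverse-CDF construction through scipy's truncnorm, which evaluates the
    standardized CDF differences in a tail-safe way, so draws remain correct
    far into the tails.  Infinite bounds are allowed.
    """
    mean, sd, lower, upper = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mean, sd, lower, upper))
    )
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    if np.any(sd < 0):
        raise ValueError("negative sd")
    out = np.empty(mean.shape)
    zero = sd == 0
    if zero.any():
        m = mean[zero]
        if np.any((m < lower[zero]) | (m > upper[zero])):
            raise ValueError("sd = 0 with mean outside the bounds")
        out[zero] = m
    if (~zero).any():
        m, s = mean[~zero], sd[~zero]
        a = (lower[~zero] - m) / s
        b = (upper[~zero] - m) / s
        u = rng.random(m.shape)
        out[~zero] = m + s * truncnorm.ppf(u, a, b)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# sweep context (precomputations shared across sweeps)


class _SweepContext:
    def __init__(self, design: DesignMatrices, data: IncompleteResponse):
        if design.n != data.n:
            raise ValueError("design and response lengths differ")
        self.design = design
        self.data = data
        self.obs = data.observed_mask
        self.unobs_idx = np.flatnonzero(~self.obs)
        self.miss_idx = np.flatnonzero(data.missing_mask)
        self.right_idx = np.flatnonzero(data.right_censored_mask)
        self.left_idx = np.flatnonzero(data.left_censored_mask)
        yo = data.y[self.obs]
        self.ymin = yo.min() if len(yo) else -np.inf
        self.ymax = yo.max() if len(yo) else np.inf
        # per-group observed response ranges (inf when a group is all-unobserved)
        self.range_s = self._group_range(design.s_index, design.n_s)
        self.range_i = self._group_range(design.i_index, design.n_i)

    def _group_range(self, index, n_levels):
        # levels with < 2 observed rows carry no range information: unbounded
        rng_ = np.full(n_levels, np.inf)
        idx = index[self.obs]
        y = self.data.y[self.obs]
        if len(y):
            gmax = np.full(n_levels, -np.inf)
            gmin = np.full(n_levels, np.inf)
            np.maximum.at(gmax, idx, y)
            np.minimum.at(gmin, idx, y)
            counts = np.bincount(idx, minlength=n_levels)
            ok = counts >= 2
            rng_[ok] = gmax[ok] - gmin[ok]
        return rng_


def _init_state(ctx: _SweepContext, params: ParameterVector) -> GibbsState:
    d = ctx.design
    u_s = np.zeros((d.n_s, len(d.term_names_s)))
    u_i = np.zeros((d.n_i, len(d.term_names_i)))
    fixed = d.X @ params.delta
    y_completed = np.where(ctx.obs, ctx.data.y, fixed)
    e = y_completed - fixed
    return GibbsState(u_s=u_s, u_i=u_i, e=e, y_completed=y_completed)


def _intercept_bounds(u_prev: np.ndarray, group_range: np.ndarray):
    """Scalar truncation interval per level for an intercept draw.

    The literal bound recipe — per-level extremes of the observed response
    minus the other current components, applied elementwise and collapsed by
    max/min — reduces to the previous value plus/minus the within-level
    observed response range.  Alternative readings are one-line swaps here.
    """
    return u_prev - group_range, u_prev + group_range


def _draw_unobserved_residuals(ctx, state, params, rng):
    """Redraw e at unobserved rows from truncated N(0, sigma_e^2); censored
    rows are truncated at their thresholds, missing rows bounded by the
    observed response range."""
    d = ctx.design
    fixed = d.X @ params.delta
    rand = ((d.z_s * state.u_s[d.s_index]).sum(axis=1)
            + (d.z_i * state.u_i[d.i_index]).sum(axis=1))
    loc = fixed + rand
    n_un = len(ctx.unobs_idx)
    lower = np.full(n_un, -np.inf)
    upper = np.full(n_un, np.inf)
    pos = {r: k for k, r in enumerate(ctx.unobs_idx)}
    if len(ctx.miss_idx):
        k = np.array([pos[r] for r in ctx.miss_idx])
        lower[k] = ctx.ymin - loc[ctx.miss_idx]
        upper[k] = ctx.ymax - loc[ctx.miss_idx]
    if len(ctx.right_idx):
        k = np.array([pos[r] for r in ctx.right_idx])
        lower[k] = ctx.data.threshold[ctx.right_idx] - loc[ctx.right_idx]
    if len(ctx.left_idx):
        k = np.array([pos[r] for r in ctx.left_idx])
        upper[k] = ctx.data.threshold[ctx.left_idx] - loc[ctx.left_idx]
    bad = lower > upper
    if bad.any():
        warnings.warn("incompatible Gibbs bounds; widened to the unconstrained "
                      "conditional")
        lower[bad], upper[bad] = -np.inf, np.inf
    e_new = draw_truncated_normal(0.0, params.vc.sigma_e, lower, upper, rng)
    state.e[ctx.unobs_idx] = e_new
    state.y_completed = ctx.data.y.copy()
    state.y_completed[ctx.unobs_idx] = loc[ctx.unobs_idx] + e_new
    return rand


def _update_factor_block(ctx, state, params, rng, role: str):
    """Coordinate-wise Gaussian full-conditional update of one factor's block,
    vectorized over levels (levels are mutually independent given the rest)."""
    d = ctx.design
    if role == PARTICIPANT:
        z, u, index, n_lev, rng_grp = d.z_s, state.u_s, d.s_index, d.n_s, ctx.range_s
        cov = params.vc.factor_cov(PARTICIPANT)
    else:
        z, u, index, n_lev, rng_grp = d.z_i, state.u_i, d.i_index, d.n_i, ctx.range_i
        cov = params.vc.factor_cov(ITEM)
    K = np.linalg.inv(cov)  # prior precision of one level's coefficient vector
    sig2 = params.vc.sigma_e ** 2
    fixed = d.X @ params.delta
    other_role = ((d.z_i * state.u_i[d.i_index]).sum(axis=1) if role == PARTICIPANT
                  else (d.z_s * state.u_s[d.s_index]).sum(axis=1))
    base = state.y_completed - fixed - other_role
    t = u.shape[1]
    for j in range(t):
        partial = base - sum(
            z[:, l] * u[index, l] for l in range(t) if l != j
        ) if t > 1 else base
        a = np.bincount(index, z[:, j] ** 2, minlength=n_lev) / sig2
        b = np.bincount(index, z[:, j] * partial, minlength=n_lev) / sig2
        prior_mean_term = -(K[j, :j] @ u[:, :j].T + K[j, j + 1:] @ u[:, j + 1:].T) \
            if t > 1 else 0.0
        post_prec = a + K[j, j]
        post_mean = (b + prior_mean_term) / post_prec
        post_sd = 1.0 / np.sqrt(post_prec)
        if j == 0:
            lo, hi = _intercept_bounds(u[:, 0], rng_grp)
            bad = lo > hi
            if bad.any():
                lo[bad], hi[bad] = -np.inf, np.inf
        else:
            lo, hi = np.full(n_lev, -np.inf), np.full(n_lev, np.inf)
        u[:, j] = draw_truncated_normal(post_mean, post_sd, lo, hi, rng)


def gibbs_sweep(
    state: GibbsState,
    design: DesignMatrices,
    data: IncompleteResponse,
    params: ParameterVector,
    rng: np.random.Generator,
    ctx: _SweepContext | None = None,
) -> GibbsState:
    """One systematic-scan sweep: residuals of the unobserved rows, then the
    participant block, then the item block, each from its truncated-normal
    full conditional.  With no unobserved rows the state is returned unchanged
    and no randomness is consumed."""
    if ctx is None:
        ctx = _SweepContext(design, data)
    if len(ctx.unobs_idx) == 0:
        return state
    _draw_unobserved_residuals(ctx, state, params, rng)
    _update_factor_block(ctx, state, params, rng, PARTICIPANT)
    _update_factor_block(ctx, state, params, rng, ITEM)
    state.sweep += 1
    return state


def impute_unobserved(
    design: DesignMatrices,
    data: IncompleteResponse,
    params: ParameterVector,
    G: int,
    rng: np.random.Generator,
    ctx: _SweepContext | None = None,
) -> tuple[np.ndarray, GibbsState]:
    """Complete the response by G Gibbs sweeps from a cold start.

    Unobserved rows are set to X delta + Z u^(G) + e^(G); right/left-censored
    imputations respect their thresholds by construction.  Observed rows are
    untouched.  The returned state also carries the implied residuals at
    observed rows (for the moment M-step)."""
    if G < 1:
        raise ValueError("G must be >= 1")
    if ctx is None:
        ctx = _SweepContext(design, data)
    state = _init_state(ctx, params)
    if len(ctx.unobs_idx) == 0:
        return data.y.copy(), state
    for _ in range(G):
        gibbs_sweep(state, design, data, params, rng, ctx=ctx)
    d = design
    rand = ((d.z_s * state.u_s[d.s_index]).sum(axis=1)
            + (d.z_i * state.u_i[d.i_index]).sum(axis=1))
    state.e = state.y_completed - d.X @ params.delta - rand
    return state.y_completed.copy(), state


# ---------------------------------------------------------------------------
# random initialization and the shared stochastic-EM loop


def _random_init(design: DesignMatrices, data: IncompleteResponse,
                 rng: np.random.Generator) -> ParameterVector:
    """Random initialization: OLS fixed effects on the observed rows, variance
    components from residual moment heuristics, all with multiplicative
    jitter so restarts differ."""
    obs = data.observed_mask
    X, y = design.X[obs], data.y[obs]
    delta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ delta
    sd_r = max(float(r.std()), 1e-3)

    def group_sd(index, n_lev):
        s = np.bincount(index[obs], r, minlength=n_lev)
        c = np.maximum(np.bincount(index[obs], minlength=n_lev), 1)
        return max(float((s / c).std()), 0.05 * sd_r)

    jit = lambda: float(np.exp(0.15 * rng.standard_normal()))
    sigma_s = [group_sd(design.s_index, design.n_s) * jit()]
    sigma_s += [0.1 * sd_r / max(float(design.z_s[:, j].std()), 1e-6) * jit()
                for j in range(1, len(design.term_names_s))]
    sigma_i = [group_sd(design.i_index, design.n_i) * jit()]
    sigma_i += [0.1 * sd_r / max(float(design.z_i[:, j].std()), 1e-6) * jit()
                for j in range(1, len(design.term_names_i))]
    vc = VarianceComponents(
        term_names_s=list(design.term_names_s), sigma_s=np.array(sigma_s),
        term_names_i=list(design.term_names_i), sigma_i=np.array(sigma_i),
        sigma_e=0.9 * sd_r * jit(),
    )
    return ParameterVector(delta=delta + 0.05 * sd_r * rng.standard_normal(len(delta)),
                           vc=vc)


def _draw_u_posterior(design: DesignMatrices, y: np.ndarray,
                      params: ParameterVector, rng: np.random.Generator):
    """One exact draw of the full random-effect vector from p(u | y, theta)."""
    sig2 = max(params.vc.sigma_e, 1e-8) ** 2
    xp = design.crossprods()
    Ginv, _ = _ginv_logdet(design, params.vc)
    P = Ginv + xp["ZtZ"] / sig2
    Z = design.incidence()
    rhs = np.asarray(Z.T @ (y - design.X @ params.delta)).ravel() / sig2
    cf = cho_factor(P, lower=True)
    mean = cho_solve(cf, rhs)
    z = rng.standard_normal(len(rhs))
    u = mean + solve_triangular(cf[0], z, lower=True, trans=1)
    t_s = len(design.term_names_s)
    q_s = design.n_s * t_s
    return {
        PARTICIPANT: u[:q_s].reshape(design.n_s, t_s),
        ITEM: u[q_s:].reshape(design.n_i, len(design.term_names_i)),
    }


def _smooth_pack(pv: ParameterVector) -> np.ndarray:
    vc = pv.vc
    return np.concatenate([
        pv.delta, vc.sigma_s**2, vc.sigma_i**2, [vc.sigma_e**2],
        np.arctanh(np.clip([vc.rho_s, vc.rho_i], -0.999, 0.999)),
    ])


def _smooth_unpack(vec: np.ndarray, template: ParameterVector) -> ParameterVector:
    n_f = len(template.delta)
    t_s = len(template.vc.sigma_s)
    t_i = len(template.vc.sigma_i)
    delta = vec[:n_f]
    var = np.maximum(vec[n_f:n_f + t_s + t_i + 1], 0.0)
    rho_s, rho_i = np.tanh(vec[n_f + t_s + t_i + 1:])
    vc = VarianceComponents(
        term_names_s=list(template.vc.term_names_s), sigma_s=np.sqrt(var[:t_s]),
        term_names_i=list(template.vc.term_names_i),
        sigma_i=np.sqrt(var[t_s:t_s + t_i]),
        rho_s=float(rho_s), rho_i=float(rho_i),
        sigma_e=float(np.sqrt(var[-1])),
    )
    return ParameterVector(delta=delta, vc=vc)


def _moment_mstep(design, ycomp_list, states, params, rng, ctx):
    """Closed-form moment M-step; with m > 1 sufficient statistics (second
    moments) are averaged over the imputations.  On fully observed data the
    latent u is drawn once from its exact posterior so the moments remain
    defined."""
    d = design

    def draws(ycomp, state):
        if len(ctx.unobs_idx) == 0:
            u = _draw_u_posterior(d, ycomp, params, rng)
        else:
            u = {PARTICIPANT: state.u_s, ITEM: state.u_i}
        rand = ((d.z_s * u[PARTICIPANT][d.s_index]).sum(axis=1)
                + (d.z_i * u[ITEM][d.i_index]).sum(axis=1))
        return u, ycomp - d.X @ params.delta - rand

    if len(ycomp_list) == 1:
        u, e = draws(ycomp_list[0], states[0])
        return complete_data_mstep(d, ycomp_list[0], u, e)
    m = len(ycomp_list)
    acc_us, acc_ui, acc_e2 = 0.0, 0.0, 0.0
    for ycomp, state in zip(ycomp_list, states):
        u, e = draws(ycomp, state)
        acc_us = acc_us + u[PARTICIPANT] ** 2 / m
        acc_ui = acc_ui + u[ITEM] ** 2 / m
        acc_e2 = acc_e2 + e ** 2 / m
    u_draw = {PARTICIPANT: np.sqrt(acc_us), ITEM: np.sqrt(acc_ui)}
    ybar = np.mean(ycomp_list, axis=0)
    return complete_data_mstep(d, ybar, u_draw, np.sqrt(acc_e2))


def _stochastic_em(
    design: DesignMatrices,
    data: IncompleteResponse,
    config: SEMConfig,
    gammas: np.ndarray,
    m_schedule: np.ndarray,
) -> FitTrace:
    rng = np.random.default_rng(config.seed)
    ctx = _SweepContext(design, data)
    params = _random_init(design, data, rng)
    rows, logliks = [], []
    names = None
    aborted = False
    for j in range(config.n_iterations):
        ycomp_list, states = [], []
        for _ in range(int(m_schedule[j])):
            ycomp, state = impute_unobserved(
                design, data, params, config.gibbs_sweeps, rng, ctx=ctx
            )
            ycomp_list.append(ycomp)
            states.append(state)
        if config.mstep == "ml":
            Y = np.column_stack(ycomp_list)
            m_params, _ = ml_fit(design, Y, start=params.vc,
                                 estimate_rho=config.estimate_rho,
                                 maxiter=config.mstep_maxiter)
        else:
            m_params = _moment_mstep(design, ycomp_list, states, params, rng, ctx)
        g = float(gammas[j])
        if g == 1.0:
            params = m_params
        elif g == 0.0:
            pass
        else:
            params = _smooth_unpack(
                _smooth_pack(params) + g * (_smooth_pack(m_params) - _smooth_pack(params)),
                params,
            )
        can = params.canonical()
        if names is None:
            names = params.canonical_names()
            if config.estimate_rho:
                names = names + ["rho_s"]
        row = np.concatenate([can, [params.vc.rho_s]]) if config.estimate_rho else can
        if not np.isfinite(row).all():
            warnings.warn("non-finite parameters; aborting with partial trace")
            aborted = True
            break
        rows.append(row)
        logliks.append(marginal_loglik(design, ycomp_list[-1], params))
    burn = min(config.burn_in, max(len(rows) - 1, 0))
    return FitTrace.from_trace(rows, names, burn, params, loglik=logliks,
                               aborted=aborted,
                               meta={"config": config, "gammas": gammas})


def sem_fit(
    design: DesignMatrices,
    data: IncompleteResponse,
    config: SEMConfig | None = None,
) -> FitTrace:
    """Algorithm: N stochastic-EM iterations from a random initialization,
    each a fresh imputation of the unobserved rows followed by complete-data
    maximization; the estimate is the post-burn-in average of the trace."""
    config = config or SEMConfig()
    if design.n <= design.X.shape[1]:
        raise ValueError("model not identifiable: n <= fixed-effect columns")
    N = config.n_iterations
    return _stochastic_em(
        design, data, config,
        gammas=np.ones(N),
        m_schedule=np.full(N, config.draws_per_iteration, dtype=int),
    )
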