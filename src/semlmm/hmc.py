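"""Hamiltonian Monte Carlo machinery and the Bayesian comparator fit.

The Hamiltonian H(p, q) = K(p) + V(q) pairs the potential V = -log target with
a Gaussian kinetic term K = sum p_i^2 / (2 m_i); proposals integrate the
dynamics with the leapfrog scheme and are accepted with the symmetric
Metropolis probability min(1, exp(H0 - H1)).

``mcmc_fit`` is a Metropolis-within-Gibbs sampler over the fixed effects,
variance components and latent unobserved responses, with the participant
random-slope block (the fixed-random interaction, where plain Monte Carlo
updates mix poorly) updated by HMC.  Priors are weakly informative:
N(0, (1e3 sd(y))^2) on fixed effects, half-Cauchy(sd(y)) on SDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .incomplete import IncompleteResponse
from .model import ITEM, PARTICIPANT, DesignMatrices, ParameterVector, VarianceComponents
from .sem import _SweepContext, _draw_unobserved_residuals, _init_state

__all__ = [
    "HMCConfig", "MCMCConfig", "PosteriorSample",
    "hamiltonian", "leapfrog", "hmc_accept", "hmc_chain", "mcmc_fit",
]


@dataclass
class HMCConfig:
    step_size: float = 0.5
    leapfrog_steps: int = 10
    mass: np.ndarray | float = 1.0
    n_samples: int = 1000
    burn_in: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.leapfrog_steps < 1:
            raise ValueError("need at least one leapfrog step")
        if np.any(np.asarray(self.mass) <= 0):
            raise ValueError("mass entries must be positive")


def hamiltonian(q, p, neg_log_target: float, mass) -> float:
    """H = V(q) + K(p), V the negative log target (up to a constant),
    K = sum p_i^2 / (2 m_i)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    m = np.broadcast_to(np.asarray(mass, dtype=float), p.shape)
    if not np.isfinite(neg_log_target):
        return np.inf
    return float(neg_log_target + 0.5 * np.sum(p**2 / m))


def leapfrog(q, p, eps: float, L: int, grad_V, mass):
    """Standard leapfrog: half momentum step, L position/momentum steps,
    half momentum step.  ``grad_V`` is the gradient of the potential."""
    q = np.atleast_1d(np.asarray(q, dtype=float)).copy()
    p = np.atleast_1d(np.asarray(p, dtype=float)).copy()
    m = np.broadcast_to(np.asarray(mass, dtype=float), p.shape)
    p -= 0.5 * eps * grad_V(q)
    for step in range(L):
        q += eps * p / m
        if step < L - 1:
            p -= eps * grad_V(q)
    p -= 0.5 * eps * grad_V(q)
    return q, p


def hmc_accept(H0: float, H1: float, rng: np.random.Generator) -> bool:
    """Symmetric-Metropolis rule: accept with probability min(1, exp(H0 - H1))."""
    if H1 == np.inf:
        return False
    if H1 <= H0:
        return True
    return rng.random() < np.exp(H0 - H1)


def hmc_chain(
    neg_log_target,
    grad,
    q0,
    config: HMCConfig,
    rng: np.random.Generator | None = None,
):
    """Plain HMC chain on a generic target; returns (draws, acceptance rate).

    Draws include the burn-in portion at the front; callers slice as needed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    q = np.atleast_1d(np.asarray(q0, dtype=float)).copy()
    m = np.broadcast_to(np.asarray(config.mass, dtype=float), q.shape)
    draws = np.empty((config.n_samples, len(q)))
    n_acc = 0
    for i in range(config.n_samples):
        p = rng.standard_normal(len(q)) * np.sqrt(m)
        H0 = hamiltonian(q, p, neg_log_target(q), m)
        q1, p1 = leapfrog(q, p, config.step_size, config.leapfrog_steps, grad, m)
        if np.isfinite(q1).all():
            H1 = hamiltonian(q1, p1, neg_log_target(q1), m)
        else:
            H1 = np.inf
        if hmc_accept(H0, H1, rng):
            q = q1
            n_acc += 1
        draws[i] = q
    return draws, n_acc / config.n_samples


# ---------------------------------------------------------------------------
# the mixed-model posterior sampler


@dataclass
class MCMCConfig:
    n_samples: int = 800
    burn_in: int = 200
    seed: int = 0
    hmc_step_size: float = 0.6
    leapfrog_steps: int = 10
    rw_scale: float = 0.15           # random-walk SD on log sigma
    delta_prior_mult: float = 1e3    # prior SD on delta, in units of sd(y)

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("need 0 <= burn_in < n_samples")


@dataclass
class PosteriorSample:
    draws: pd.DataFrame
    acceptance_rate: float
    params: ParameterVector
    meta: dict = field(default_factory=dict)


def _half_cauchy_logpdf(x, scale):
    return -np.log1p((x / scale) ** 2)  # up to a constant


def _update_sd_mh(sd, values, scale, rw, rng):
    """Random-walk MH on log sigma for a block of zero-mean draws."""
    sd = max(sd, 1e-8)
    prop = sd * np.exp(rw * rng.standard_normal())
    ssq = float(np.sum(values**2))
    k = len(values)

    def logpost(s):
        return (-k * np.log(s) - 0.5 * ssq / s**2
                + _half_cauchy_logpdf(s, scale) + np.log(s))

    if np.log(rng.random()) < logpost(prop) - logpost(sd):
        return prop
    return sd


def mcmc_fit(
    design: DesignMatrices,
    data: IncompleteResponse,
    config: MCMCConfig | None = None,
) -> PosteriorSample:
    """Metropolis-within-Gibbs posterior sampling of the censored/missing
    mixed model; the participant slope block moves by HMC.  The point estimate
    is the post-burn-in posterior mean."""
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    ctx = _SweepContext(design, data)
    d = design
    t_s = len(d.term_names_s)
    yo = data.y[data.observed_mask]
    y_scale = max(float(yo.std()), 1e-6)
    tau = config.delta_prior_mult * y_scale

    # initial state: OLS fixed effects, heuristic SDs
    delta, *_ = np.linalg.lstsq(d.X[data.observed_mask], yo, rcond=None)
    r = yo - d.X[data.observed_mask] @ delta
    sd_r = max(float(r.std()), 1e-3)
    sigma_s = np.full(t_s, 0.3 * sd_r)
    sigma_i = np.full(len(d.term_names_i), 0.3 * sd_r)
    sigma_e = 0.9 * sd_r

    def current_params():
        return ParameterVector(delta=delta.copy(), vc=VarianceComponents(
            term_names_s=list(d.term_names_s), sigma_s=sigma_s.copy(),
            term_names_i=list(d.term_names_i), sigma_i=sigma_i.copy(),
            sigma_e=sigma_e,
        ))

    state = _init_state(ctx, current_params())
    XtX = d.X.T @ d.X
    eps = config.hmc_step_size
    halved = False
    recent: list[bool] = []
    n_acc = n_prop = 0
    rows = []
    names = current_params().canonical_names()

    for it in range(config.n_samples):
        params = current_params()
        # latent unobserved responses
        if len(ctx.unobs_idx):
            _draw_unobserved_residuals(ctx, state, params, rng)
        else:
            state.y_completed = data.y.copy()
        fixed = d.X @ delta
        item_contrib = (d.z_i * state.u_i[d.i_index]).sum(axis=1)

        # participant intercepts: conjugate Gaussian conditional
        w = state.y_completed - fixed - item_contrib
        if t_s > 1:
            w = w - sum(d.z_s[:, l] * state.u_s[d.s_index, l] for l in range(1, t_s))
        a = np.bincount(d.s_index, minlength=d.n_s) / sigma_e**2 + 1.0 / sigma_s[0] ** 2
        b = np.bincount(d.s_index, w, minlength=d.n_s) / sigma_e**2
        state.u_s[:, 0] = b / a + rng.standard_normal(d.n_s) / np.sqrt(a)

        # participant slope block (fixed-random interaction) by HMC
        if t_s > 1:
            for j in range(1, t_s):
                others = state.y_completed - fixed - item_contrib - sum(
                    d.z_s[:, l] * state.u_s[d.s_index, l]
                    for l in range(t_s) if l != j
                )
                prec = (np.bincount(d.s_index, d.z_s[:, j] ** 2, minlength=d.n_s)
                        / sigma_e**2 + 1.0 / sigma_s[j] ** 2)
                mean = (np.bincount(d.s_index, d.z_s[:, j] * others, minlength=d.n_s)
                        / sigma_e**2) / prec

                def neg_log(qv):
                    return 0.5 * float(prec @ (qv - mean) ** 2)

                def grad(qv):
                    return prec * (qv - mean)

                q = state.u_s[:, j].copy()
                p = rng.standard_normal(d.n_s) * np.sqrt(prec)
                H0 = hamiltonian(q, p, neg_log(q), prec)
                q1, p1 = leapfrog(q, p, eps, config.leapfrog_steps, grad, prec)
                H1 = (hamiltonian(q1, p1, neg_log(q1), prec)
                      if np.isfinite(q1).all() else np.inf)
                ok = hmc_accept(H0, H1, rng)
                n_prop += 1
                recent.append(ok)
                if ok:
                    state.u_s[:, j] = q1
                    n_acc += 1
                if len(recent) >= 50 and not any(recent[-50:]):
                    if halved:
                        raise RuntimeError(
                            "HMC acceptance stuck at zero after halving the "
                            f"step size (eps={eps:.3g})"
                        )
                    eps *= 0.5
                    halved = True
                    recent.clear()

        # item blocks: conjugate Gaussian conditionals, coordinate-wise
        part_contrib = (d.z_s * state.u_s[d.s_index]).sum(axis=1)
        for j in range(len(d.term_names_i)):
            others = state.y_completed - fixed - part_contrib - sum(
                d.z_i[:, l] * state.u_i[d.i_index, l]
                for l in range(len(d.term_names_i)) if l != j
            )
            a = (np.bincount(d.i_index, d.z_i[:, j] ** 2, minlength=d.n_i)
                 / sigma_e**2 + 1.0 / sigma_i[j] ** 2)
            b = (np.bincount(d.i_index, d.z_i[:, j] * others, minlength=d.n_i)
                 / sigma_e**2)
            state.u_i[:, j] = b / a + rng.standard_normal(d.n_i) / np.sqrt(a)

        # fixed effects: Gaussian conditional with the wide normal prior
        rand = ((d.z_s * state.u_s[d.s_index]).sum(axis=1)
                + (d.z_i * state.u_i[d.i_index]).sum(axis=1))
        prec_d = XtX / sigma_e**2 + np.eye(d.X.shape[1]) / tau**2
        mean_d = np.linalg.solve(prec_d, d.X.T @ (state.y_completed - rand) / sigma_e**2)
        cf = cho_factor(prec_d, lower=True)
        delta = mean_d + solve_triangular(
            cf[0], rng.standard_normal(d.X.shape[1]), lower=True, trans=1
        )

        # variance components: random-walk MH with half-Cauchy priors
        for j in range(t_s):
            sigma_s[j] = _update_sd_mh(sigma_s[j], state.u_s[:, j], y_scale,
                                       config.rw_scale, rng)
        for j in range(len(d.term_names_i)):
            sigma_i[j] = _update_sd_mh(sigma_i[j], state.u_i[:, j], y_scale,
                                       config.rw_scale, rng)
        e = state.y_completed - d.X @ delta - rand
        sigma_e = _update_sd_mh(sigma_e, e, y_scale, config.rw_scale, rng)

        rows.append(current_params().canonical())

    draws = pd.DataFrame(rows, columns=names)
    post = draws.iloc[config.burn_in:]
    template = current_params()
    params_hat = ParameterVector.from_canonical(post.mean().to_numpy(), template)
    acc = n_acc / n_prop if n_prop else 1.0
    return PosteriorSample(
        draws=draws, acceptance_rate=acc, params=params_hat,
        meta={"eps_final": eps, "halved": halved},
    )
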