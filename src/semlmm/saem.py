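"""SAEM and MCEM variants of the stochastic-EM engine.

SAEM damps the stochastic-EM update with a decreasing step-size sequence:

    theta_{j+1} = theta_j + gamma_j (M(Y_j) - theta_j),

applied componentwise to the fixed effects, the variances, and the Fisher-z
transform of the correlations, where M(Y_j) is the complete-data maximizer of
the current imputation.  gamma identically 1 recovers SEM exactly.  MCEM keeps
gamma = 1 but averages the complete-data objective over m(k) independent
imputations per iteration; m identically 1 again recovers SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DesignMatrices
from .incomplete import IncompleteResponse
from .sem import FitTrace, SEMConfig, _stochastic_em

__all__ = ["StepSchedule", "step_size", "saem_fit", "mcem_fit"]

_STANDARD_MODES = ("slow_cosine", "linear", "hybrid", "constant")
_HYBRID_SWITCH = 20
_HYBRID_C = 6.0  # chosen so gamma_20 = c/20 = 0.3, continuous with the cosine branch


def step_size(mode: str, j: int, N: int) -> float:
    """Step size gamma_j for iteration j of an N-iteration schedule.

    slow_cosine: cos(j pi / (2N)); hybrid: cos(j arccos(0.3)/20) for j <= 20
    then 6/j; linear: 1 - (j+1)/N clipped to [0, 1]; linear_literal: the
    (negative) printed form -(j+1)/N, kept selectable; constant: 1.
    """
    if not 0 <= j <= N:
        raise ValueError(f"iteration index {j} outside [0, {N}]")
    if mode == "slow_cosine":
        return float(np.cos(j * np.pi / (2 * N)))
    if mode == "linear":
        return float(np.clip(1.0 - (j + 1) / N, 0.0, 1.0))
    if mode == "linear_literal":
        return -(j + 1) / N
    if mode == "hybrid":
        if j <= _HYBRID_SWITCH:
            return float(np.cos(j * np.arccos(0.3) / _HYBRID_SWITCH))
        return _HYBRID_C / j
    if mode == "constant":
        return 1.0
    raise ValueError(f"unknown step-size mode {mode!r}")


@dataclass
class StepSchedule:
    """A realized gamma_0 .. gamma_N sequence."""

    mode: str
    N: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.N + 1:
            raise ValueError("schedule length must be N + 1")
        if self.mode in _STANDARD_MODES:
            if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
                raise ValueError("step sizes must lie in [0, 1]")
            if (np.diff(self.values) > 1e-12).any():
                raise ValueError("step sizes must be non-increasing")

    @classmethod
    def make(cls, mode: str, N: int) -> "StepSchedule":
        return cls(mode=mode, N=N,
                   values=np.array([step_size(mode, j, N) for j in range(N + 1)]))

    def to_json(self) -> str:
        import json
        return json.dumps({"mode": self.mode, "N": self.N,
                           "values": self.values.tolist()})


def saem_fit(
    design: DesignMatrices,
    data: IncompleteResponse,
    config: SEMConfig | None = None,
    schedule: StepSchedule | None = None,
) -> FitTrace:
    """Stochastic-approximation EM with a decreasing step-size sequence.

    The estimate keeps the same post-burn-in trace average as SEM.
    """
    config = config or SEMConfig()
    N = config.n_iterations
    if schedule is None:
        schedule = StepSchedule.make("slow_cosine", N)
    if schedule.N != N:
        raise ValueError("schedule length does not match n_iterations")
    return _stochastic_em(
        design, data, config,
        gammas=schedule.values[:N],
        m_schedule=np.full(N, config.draws_per_iteration, dtype=int),
    )


def mcem_fit(
    design: DesignMatrices,
    data: IncompleteResponse,
    config: SEMConfig | None = None,
    m_schedule=None,
) -> FitTrace:
    """Monte-Carlo EM: m(k) independent imputations per iteration, M-step on
    the averaged complete-data statistics."""
    config = config or SEMConfig()
    N = config.n_iterations
    if m_schedule is None:
        m_schedule = np.full(N, config.draws_per_iteration, dtype=int)
    else:
        m_schedule = np.asarray(np.broadcast_to(m_schedule, (N,)), dtype=int)
    if (m_schedule < 1).any():
        raise ValueError("m(k) must be >= 1")
    return _stochastic_em(
        design, data, config, gammas=np.ones(N), m_schedule=m_schedule,
    )
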