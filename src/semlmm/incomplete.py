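"""Censoring and missingness: representation, generation, and the condition grid.

A response vector is partitioned into observed, missing, left-censored and
right-censored rows.  Censoring is by empirical quantile so the achieved count
equals the requested count exactly; missingness is MCAR (Bernoulli), MAR
(logistic in an observed covariate, intercept calibrated by bisection) or MNAR
(logistic in the response itself).  Corruption is applied censoring-first, then
missingness among the remaining observed rows, so combined rates match the
requested ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd
from scipy.special import expit

OBSERVED = "observed"
MISSING = "missing"
LEFT_CENSORED = "left_censored"
RIGHT_CENSORED = "right_censored"
STATUS_CODES = (OBSERVED, MISSING, LEFT_CENSORED, RIGHT_CENSORED)

__all__ = [
    "OBSERVED", "MISSING", "LEFT_CENSORED", "RIGHT_CENSORED", "STATUS_CODES",
    "IncompletenessConfig", "IncompleteResponse",
    "apply_censoring", "apply_missingness", "corrupt", "condition_grid",
]


@dataclass
class IncompletenessConfig:
    """One cell of the incomplete-data grid."""

    miss_rate: float = 0.0
    cens_rate: float = 0.0
    miss_mechanism: str = "MAR"        # MCAR | MAR | MNAR
    cens_side: str = "right"           # right | left | both
    miss_covariate: str = "AoA"
    trim_sd: float | None = None       # alternative outlier-trimming rule
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.miss_rate < 1 and 0 <= self.cens_rate < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.miss_rate + self.cens_rate >= 1:
            raise ValueError("miss_rate + cens_rate must be < 1")
        if self.miss_mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ValueError(f"unknown missingness mechanism {self.miss_mechanism!r}")
        if self.cens_side not in ("right", "left", "both"):
            raise ValueError(f"unknown censoring side {self.cens_side!r}")


@dataclass
class IncompleteResponse:
    """Response vector plus per-row observation status.

    ``y`` holds the working values: the original value at observed rows, the
    censoring threshold at censored rows (the value is known only up to that
    bound) and NaN at missing rows.  ``provenance`` retains the true
    pre-corruption vector for synthetic data (held out from fitters; test-only).
    """

    y: np.ndarray
    status: np.ndarray
    threshold: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.status = np.asarray(self.status, dtype=object)
        self.threshold = np.asarray(self.threshold, dtype=float)
        bad = set(self.status) - set(STATUS_CODES)
        if bad:
            raise ValueError(f"unknown status codes: {bad}")
        cens = np.isin(self.status, (LEFT_CENSORED, RIGHT_CENSORED))
        if not np.isfinite(self.threshold[cens]).all():
            raise ValueError("censored rows must carry a finite threshold")
        if np.isfinite(self.threshold[~cens]).any():
            raise ValueError("only censored rows may carry a threshold")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def observed_mask(self) -> np.ndarray:
        return self.status == OBSERVED

    @property
    def missing_mask(self) -> np.ndarray:
        return self.status == MISSING

    @property
    def right_censored_mask(self) -> np.ndarray:
        return self.status == RIGHT_CENSORED

    @property
    def left_censored_mask(self) -> np.ndarray:
        return self.status == LEFT_CENSORED

    @property
    def censored_mask(self) -> np.ndarray:
        return self.left_censored_mask | self.right_censored_mask

    @property
    def unobserved_mask(self) -> np.ndarray:
        return ~self.observed_mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "y": self.y, "status": self.status, "threshold": self.threshold,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncompleteResponse":
        return cls(
            y=df["y"].to_numpy(dtype=float),
            status=df["status"].to_numpy(dtype=object),
            threshold=df["threshold"].to_numpy(dtype=float),
        )

    @classmethod
    def fully_observed(cls, y) -> "IncompleteResponse":
        y = np.asarray(y, dtype=float)
        return cls(
            y=y.copy(),
            status=np.array([OBSERVED] * len(y), dtype=object),
            threshold=np.full(len(y), np.nan),
            provenance=y.copy(),
        )


def apply_censoring(
    y: np.ndarray,
    rate: float,
    side: str = "right",
    rng: np.random.Generator | None = None,
    trim_sd: float | None = None,
) -> IncompleteResponse:
    """Flag the extreme ``rate`` fraction of rows as censored at the empirical
    quantile threshold; flagged values are replaced by the threshold.

    Ties at the threshold are broken by row order (stable sort), so the
    achieved count equals round(rate * n) exactly.  ``side='both'`` splits the
    rate equally between tails.  ``trim_sd`` switches to the alternative
    outlier-trimming rule (rows beyond ``trim_sd`` SDs of the mean are
    right/left censored at those cut points) and ignores ``rate``.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    resp = IncompleteResponse.fully_observed(y)
    if trim_sd is not None:
        mu, sd = y.mean(), y.std()
        hi, lo = mu + trim_sd * sd, mu - trim_sd * sd
        _flag(resp, np.flatnonzero(y > hi), RIGHT_CENSORED, hi)
        _flag(resp, np.flatnonzero(y < lo), LEFT_CENSORED, lo)
        return resp
    if rate == 0:
        return resp

    def tail_idx(count, right):
        order = np.argsort(-y if right else y, kind="stable")
        return order[:count]

    if side == "both":
        n_each = int(round(rate * n / 2))
        counts = {"right": n_each, "left": n_each}
    else:
        counts = {side: int(round(rate * n))}
    for sd_side, count in counts.items():
        if count == 0:
            continue
        if count >= n:
            raise ValueError("censoring rate flags every row")
        idx = tail_idx(count, sd_side == "right")
        t = y[idx].min() if sd_side == "right" else y[idx].max()
        _flag(resp, idx, RIGHT_CENSORED if sd_side == "right" else LEFT_CENSORED, t)
    return resp


def _flag(resp: IncompleteResponse, idx, code, t):
    resp.status[idx] = code
    resp.threshold[idx] = t
    resp.y[idx] = t


def _calibrate_intercept(x_std: np.ndarray, target: float) -> float:
    """Bisection for a in mean(expit(a + x_std)) = target, to 1e-4."""
    lo, hi = -40.0, 40.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        r = expit(mid + x_std).mean()
        if abs(r - target) < 1e-4:
            return mid
        if r < target:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("intercept calibration did not converge in 100 bisection steps")


def apply_missingness(
    resp: IncompleteResponse | np.ndarray,
    covariates: pd.DataFrame | None,
    config: IncompletenessConfig,
    rng: np.random.Generator,
) -> IncompleteResponse:
    """Mask rows as missing among the currently observed ones.

    MCAR draws i.i.d. Bernoulli masks; MAR makes the masking probability
    logistic in the chosen observed covariate (slope 1 per covariate SD,
    intercept calibrated so the expected count is ``miss_rate * n``); MNAR uses
    the same logistic form driven by the true response.
    """
    if not isinstance(resp, IncompleteResponse):
        resp = IncompleteResponse.fully_observed(resp)
    rate = config.miss_rate
    if rate == 0:
        return resp
    eligible = np.flatnonzero(resp.observed_mask)
    if len(eligible) == 0:
        raise ValueError("no observed rows left to mask")
    # expected count is rate * n of all rows, achieved among eligible rows
    target = rate * resp.n / len(eligible)
    if target >= 1:
        raise ValueError("missingness rate exhausts the observed rows")
    if config.miss_mechanism == "MCAR":
        p = np.full(len(eligible), target)
    else:
        if config.miss_mechanism == "MAR":
            if covariates is None or config.miss_covariate not in covariates:
                raise ValueError(
                    "MAR requires a fully observed covariate "
                    f"({config.miss_covariate!r} not available)"
                )
            x = covariates[config.miss_covariate].to_numpy(dtype=float)[eligible]
        else:  # MNAR: driven by the (true) response value itself
            base = resp.provenance if resp.provenance is not None else resp.y
            x = base[eligible]
        x_std = (x - x.mean()) / max(x.std(), 1e-12)
        a = _calibrate_intercept(x_std, target)
        p = expit(a + x_std)
    mask = eligible[rng.random(len(eligible)) < p]
    resp.status[mask] = MISSING
    resp.y[mask] = np.nan
    return resp


def corrupt(
    y: np.ndarray,
    covariates: pd.DataFrame | None,
    config: IncompletenessConfig,
) -> IncompleteResponse:
    """Apply one grid condition: censoring first, then missingness."""
    rng = np.random.default_rng(config.seed)
    resp = apply_censoring(y, config.cens_rate, config.cens_side, rng,
                           trim_sd=config.trim_sd)
    return apply_missingness(resp, covariates, config, rng)


def condition_grid(
    miss_rates=(0.0, 0.05, 0.10, 0.20),
    cens_rates=(0.0, 0.05, 0.10, 0.20),
    base_seed: int = 0,
    **kwargs,
) -> list[IncompletenessConfig]:
    """Cartesian product of rates (missingness outer, censoring inner), each
    condition carrying a deterministically derived child seed."""
    if not len(miss_rates) or not len(cens_rates):
        raise ValueError("rate lists must be nonempty")
    configs = []
    for idx, (m, c) in enumerate(product(miss_rates, cens_rates)):
        child = int((base_seed * 100003 + 7919 * idx + 1) % (2**31))
        configs.append(IncompletenessConfig(
            miss_rate=m, cens_rate=c, seed=child, **kwargs
        ))
    return configs
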