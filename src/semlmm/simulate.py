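"""Synthetic picture-naming reaction-time data.

Emulates a psycholinguistic handwriting-latency experiment: S participants each
write the names of I drawings, giving S x I reaction times (RTs, ms).  Each
item carries an age-of-acquisition estimate (AoA, years) and a word-length
category (Lett_cat) from a balanced median split of simulated letter counts.
The generating model is

    RT = b0 + b1 AoA + b2 Lett_cat + b3 AoA*Lett_cat
         + S0_s + I0_i + S1_s AoA + e,

with participant intercepts S0 ~ N(0, sig1^2), item intercepts I0 ~ N(0,
sig2^2), participant AoA slopes S1 ~ N(0, sig3^2) and residuals e ~ N(0,
sig4^2).  The default truth is the complete-data reference vector
(1045, 93.16, -52.28, 2.80, 14.57, 230.8, 9.79, 282.0) and the default sizes
are 30 participants x 150 items = 4500 rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    INTERCEPT, ITEM, PARTICIPANT, ModelSpec, ParameterVector, VarianceComponents,
    build_design,
)

__all__ = [
    "REFERENCE_TRUTH", "ScenarioSpec", "SimulatedDataset", "standard_model_spec",
    "default_true_params", "generate_covariates", "simulate_responses",
    "simulate_dataset", "reference_scenario",
]

# canonical order: b0, b1, b2, b3, sig1, sig2, sig3, sig4
REFERENCE_TRUTH = (1045.0, 93.16, -52.28, 2.80, 14.57, 230.8, 9.79, 282.0)
_REFERENCE_SEED = 7


def standard_model_spec() -> ModelSpec:
    """RT ~ AoA * Lett_cat with crossed intercepts and an AoA participant slope."""
    return ModelSpec(
        covariate_names=["AoA", "Lett_cat"],
        include_fixed_interactions=True,
        random_slope_terms={PARTICIPANT: ["AoA"], ITEM: []},
    )


def default_true_params() -> ParameterVector:
    b0, b1, b2, b3, s1, s2, s3, s4 = REFERENCE_TRUTH
    return ParameterVector(
        delta=np.array([b0, b1, b2, b3]),
        vc=VarianceComponents(
            term_names_s=[INTERCEPT, "AoA"], sigma_s=np.array([s1, s3]),
            term_names_i=[INTERCEPT], sigma_i=np.array([s2]),
            sigma_e=s4,
        ),
    )


@dataclass
class ScenarioSpec:
    """Study design: sizes, covariate distributions and the generating truth.

    AoA is uniform over ``aoa_range`` (years, per item); letter counts are
    Poisson(``letter_mean`` - 2) + 2 per item.  AoA is centered at the item
    sample mean by default ("center"), keeping the year scale: the intercepts
    then describe RT at the mean acquisition age, which keeps the participant
    intercept SD and the AoA-slope SD separately identifiable without changing
    the units of the slopes.  ``aoa_scaling`` may also be "zscore" or "raw".
    """

    n_participants: int = 30
    n_items: int = 150
    aoa_range: tuple[float, float] = (1.0, 15.0)
    letter_mean: float = 7.0
    aoa_scaling: str = "center"
    true_params: ParameterVector = field(default_factory=default_true_params)
    seed: int = _REFERENCE_SEED

    def __post_init__(self):
        if self.n_participants < 2 or self.n_items < 2:
            raise ValueError("need at least 2 participants and 2 items")
        if self.aoa_scaling not in ("center", "zscore", "raw"):
            raise ValueError(f"unknown aoa_scaling {self.aoa_scaling!r}")


@dataclass
class SimulatedDataset:
    data: pd.DataFrame                 # participant, item, AoA, Lett_cat, RT
    truth: dict                        # generating random effects + residuals

    @property
    def n(self) -> int:
        return len(self.data)


def generate_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Item-level AoA and letter counts, median-split into Lett_cat, replicated
    across participants into long format.

    The split is balanced to within one item: items are ranked by letter count
    (ties broken by item index) and the upper half labelled long words.
    """
    aoa = rng.uniform(*spec.aoa_range, size=spec.n_items)
    letters = rng.poisson(max(spec.letter_mean - 2.0, 0.1), size=spec.n_items) + 2
    order = np.lexsort((np.arange(spec.n_items), letters))
    lett_cat = np.zeros(spec.n_items, dtype=int)
    lett_cat[order[spec.n_items // 2:]] = 1
    if spec.aoa_scaling == "center":
        aoa = aoa - aoa.mean()
    elif spec.aoa_scaling == "zscore":
        aoa = (aoa - aoa.mean()) / aoa.std()
    items = pd.DataFrame({
        "item": np.arange(1, spec.n_items + 1),
        "AoA": aoa,
        "letters": letters,
        "Lett_cat": lett_cat,
    })
    long = items.loc[items.index.repeat(spec.n_participants)].reset_index(drop=True)
    long.insert(0, "participant", np.tile(
        np.arange(1, spec.n_participants + 1), spec.n_items
    ))
    return long


def simulate_responses(
    table: pd.DataFrame,
    true_params: ParameterVector,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Draw random effects and residuals and assemble the response."""
    spec = standard_model_spec()
    design = build_design(spec, table)
    vc = true_params.vc
    S, I = design.n_s, design.n_i
    chol_s = np.linalg.cholesky(vc.factor_cov(PARTICIPANT))
    u_s = rng.standard_normal((S, len(vc.sigma_s))) @ chol_s.T
    u_i = rng.standard_normal((I, len(vc.sigma_i))) * vc.sigma_i
    e = rng.standard_normal(design.n) * vc.sigma_e
    rand = (
        (design.z_s * u_s[design.s_index]).sum(axis=1)
        + (design.z_i * u_i[design.i_index]).sum(axis=1)
    )
    rt = design.X @ true_params.delta + rand + e
    out = table.copy()
    out["RT"] = rt
    return SimulatedDataset(
        data=out,
        truth={"u_s": u_s, "u_i": u_i, "e": e, "params": true_params},
    )


def simulate_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Covariates + responses from the scenario's own seed."""
    rng = np.random.default_rng(spec.seed)
    table = generate_covariates(spec, rng)
    return simulate_responses(table, spec.true_params, rng)


def reference_scenario() -> tuple[SimulatedDataset, ParameterVector]:
    """The default 30 x 150 scenario at the documented seed, with its truth."""
    spec = ScenarioSpec()
    return simulate_dataset(spec), spec.true_params
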