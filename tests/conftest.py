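import numpy as np
import pandas as pd
import pytest

from semlmm import (
    ModelSpec, ScenarioSpec, build_design, simulate_dataset, standard_model_spec,
)
from semlmm.model import INTERCEPT, VarianceComponents


@pytest.fixture(scope="session")
def small_sim():
    """A 10 x 30 scenario (300 rows) shared by the fitter tests."""
    spec = ScenarioSpec(n_participants=10, n_items=30, seed=3)
    sim = simulate_dataset(spec)
    design = build_design(standard_model_spec(), sim.data)
    return spec, sim, design, sim.data["RT"].to_numpy()


def random_crossed_table(rng, S=3, I=4, n=None, p=2):
    """A random long table with two crossed grouping factors."""
    n = n or S * I
    df = pd.DataFrame({
        "participant": rng.integers(0, S, n),
        "item": rng.integers(0, I, n),
    })
    # make sure every level occurs
    df.loc[:S - 1, "participant"] = np.arange(S)
    df.loc[:I - 1, "item"] = np.arange(I)
    for j in range(p):
        df[f"x{j + 1}"] = rng.normal(size=n)
    return df


def random_vc(rng, term_names_s=(INTERCEPT, "x1"), term_names_i=(INTERCEPT,),
              rho=True):
    return VarianceComponents(
        term_names_s=list(term_names_s),
        sigma_s=rng.uniform(0.3, 3.0, len(term_names_s)),
        term_names_i=list(term_names_i),
        sigma_i=rng.uniform(0.3, 3.0, len(term_names_i)),
        rho_s=rng.uniform(-0.6, 0.6) if rho else 0.0,
        rho_i=rng.uniform(-0.6, 0.6) if rho else 0.0,
        sigma_e=rng.uniform(0.5, 2.0),
    )


def crossed_spec(p=2):
    return ModelSpec(
        covariate_names=[f"x{j + 1}" for j in range(p)],
        random_slope_terms={"participant": ["x1"], "item": []},
    )
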