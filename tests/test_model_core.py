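"""Model core: design expansion, variance assembly, Henderson solver, M-step."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from semlmm import (
    ModelSpec, ParameterVector, VarianceComponents,
    assemble_G, assemble_V, build_design, complete_data_mstep,
    expand_interactions, marginal_loglik, solve_henderson,
)
from semlmm.model import (
    INTERCEPT, ITEM, PARTICIPANT, DegenerateDrawWarning, marginal_covariance,
)
from conftest import crossed_spec, random_crossed_table, random_vc


# ---------------------------------------------------------------------------
# interaction expansion


@pytest.mark.parametrize("p,expected_k", [(1, 0), (2, 1), (3, 4), (4, 11)])
def test_full_interaction_count(p, expected_k):
    spec = ModelSpec(covariate_names=[f"x{j}" for j in range(p)])
    terms = expand_interactions(spec)
    products = [t for t in terms if len(t) >= 2]
    assert len(products) == expected_k == 2**p - p - 1
    assert terms[:p] == [(f"x{j}",) for j in range(p)]


def test_expand_interactions_p2_order():
    spec = ModelSpec(covariate_names=["x1", "x2"])
    assert expand_interactions(spec) == [("x1",), ("x2",), ("x1", "x2")]


def test_expand_interactions_errors():
    with pytest.raises(ValueError):
        ModelSpec(covariate_names=[])
    with pytest.raises(ValueError):
        ModelSpec(covariate_names=["a", "a"])
    spec = ModelSpec(covariate_names=["a", "b"],
                     include_fixed_interactions=[("a", "zzz")])
    with pytest.raises(ValueError):
        expand_interactions(spec)


# ---------------------------------------------------------------------------
# design construction


def test_build_design_binary_interaction_column():
    df = pd.DataFrame({
        "x1": [0, 0, 1, 1], "x2": [0, 1, 0, 1],
        "participant": [1, 1, 2, 2], "item": [1, 2, 1, 2],
    })
    d = build_design(ModelSpec(covariate_names=["x1", "x2"]), df)
    assert d.X.shape == (4, 4)
    np.testing.assert_array_equal(d.X[:, 0], 1.0)
    np.testing.assert_array_equal(d.X[:, 3], d.X[:, 1] * d.X[:, 2])
    # 2 x 2 full factorial: each (s, i) pair exactly once
    pairs = set(zip(d.s_index, d.i_index))
    assert len(pairs) == 4 and d.n_s == d.n_i == 2


def test_build_design_errors_and_warnings():
    df = pd.DataFrame({"x1": [1.0, 2.0], "participant": [1, 2], "item": [1, 1]})
    with pytest.raises(ValueError):
        build_design(ModelSpec(covariate_names=["nope"]), df)
    with pytest.warns(UserWarning, match="constant"):
        build_design(ModelSpec(covariate_names=["x1"]), df)
    df_nan = df.assign(x1=[1.0, np.nan], item=[1, 2])
    with pytest.raises(ValueError, match="covariate"):
        build_design(ModelSpec(covariate_names=["x1"]), df_nan)


# ---------------------------------------------------------------------------
# variance assembly


def test_assemble_G_diagonal_when_uncorrelated():
    vc = VarianceComponents(
        term_names_s=[INTERCEPT, "x1"], sigma_s=[2.0, 3.0],
        term_names_i=[INTERCEPT, "x1"], sigma_i=[1.0, 4.0], sigma_e=1.0,
    )
    G = assemble_G(vc)
    np.testing.assert_allclose(G, np.diag([5.0, 25.0]))


def test_assemble_G_unit_sds_full_correlation():
    vc = VarianceComponents(
        term_names_s=[INTERCEPT, "x1"], sigma_s=[1.0, 1.0],
        term_names_i=[INTERCEPT, "x1"], sigma_i=[1.0, 1.0],
        rho_s=1.0, rho_i=1.0, sigma_e=1.0,
    )
    np.testing.assert_allclose(assemble_G(vc), [[2.0, 2.0], [2.0, 2.0]])


def test_assemble_G_psd_on_random_draws():
    rng = np.random.default_rng(42)
    for _ in range(100):
        G = assemble_G(random_vc(rng, term_names_i=(INTERCEPT, "x1")))
        assert np.linalg.eigvalsh(G).min() >= -1e-10
        np.testing.assert_allclose(G, G.T)


def test_assemble_G_invalid_inputs():
    with pytest.raises(ValueError):
        VarianceComponents(term_names_s=[INTERCEPT], sigma_s=[-1.0],
                           term_names_i=[INTERCEPT], sigma_i=[1.0], sigma_e=1.0)
    with pytest.raises(ValueError):
        VarianceComponents(term_names_s=[INTERCEPT], sigma_s=[1.0],
                           term_names_i=[INTERCEPT], sigma_i=[1.0],
                           rho_s=1.5, sigma_e=1.0)


def test_assemble_V_limits():
    vc0 = VarianceComponents(term_names_s=[INTERCEPT], sigma_s=[0.0],
                             term_names_i=[INTERCEPT], sigma_i=[0.0], sigma_e=2.0)
    Z = np.ones((5, 1))
    np.testing.assert_allclose(assemble_V(Z, vc0), 4.0 * np.eye(5))
    vc = VarianceComponents(term_names_s=[INTERCEPT, "x1"], sigma_s=[1.0, 2.0],
                            term_names_i=[INTERCEPT, "x1"], sigma_i=[0.5, 0.5],
                            rho_s=0.3, sigma_e=0.0)
    np.testing.assert_allclose(assemble_V(np.eye(2), vc), assemble_G(vc))
    with pytest.raises(ValueError):
        assemble_V(np.ones((3, 3)), vc0)


def test_assemble_V_matches_triple_loop_oracle():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(12, 2))
    vc = random_vc(rng, term_names_i=(INTERCEPT, "x1"))
    G = assemble_G(vc)
    expected = vc.sigma_e**2 * np.eye(12)
    for j in range(2):
        for l in range(2):
            expected += G[j, l] * np.outer(Z[:, j], Z[:, l])
    np.testing.assert_allclose(assemble_V(Z, vc), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Henderson solver


def test_henderson_reduces_to_ols_when_random_sds_vanish():
    rng = np.random.default_rng(5)
    df = random_crossed_table(rng, n=40)
    spec = crossed_spec()
    d = build_design(spec, df)
    y = rng.normal(size=40)
    vc = VarianceComponents(
        term_names_s=[INTERCEPT, "x1"], sigma_s=[1e-9, 1e-9],
        term_names_i=[INTERCEPT], sigma_i=[1e-9], sigma_e=1.0,
    )
    fit = solve_henderson(d, y, vc)
    ols, *_ = np.linalg.lstsq(d.X, y, rcond=None)
    np.testing.assert_allclose(fit.delta_hat, ols, atol=1e-6)


def test_henderson_oneway_blup_shrinkage():
    # balanced one-way layout: u_s = (m su^2 / (m su^2 + se^2)) * mean residual
    rng = np.random.default_rng(8)
    S, m = 6, 10
    df = pd.DataFrame({
        "participant": np.repeat(np.arange(S), m),
        "item": np.arange(S * m),          # distinct item per row, SD ~ 0
        "x1": rng.normal(size=S * m),
    })
    spec = ModelSpec(covariate_names=["x1"],
                     random_slope_terms={"participant": [], "item": []})
    d = build_design(spec, df)
    su, se = 2.0, 1.5
    y = rng.normal(size=S * m)
    vc = VarianceComponents(term_names_s=[INTERCEPT], sigma_s=[su],
                            term_names_i=[INTERCEPT], sigma_i=[1e-9], sigma_e=se)
    fit = solve_henderson(d, y, vc)
    resid = y - d.X @ fit.delta_hat
    shrink = m * su**2 / (m * su**2 + se**2)
    expected = shrink * np.array([resid[df.participant == s].mean() for s in range(S)])
    np.testing.assert_allclose(fit.u_hat[PARTICIPANT][:, 0], expected, atol=1e-8)


def test_henderson_matches_explicit_gls_once():
    rng = np.random.default_rng(11)
    df = random_crossed_table(rng, S=4, I=5, n=30)
    d = build_design(crossed_spec(), df)
    vc = random_vc(rng)
    y = rng.normal(size=30)
    fit = solve_henderson(d, y, vc)
    V = marginal_covariance(d, vc)
    Vi = np.linalg.inv(V)
    delta_gls = np.linalg.solve(d.X.T @ Vi @ d.X, d.X.T @ Vi @ y)
    np.testing.assert_allclose(fit.delta_hat, delta_gls, atol=1e-8)
    # fitted + residuals reproduces the response exactly
    np.testing.assert_allclose(fit.fitted + fit.residuals, y, atol=1e-10)


def test_henderson_equals_gls_on_many_random_instances():
    rng = np.random.default_rng(2024)
    worst = 0.0
    for _ in range(200):
        S, I = rng.integers(2, 5), rng.integers(2, 5)
        n = int(rng.integers(15, 30))
        df = random_crossed_table(rng, S=S, I=I, n=n)
        d = build_design(crossed_spec(), df)
        vc = random_vc(rng)
        y = rng.normal(size=n)
        fit = solve_henderson(d, y, vc)
        Vi = np.linalg.inv(marginal_covariance(d, vc))
        delta_gls = np.linalg.solve(d.X.T @ Vi @ d.X, d.X.T @ Vi @ y)
        worst = max(worst, float(np.abs(fit.delta_hat - delta_gls).max()))
    assert worst < 1e-6


def test_specific_cases_reduce_to_ols():
    rng = np.random.default_rng(21)
    df = random_crossed_table(rng, n=50)
    y = rng.normal(size=50)
    zero_vc = lambda terms_s: VarianceComponents(
        term_names_s=terms_s, sigma_s=[1e-9] * len(terms_s),
        term_names_i=[INTERCEPT], sigma_i=[1e-9], sigma_e=1.0,
    )
    # fixed-fixed interactions only (random part zero) -> OLS with interactions
    spec1 = ModelSpec(covariate_names=["x1", "x2"])
    d1 = build_design(spec1, df)
    fit1 = solve_henderson(d1, y, zero_vc([INTERCEPT]))
    ols1, *_ = np.linalg.lstsq(d1.X, y, rcond=None)
    np.testing.assert_allclose(fit1.delta_hat, ols1, atol=1e-6)
    assert d1.X.shape[1] == 4
    # no interactions at all -> plain OLS
    spec2 = ModelSpec(covariate_names=["x1", "x2"], include_fixed_interactions=False)
    d2 = build_design(spec2, df)
    fit2 = solve_henderson(d2, y, zero_vc([INTERCEPT]))
    ols2, *_ = np.linalg.lstsq(d2.X, y, rcond=None)
    np.testing.assert_allclose(fit2.delta_hat, ols2, atol=1e-6)
    assert d2.X.shape[1] == 3


# ---------------------------------------------------------------------------
# marginal log-likelihood


def test_loglik_single_point():
    df = pd.DataFrame({"x1": [0.0], "participant": [1], "item": [1]})
    with pytest.warns(UserWarning):
        d = build_design(ModelSpec(covariate_names=["x1"]), df)
    vc = VarianceComponents(term_names_s=[INTERCEPT], sigma_s=[0.0],
                            term_names_i=[INTERCEPT], sigma_i=[0.0], sigma_e=1.0)
    pv = ParameterVector(delta=[2.5, 0.0], vc=vc)
    ll = marginal_loglik(d, np.array([2.5]), pv)
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)


def test_loglik_matches_dense_mvn_oracle():
    rng = np.random.default_rng(31)
    df = random_crossed_table(rng, S=3, I=3, n=10)
    d = build_design(crossed_spec(), df)
    vc = random_vc(rng)
    delta = rng.normal(size=4)
    pv = ParameterVector(delta=delta, vc=vc)
    y = rng.normal(size=10)
    dense = multivariate_normal.logpdf(y, mean=d.X @ delta,
                                       cov=marginal_covariance(d, vc))
    assert marginal_loglik(d, y, pv) == pytest.approx(dense, rel=1e-9)


def test_loglik_invariant_under_joint_row_permutation():
    rng = np.random.default_rng(32)
    df = random_crossed_table(rng, S=3, I=3, n=12)
    d = build_design(crossed_spec(), df)
    vc = random_vc(rng)
    pv = ParameterVector(delta=rng.normal(size=4), vc=vc)
    y = rng.normal(size=12)
    perm = rng.permutation(12)
    d2 = build_design(crossed_spec(), df.iloc[perm].reset_index(drop=True))
    assert marginal_loglik(d, y, pv) == pytest.approx(
        marginal_loglik(d2, y[perm], pv), rel=1e-10)


# ---------------------------------------------------------------------------
# complete-data M-step


def _toy_design(rng, S=4, I=4, n=24):
    df = random_crossed_table(rng, S=S, I=I, n=n)
    return build_design(crossed_spec(), df)


def test_mstep_zero_draws_warns_and_returns_zero_sds():
    rng = np.random.default_rng(41)
    d = _toy_design(rng)
    y = rng.normal(size=d.n)
    u = {PARTICIPANT: np.zeros((d.n_s, 2)), ITEM: np.zeros((d.n_i, 1))}
    with pytest.warns(DegenerateDrawWarning):
        pv = complete_data_mstep(d, y, u, np.zeros(d.n))
    assert pv.vc.sigma_e <= 1e-8
    assert (pv.vc.sigma_s == 0).all()


def test_mstep_recovers_sd_from_ssq():
    rng = np.random.default_rng(43)
    d = _toy_design(rng)
    y = rng.normal(size=d.n)
    S = d.n_s
    u_col = np.full(S, 2.0)   # SSQ = 4S -> sd = 2
    u = {PARTICIPANT: np.column_stack([u_col, np.zeros(S)]),
         ITEM: rng.normal(size=(d.n_i, 1))}
    pv = complete_data_mstep(d, y, u, rng.normal(size=d.n))
    assert pv.vc.sigma_s[0] == pytest.approx(2.0)


def test_mstep_moment_recovery_within_monte_carlo_error():
    rng = np.random.default_rng(44)
    S = I = 200
    n = 6000
    df = random_crossed_table(rng, S=S, I=I, n=n)
    d = build_design(crossed_spec(), df)
    sig_s, sig_i, sig_e = 3.0, 5.0, 2.0
    draw_rng = np.random.default_rng(0)
    u = {PARTICIPANT: np.column_stack([draw_rng.normal(0, sig_s, S),
                                       draw_rng.normal(0, 1.0, S)]),
         ITEM: draw_rng.normal(0, sig_i, (I, 1))}
    e = draw_rng.normal(0, sig_e, n)
    y = rng.normal(size=n)
    pv = complete_data_mstep(d, y, u, e)
    assert abs(pv.vc.sigma_s[0] - sig_s) < 3 * sig_s / np.sqrt(2 * S)
    assert abs(pv.vc.sigma_i[0] - sig_i) < 3 * sig_i / np.sqrt(2 * I)
    assert abs(pv.vc.sigma_e - sig_e) < 3 * sig_e / np.sqrt(2 * n)


def test_mstep_is_exact_maximizer_on_one_parameter_slice():
    # diagonal case: the complete-data likelihood over sigma_S is maximized at
    # the root-mean-square of the draws
    rng = np.random.default_rng(45)
    u = rng.normal(0, 2.0, 50)
    sd_hat = np.sqrt(np.mean(u**2))
    grid = np.linspace(0.5 * sd_hat, 2.0 * sd_hat, 401)
    ll = [-0.5 * np.sum(u**2) / s**2 - len(u) * np.log(s) for s in grid]
    assert abs(grid[int(np.argmax(ll))] - sd_hat) < (grid[1] - grid[0])


# ---------------------------------------------------------------------------
# serialization


def test_parameter_vector_json_roundtrip():
    vc = VarianceComponents(term_names_s=[INTERCEPT, "AoA"], sigma_s=[14.57, 9.79],
                            term_names_i=[INTERCEPT], sigma_i=[230.8],
                            rho_s=0.2, sigma_e=282.0)
    pv = ParameterVector(delta=[1045.0, 93.16, -52.28, 2.80], vc=vc)
    back = ParameterVector.from_json(pv.to_json())
    np.testing.assert_array_equal(back.canonical(), pv.canonical())
    assert back.vc.rho_s == pv.vc.rho_s
    assert pv.canonical_names() == ["b0", "b1", "b2", "b3",
                                    "sig1", "sig2", "sig3", "sig4"]
    # canonical values round-trip through from_canonical
    rebuilt = ParameterVector.from_canonical(pv.canonical(), pv)
    np.testing.assert_allclose(rebuilt.canonical(), pv.canonical())


def test_model_spec_json_roundtrip():
    spec = ModelSpec(covariate_names=["AoA", "Lett_cat"],
                     random_slope_terms={"participant": ["AoA"], "item": []})
    back = ModelSpec.from_json(spec.to_json())
    assert back == spec
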