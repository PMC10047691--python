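"""Model core for linear mixed-effects models with two crossed grouping factors.

The model is

    y = X delta + Z u + e,        u ~ N(0, G),   e ~ N(0, sigma_e^2 I_n),

where X carries an intercept, p base covariates and their fixed-fixed
interaction products (all products of order >= 2; with every interaction
included there are k = 2^p - p - 1 of them), and the random part has, for each
grouping factor (participants and items), a random intercept plus optional
random slopes on fixed-effect columns.  Fixed effects and BLUPs are obtained
from Henderson's mixed-model equations; the marginal Gaussian likelihood is
evaluated through the Woodbury identity on the low-rank random-effect
structure, so no n x n matrix is ever formed for real problem sizes.
"""

from __future__ import annotations

import itertools
import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "VarianceComponents",
    "ParameterVector",
    "MixedModelFit",
    "expand_interactions",
    "build_design",
    "assemble_G",
    "assemble_V",
    "solve_henderson",
    "complete_data_mstep",
    "marginal_loglik",
    "ml_fit",
    "load_long_csv",
    "DegenerateDrawWarning",
]

SIGMA_E_FLOOR = 1e-8
_SD_FLOOR = 1e-10
PARTICIPANT = "participant"
ITEM = "item"
INTERCEPT = "1"


class DegenerateDrawWarning(UserWarning):
    """Raised when an M-step receives degenerate (e.g. all-zero) draws."""


# ---------------------------------------------------------------------------
# specification and design


@dataclass
class ModelSpec:
    """Declarative description of the fixed and random structure.

    Parameters
    ----------
    covariate_names
        The p base fixed-effect covariates, in the order they enter X.
    include_fixed_interactions
        True for every product of order >= 2 (k = 2^p - p - 1 columns),
        False for none, or an explicit list of tuples of covariate names.
    random_slope_terms
        Mapping from grouping factor role ("participant" / "item") to the
        fixed-effect columns that get a random slope for that factor.  Random
        intercepts for both factors are always included.
    grouping_factors
        Column names of the two grouping factors, (participants, items).
    estimate_rho
        Whether intercept/slope correlations are free parameters in ML fits.
    """

    covariate_names: list[str]
    include_fixed_interactions: bool | list[tuple[str, ...]] = True
    random_slope_terms: dict[str, list[str]] = field(
        default_factory=lambda: {PARTICIPANT: [], ITEM: []}
    )
    grouping_factors: tuple[str, str] = (PARTICIPANT, ITEM)
    estimate_rho: bool = False

    def __post_init__(self):
        if not self.covariate_names:
            raise ValueError("at least one covariate is required")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("duplicate covariate names")
        if len(self.grouping_factors) != 2:
            raise ValueError("exactly two grouping factors are required")
        for role in (PARTICIPANT, ITEM):
            self.random_slope_terms.setdefault(role, [])

    def factor_terms(self, role: str) -> list[str]:
        """Random-effect term names for one factor (intercept first)."""
        return [INTERCEPT] + list(self.random_slope_terms[role])

    def to_json(self) -> str:
        d = asdict(self)
        d["grouping_factors"] = list(d["grouping_factors"])
        if isinstance(d["include_fixed_interactions"], list):
            d["include_fixed_interactions"] = [
                list(t) for t in d["include_fixed_interactions"]
            ]
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["grouping_factors"] = tuple(d["grouping_factors"])
        if isinstance(d["include_fixed_interactions"], list):
            d["include_fixed_interactions"] = [
                tuple(t) for t in d["include_fixed_interactions"]
            ]
        return cls(**d)


def expand_interactions(spec: ModelSpec) -> list[tuple[str, ...]]:
    """Ordered fixed-effect column descriptors: base columns, then products.

    Product terms are every subset of the covariates of order >= 2, ordered by
    interaction order and then lexicographically by covariate position, so the
    expansion is deterministic.  With all interactions requested the number of
    product terms is 2^p - p - 1.
    """
    names = spec.covariate_names
    base = [(nm,) for nm in names]
    if spec.include_fixed_interactions is False:
        return base
    if spec.include_fixed_interactions is True:
        prods = [
            tuple(names[i] for i in combo)
            for r in range(2, len(names) + 1)
            for combo in itertools.combinations(range(len(names)), r)
        ]
    else:
        prods = []
        for term in spec.include_fixed_interactions:
            if len(term) < 2:
                raise ValueError(f"interaction term {term} has order < 2")
            unknown = set(term) - set(names)
            if unknown:
                raise ValueError(f"unknown covariates in interaction: {unknown}")
            prods.append(tuple(term))
    return base + prods


def _column_name(term: tuple[str, ...]) -> str:
    return ":".join(term)


@dataclass
class DesignMatrices:
    """Realized design: fixed-effect matrix, random-term columns, group codes."""

    X: np.ndarray                    # n x (1 + p + k), column 0 all ones
    x_names: list[str]
    s_index: np.ndarray              # dense participant codes, 0..S-1
    i_index: np.ndarray              # dense item codes, 0..I-1
    n_s: int
    n_i: int
    z_s: np.ndarray                  # n x t_S covariate columns of the participant terms
    z_i: np.ndarray                  # n x t_I
    term_names_s: list[str]
    term_names_i: list[str]
    labels_s: np.ndarray
    labels_i: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.n_s * len(self.term_names_s) + self.n_i * len(self.term_names_i)

    def incidence(self) -> sparse.csr_matrix:
        """Expanded n x q random-effect incidence matrix Z~.

        Columns are participant-major blocks (all terms of participant 0,
        participant 1, ...) followed by item blocks.
        """
        if "Z" not in self._cache:
            t_s, t_i = len(self.term_names_s), len(self.term_names_i)
            n = self.n
            rows = np.repeat(np.arange(n), t_s + t_i)
            cols = np.empty((n, t_s + t_i), dtype=np.int64)
            vals = np.empty((n, t_s + t_i))
            for j in range(t_s):
                cols[:, j] = self.s_index * t_s + j
                vals[:, j] = self.z_s[:, j]
            off = self.n_s * t_s
            for j in range(t_i):
                cols[:, t_s + j] = off + self.i_index * t_i + j
                vals[:, t_s + j] = self.z_i[:, j]
            Z = sparse.csr_matrix(
                (vals.ravel(), (rows, cols.ravel())), shape=(n, self.q)
            )
            self._cache["Z"] = Z
        return self._cache["Z"]

    def crossprods(self) -> dict:
        """Cached X'X, Z~'X, Z~'Z~ (dense); the only O(n) work per design."""
        if "xp" not in self._cache:
            Z = self.incidence()
            self._cache["xp"] = {
                "XtX": self.X.T @ self.X,
                "ZtX": np.asarray((Z.T @ self.X)),
                "ZtZ": np.asarray((Z.T @ Z).todense()),
            }
        return self._cache["xp"]


def build_design(spec: ModelSpec, data: pd.DataFrame) -> DesignMatrices:
    """Expand a long-format table into design matrices with dense group codes."""
    missing = [c for c in spec.covariate_names if c not in data.columns]
    if missing:
        raise ValueError(f"unknown covariates not in table: {missing}")
    for g in spec.grouping_factors:
        if g not in data.columns:
            raise ValueError(f"grouping column {g!r} not in table")
    cov = data[spec.covariate_names].to_numpy(dtype=float)
    if not np.isfinite(cov).all():
        raise ValueError("missing or non-finite covariate values")

    terms = expand_interactions(spec)
    n = len(data)
    X = np.ones((n, 1 + len(terms)))
    x_names = ["Intercept"]
    col_of = {}
    for j, term in enumerate(terms, start=1):
        col = np.ones(n)
        for nm in term:
            col = col * data[nm].to_numpy(dtype=float)
        X[:, j] = col
        nm = _column_name(term)
        x_names.append(nm)
        col_of[nm] = j

    s_codes, s_labels = pd.factorize(data[spec.grouping_factors[0]], sort=True)
    i_codes, i_labels = pd.factorize(data[spec.grouping_factors[1]], sort=True)
    for codes, g in ((s_codes, spec.grouping_factors[0]), (i_codes, spec.grouping_factors[1])):
        if len(np.unique(codes)) < 2:
            warnings.warn(f"grouping column {g!r} is constant over all rows")

    def z_matrix(role: str) -> tuple[np.ndarray, list[str]]:
        names = spec.factor_terms(role)
        cols = []
        for nm in names:
            if nm == INTERCEPT:
                cols.append(np.ones(n))
            elif nm in col_of:
                cols.append(X[:, col_of[nm]])
            else:
                raise ValueError(
                    f"random-slope term {nm!r} is not a fixed-effect column"
                )
        return np.column_stack(cols), names

    z_s, tn_s = z_matrix(PARTICIPANT)
    z_i, tn_i = z_matrix(ITEM)
    return DesignMatrices(
        X=X, x_names=x_names,
        s_index=np.asarray(s_codes, dtype=np.int64),
        i_index=np.asarray(i_codes, dtype=np.int64),
        n_s=len(s_labels), n_i=len(i_labels),
        z_s=z_s, z_i=z_i, term_names_s=tn_s, term_names_i=tn_i,
        labels_s=np.asarray(s_labels), labels_i=np.asarray(i_labels),
    )


# ---------------------------------------------------------------------------
# variance components


@dataclass
class VarianceComponents:
    """Per-factor random-effect SDs, within-factor correlations, residual SD.

    ``term_names_s`` / ``term_names_i`` list the active random terms per factor
    (intercept first); ``rho_s`` / ``rho_i`` are the common within-factor
    correlations between term pairs.
    """

    term_names_s: list[str]
    sigma_s: np.ndarray
    term_names_i: list[str]
    sigma_i: np.ndarray
    rho_s: float = 0.0
    rho_i: float = 0.0
    sigma_e: float = 1.0

    def __post_init__(self):
        self.sigma_s = np.atleast_1d(np.asarray(self.sigma_s, dtype=float))
        self.sigma_i = np.atleast_1d(np.asarray(self.sigma_i, dtype=float))
        if len(self.sigma_s) != len(self.term_names_s):
            raise ValueError("sigma_s length does not match term_names_s")
        if len(self.sigma_i) != len(self.term_names_i):
            raise ValueError("sigma_i length does not match term_names_i")
        if (self.sigma_s < 0).any() or (self.sigma_i < 0).any() or self.sigma_e < 0:
            raise ValueError("negative standard deviation")
        if abs(self.rho_s) > 1 or abs(self.rho_i) > 1:
            raise ValueError("|rho| > 1")

    def factor_cov(self, role: str) -> np.ndarray:
        sd = self.sigma_s if role == PARTICIPANT else self.sigma_i
        rho = self.rho_s if role == PARTICIPANT else self.rho_i
        sd = np.maximum(sd, _SD_FLOOR)
        C = np.outer(sd, sd)
        off = np.ones((len(sd), len(sd))) * rho
        np.fill_diagonal(off, 1.0)
        return C * off

    def union_terms(self) -> list[str]:
        out = list(self.term_names_s)
        out.extend(t for t in self.term_names_i if t not in out)
        return out


def assemble_G(vc: VarianceComponents) -> np.ndarray:
    """Aligned-terms covariance of the summed random coefficients u_j = S_j + I_j.

    Diagonal sigma_{j,S}^2 + sigma_{j,I}^2; off-diagonal
    rho_S sigma_{j,S} sigma_{l,S} + rho_I sigma_{j,I} sigma_{l,I}.  Terms a
    factor does not carry contribute zero.
    """
    terms = vc.union_terms()
    sd_s = np.array([
        vc.sigma_s[vc.term_names_s.index(t)] if t in vc.term_names_s else 0.0
        for t in terms
    ])
    sd_i = np.array([
        vc.sigma_i[vc.term_names_i.index(t)] if t in vc.term_names_i else 0.0
        for t in terms
    ])
    G = vc.rho_s * np.outer(sd_s, sd_s) + vc.rho_i * np.outer(sd_i, sd_i)
    np.fill_diagonal(G, sd_s**2 + sd_i**2)
    return G


def assemble_V(design_or_z, vc: VarianceComponents) -> np.ndarray:
    """Dense term-level covariance V = Z G Z' + sigma_e^2 I.

    ``design_or_z`` is either a DesignMatrices (the term columns are built from
    the union of the factor terms) or an explicit n x T column matrix aligned
    with ``assemble_G(vc)``.  This is the compact single-observation-structure
    form; the per-level expanded covariance used by the solver is exposed
    through :func:`marginal_covariance`.
    """
    G = assemble_G(vc)
    if isinstance(design_or_z, DesignMatrices):
        d = design_or_z
        cols = {}
        for nm, j in zip(d.term_names_s, range(len(d.term_names_s))):
            cols[nm] = d.z_s[:, j]
        for nm, j in zip(d.term_names_i, range(len(d.term_names_i))):
            cols.setdefault(nm, d.z_i[:, j])
        Z = np.column_stack([cols[t] for t in vc.union_terms()])
    else:
        Z = np.asarray(design_or_z, dtype=float)
    if Z.shape[1] != G.shape[0]:
        raise ValueError("dimension mismatch between Z columns and G")
    return Z @ G @ Z.T + vc.sigma_e**2 * np.eye(Z.shape[0])


def marginal_covariance(design: DesignMatrices, vc: VarianceComponents) -> np.ndarray:
    """Dense n x n marginal covariance Z~ G~ Z~' + sigma_e^2 I (small n only)."""
    Z = design.incidence().toarray()
    Gt = _big_G(design, vc)
    return Z @ Gt @ Z.T + vc.sigma_e**2 * np.eye(design.n)


def _big_G(design: DesignMatrices, vc: VarianceComponents) -> np.ndarray:
    return np.block([
        [np.kron(np.eye(design.n_s), vc.factor_cov(PARTICIPANT)),
         np.zeros((design.n_s * len(design.term_names_s),
                   design.n_i * len(design.term_names_i)))],
        [np.zeros((design.n_i * len(design.term_names_i),
                   design.n_s * len(design.term_names_s))),
         np.kron(np.eye(design.n_i), vc.factor_cov(ITEM))],
    ])


def _ginv_logdet(design: DesignMatrices, vc: VarianceComponents):
    """Block-diagonal G~^{-1} (dense q x q) and log|G~|."""
    cov_s = vc.factor_cov(PARTICIPANT)
    cov_i = vc.factor_cov(ITEM)
    sign_s, ld_s = np.linalg.slogdet(cov_s)
    sign_i, ld_i = np.linalg.slogdet(cov_i)
    if sign_s <= 0 or sign_i <= 0:
        raise np.linalg.LinAlgError("factor covariance not positive definite")
    inv_s = np.linalg.inv(cov_s)
    inv_i = np.linalg.inv(cov_i)
    q_s = design.n_s * len(design.term_names_s)
    q_i = design.n_i * len(design.term_names_i)
    Ginv = np.zeros((q_s + q_i, q_s + q_i))
    Ginv[:q_s, :q_s] = np.kron(np.eye(design.n_s), inv_s)
    Ginv[q_s:, q_s:] = np.kron(np.eye(design.n_i), inv_i)
    logdet = design.n_s * ld_s + design.n_i * ld_i
    return Ginv, logdet


# ---------------------------------------------------------------------------
# parameter vector


@dataclass
class ParameterVector:
    """Fixed effects plus variance components; the object all fitters return.

    The canonical report ordering is (delta_0, ..., delta_{p+k},
    sd participant intercept, sd item intercept, participant slope SDs,
    item slope SDs, sd residual) — for the standard two-covariate model with
    one participant AoA slope that is (b0, b1, b2, b3, sig1, sig2, sig3, sig4).
    """

    delta: np.ndarray
    vc: VarianceComponents

    def __post_init__(self):
        self.delta = np.atleast_1d(np.asarray(self.delta, dtype=float))

    def canonical(self) -> np.ndarray:
        return np.concatenate([
            self.delta,
            [self.vc.sigma_s[0], self.vc.sigma_i[0]],
            self.vc.sigma_s[1:], self.vc.sigma_i[1:],
            [self.vc.sigma_e],
        ])

    def canonical_names(self) -> list[str]:
        n_fix = len(self.delta)
        n_sd = 2 + len(self.vc.sigma_s) - 1 + len(self.vc.sigma_i) - 1 + 1
        if n_fix == 4 and n_sd == 4:
            return ["b0", "b1", "b2", "b3", "sig1", "sig2", "sig3", "sig4"]
        names = [f"b{j}" for j in range(n_fix)]
        names += ["sd_part:1", "sd_item:1"]
        names += [f"sd_part:{t}" for t in self.vc.term_names_s[1:]]
        names += [f"sd_item:{t}" for t in self.vc.term_names_i[1:]]
        names += ["sd_resid"]
        return names

    @classmethod
    def from_canonical(cls, values, template: "ParameterVector") -> "ParameterVector":
        """Rebuild a ParameterVector from canonical values, copying structure
        (term names, correlations) from ``template``."""
        values = np.asarray(values, dtype=float)
        n_fix = len(template.delta)
        t_s = len(template.vc.sigma_s)
        t_i = len(template.vc.sigma_i)
        delta = values[:n_fix]
        sd = values[n_fix:]
        sigma_s = np.concatenate([[sd[0]], sd[2:2 + t_s - 1]])
        sigma_i = np.concatenate([[sd[1]], sd[2 + t_s - 1:2 + t_s - 1 + t_i - 1]])
        vc = VarianceComponents(
            term_names_s=list(template.vc.term_names_s),
            sigma_s=np.maximum(sigma_s, 0.0),
            term_names_i=list(template.vc.term_names_i),
            sigma_i=np.maximum(sigma_i, 0.0),
            rho_s=template.vc.rho_s, rho_i=template.vc.rho_i,
            sigma_e=max(float(sd[-1]), 0.0),
        )
        return cls(delta=delta, vc=vc)

    def to_json(self) -> str:
        return json.dumps({
            "delta": self.delta.tolist(),
            "term_names_s": self.vc.term_names_s,
            "sigma_s": self.vc.sigma_s.tolist(),
            "term_names_i": self.vc.term_names_i,
            "sigma_i": self.vc.sigma_i.tolist(),
            "rho_s": self.vc.rho_s,
            "rho_i": self.vc.rho_i,
            "sigma_e": self.vc.sigma_e,
        })

    @classmethod
    def from_json(cls, s: str) -> "ParameterVector":
        d = json.loads(s)
        vc = VarianceComponents(
            term_names_s=d["term_names_s"], sigma_s=np.array(d["sigma_s"]),
            term_names_i=d["term_names_i"], sigma_i=np.array(d["sigma_i"]),
            rho_s=d["rho_s"], rho_i=d["rho_i"], sigma_e=d["sigma_e"],
        )
        return cls(delta=np.array(d["delta"]), vc=vc)


# ---------------------------------------------------------------------------
# Henderson solver and likelihood


@dataclass
class MixedModelFit:
    delta_hat: np.ndarray
    u_hat: dict                      # role -> (levels x terms) BLUP array
    fitted: np.ndarray
    residuals: np.ndarray
    loglik: float
    condition_number: float = np.nan


def _mme_solve(design: DesignMatrices, y_stats, vc: VarianceComponents):
    """Solve the mixed-model equations given cross-product statistics.

    y_stats = (Xty, Zty).  Returns (delta, u, condition number).
    """
    xp = design.crossprods()
    sigma_e = max(vc.sigma_e, SIGMA_E_FLOOR)
    Ginv, _ = _ginv_logdet(design, vc)
    f = design.X.shape[1]
    q = design.q
    C = np.empty((f + q, f + q))
    C[:f, :f] = xp["XtX"]
    C[:f, f:] = xp["ZtX"].T
    C[f:, :f] = xp["ZtX"]
    C[f:, f:] = xp["ZtZ"] + sigma_e**2 * Ginv
    rhs = np.concatenate(y_stats)
    try:
        cf = cho_factor(C)
        sol = cho_solve(cf, rhs)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(C)
        raise np.linalg.LinAlgError(
            f"singular Henderson coefficient matrix (cond ~ {cond:.3e})"
        )
    return sol[:f], sol[f:], np.nan


def _loglik_from_stats(design, vc, yty, Xty, Zty, delta, n):
    """Marginal Gaussian log-density via the Woodbury identity."""
    sigma_e = max(vc.sigma_e, SIGMA_E_FLOOR)
    xp = design.crossprods()
    Ginv, logdet_G = _ginv_logdet(design, vc)
    P = Ginv + xp["ZtZ"] / sigma_e**2
    cf = cho_factor(P)
    logdet_P = 2.0 * np.log(np.diag(cf[0])).sum()
    logdet_V = n * np.log(sigma_e**2) + logdet_G + logdet_P
    rtr = yty - 2 * delta @ Xty + delta @ xp["XtX"] @ delta
    Ztr = Zty - xp["ZtX"] @ delta
    quad = (rtr - Ztr @ cho_solve(cf, Ztr) / sigma_e**2) / sigma_e**2
    return -0.5 * (n * np.log(2 * np.pi) + logdet_V + quad)


def solve_henderson(
    design: DesignMatrices, y: np.ndarray, vc: VarianceComponents
) -> MixedModelFit:
    """GLS fixed effects and BLUP random effects from Henderson's equations.

    Equivalent to delta = (X'V^-1 X)^-1 X'V^-1 y and
    u = G~ Z~' V^-1 (y - X delta) with V the expanded marginal covariance.
    """
    y = np.asarray(y, dtype=float)
    if design.n < design.X.shape[1]:
        raise ValueError("fewer rows than fixed-effect columns")
    if vc.sigma_e < SIGMA_E_FLOOR:
        warnings.warn("sigma_e below floor; flooring at 1e-8")
        vc = VarianceComponents(
            term_names_s=vc.term_names_s, sigma_s=vc.sigma_s,
            term_names_i=vc.term_names_i, sigma_i=vc.sigma_i,
            rho_s=vc.rho_s, rho_i=vc.rho_i, sigma_e=SIGMA_E_FLOOR,
        )
    Z = design.incidence()
    Xty = design.X.T @ y
    Zty = np.asarray(Z.T @ y).ravel()
    delta, u, cond = _mme_solve(design, (Xty, Zty), vc)
    fitted = design.X @ delta + Z @ u
    t_s = len(design.term_names_s)
    q_s = design.n_s * t_s
    u_hat = {
        PARTICIPANT: u[:q_s].reshape(design.n_s, t_s),
        ITEM: u[q_s:].reshape(design.n_i, len(design.term_names_i)),
    }
    ll = _loglik_from_stats(design, vc, float(y @ y), Xty, Zty, delta, design.n)
    return MixedModelFit(
        delta_hat=delta, u_hat=u_hat, fitted=fitted,
        residuals=y - fitted, loglik=float(ll), condition_number=cond,
    )


def marginal_loglik(design: DesignMatrices, y: np.ndarray, params: ParameterVector) -> float:
    """log N(y; X delta, V) with V = Z~ G~ Z~' + sigma_e^2 I, numerically stable."""
    if params.vc.sigma_e <= 0:
        raise ValueError("sigma_e must be positive for a nonsingular V")
    y = np.asarray(y, dtype=float)
    Z = design.incidence()
    Xty = design.X.T @ y
    Zty = np.asarray(Z.T @ y).ravel()
    return float(_loglik_from_stats(
        design, params.vc, float(y @ y), Xty, Zty, params.delta, design.n
    ))


# ---------------------------------------------------------------------------
# complete-data M-step (moment form) and direct ML


def complete_data_mstep(
    design: DesignMatrices,
    y: np.ndarray,
    u_draw: dict,
    e_draw: np.ndarray,
) -> ParameterVector:
    """Exact maximizer of the complete-data likelihood given sampled (u, e).

    Variance components are the second moments of the draws
    (sigma_{j,S}^2 = S^-1 sum_s u_{j,s}^2, etc.; correlations are sample
    correlations of the paired columns); fixed effects are then re-solved from
    Henderson's equations on the completed response.
    """
    u_s = np.atleast_2d(np.asarray(u_draw[PARTICIPANT], dtype=float))
    u_i = np.atleast_2d(np.asarray(u_draw[ITEM], dtype=float))
    e = np.asarray(e_draw, dtype=float)
    if u_s.shape[0] == 0 or u_i.shape[0] == 0:
        raise ValueError("zero groups in random-effect draws")
    sigma_s = np.sqrt((u_s**2).mean(axis=0))
    sigma_i = np.sqrt((u_i**2).mean(axis=0))
    sigma_e = float(np.sqrt((e**2).mean()))
    if sigma_e == 0.0 or (sigma_s == 0).all():
        warnings.warn("all-zero draws; degenerate variance estimate",
                      DegenerateDrawWarning)

    def _rho(u):
        if u.shape[1] < 2 or u[:, 0].std() == 0 or u[:, 1].std() == 0:
            return 0.0
        c = np.corrcoef(u[:, 0], u[:, 1])[0, 1]
        return float(np.clip(np.nan_to_num(c), -0.999, 0.999))

    vc = VarianceComponents(
        term_names_s=list(design.term_names_s), sigma_s=sigma_s,
        term_names_i=list(design.term_names_i), sigma_i=sigma_i,
        rho_s=_rho(u_s), rho_i=_rho(u_i),
        sigma_e=max(sigma_e, SIGMA_E_FLOOR),
    )
    fit = solve_henderson(design, y, vc)
    return ParameterVector(delta=fit.delta_hat, vc=vc)


def _pack_vc(vc: VarianceComponents, estimate_rho: bool) -> np.ndarray:
    phi = np.log(np.concatenate([
        np.maximum(vc.sigma_s, 1e-6), np.maximum(vc.sigma_i, 1e-6),
        [max(vc.sigma_e, 1e-6)],
    ]))
    if estimate_rho and len(vc.sigma_s) > 1:
        phi = np.concatenate([phi, [np.arctanh(np.clip(vc.rho_s, -0.99, 0.99))]])
    return phi


def _unpack_vc(phi, design, estimate_rho) -> VarianceComponents:
    t_s = len(design.term_names_s)
    t_i = len(design.term_names_i)
    sd = np.exp(phi[: t_s + t_i + 1])
    rho_s = float(np.tanh(phi[t_s + t_i + 1])) if (estimate_rho and t_s > 1) else 0.0
    return VarianceComponents(
        term_names_s=list(design.term_names_s), sigma_s=sd[:t_s],
        term_names_i=list(design.term_names_i), sigma_i=sd[t_s:t_s + t_i],
        rho_s=rho_s, rho_i=0.0, sigma_e=float(sd[-1]),
    )


def ml_fit(
    design: DesignMatrices,
    y: np.ndarray,
    start: VarianceComponents | None = None,
    estimate_rho: bool = False,
    maxiter: int = 200,
) -> tuple[ParameterVector, MixedModelFit]:
    """Maximum-likelihood fit by quasi-Newton search over log-SD variance
    parameters with the fixed effects profiled out through Henderson's system.

    ``y`` may be a matrix (n x m) of completed responses, in which case the
    averaged complete-data objective (1/m) sum_j log L(theta; y_j) is
    maximized — the Monte-Carlo EM M-step.
    """
    Y = np.asarray(y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    Z = design.incidence()
    XtY = design.X.T @ Y
    ZtY = np.asarray(Z.T @ Y)
    ytys = (Y * Y).sum(axis=0)
    ybar = Y.mean(axis=1)
    Xty_bar = XtY.mean(axis=1)
    Zty_bar = ZtY.mean(axis=1)

    if start is None:
        # moment heuristics on OLS residuals
        delta0, *_ = np.linalg.lstsq(design.X, ybar, rcond=None)
        r = ybar - design.X @ delta0
        sd_r = max(float(r.std()), 1e-3)
        g_s = np.bincount(design.s_index, r, minlength=design.n_s)
        c_s = np.bincount(design.s_index, minlength=design.n_s)
        g_i = np.bincount(design.i_index, r, minlength=design.n_i)
        c_i = np.bincount(design.i_index, minlength=design.n_i)
        sd_s0 = max(float((g_s / np.maximum(c_s, 1)).std()), 0.05 * sd_r)
        sd_i0 = max(float((g_i / np.maximum(c_i, 1)).std()), 0.05 * sd_r)
        start = VarianceComponents(
            term_names_s=list(design.term_names_s),
            sigma_s=np.array([sd_s0] + [
                0.1 * sd_r / max(float(design.z_s[:, j].std()), 1e-6)
                for j in range(1, len(design.term_names_s))
            ]),
            term_names_i=list(design.term_names_i),
            sigma_i=np.array([sd_i0] + [
                0.1 * sd_r / max(float(design.z_i[:, j].std()), 1e-6)
                for j in range(1, len(design.term_names_i))
            ]),
            sigma_e=0.9 * sd_r,
        )

    def neg_avg_loglik(phi):
        vc = _unpack_vc(phi, design, estimate_rho)
        try:
            delta, _, _ = _mme_solve(design, (Xty_bar, Zty_bar), vc)
            ll = 0.0
            for j in range(m):
                ll += _loglik_from_stats(
                    design, vc, float(ytys[j]), XtY[:, j], ZtY[:, j], delta, n
                )
            return -ll / m
        except np.linalg.LinAlgError:
            return 1e12

    phi0 = _pack_vc(start, estimate_rho)
    lo, hi = phi0 - 12.0, phi0 + 12.0
    res = minimize(
        neg_avg_loglik, phi0, method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
    )
    vc = _unpack_vc(res.x, design, estimate_rho)
    fit = solve_henderson(design, ybar, vc)
    return ParameterVector(delta=fit.delta_hat, vc=vc), fit


# ---------------------------------------------------------------------------
# I/O


def load_long_csv(path, spec: ModelSpec, response: str = "RT") -> tuple[pd.DataFrame, np.ndarray]:
    """Read a long-format CSV (response, covariates, participant, item)."""
    df = pd.read_csv(path)
    needed = [response, *spec.covariate_names, *spec.grouping_factors]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing columns: {missing}")
    return df, df[response].to_numpy(dtype=float)
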