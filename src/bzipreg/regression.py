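"""BZIP regression: datasets, log-link predictors, priors, and log-posteriors.

The full model places a log link on each count rate,

    log lambda1_i = x_i' beta,   log lambda2_i = x_i' gamma,
    lambda3 = exp(alpha),        p0 ~ Uniform(0, 1),

with independent N(0, 1000) priors on every regression coefficient and on
alpha.  Both responses share one design matrix (the same covariates enter
both predictors).  The comparator models are restrictions of this: the
univariate Poisson models drop p0 and lambda3; the univariate ZIP models
keep a scalar zero-inflation mass for their own response; the bivariate
Poisson (BP) model fixes p0 = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .distributions import _bp_log_pmf_arrays, _bzip_log_pmf_arrays

logger = logging.getLogger(__name__)

__all__ = [
    "BivariateCountDataset",
    "RegressionParams",
    "PriorSpec",
    "compute_rates",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "restrict_model",
    "load_dataset",
    "MODEL_FAMILIES",
]

#: Bound on linear predictors before exponentiation; exp(700) is the largest
#: finite double, so rates are clipped into a representable range.
LINPRED_GUARD = 700.0

MODEL_FAMILIES = ("poisson_y1", "poisson_y2", "zip_y1", "zip_y2", "bp", "bzip")


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class BivariateCountDataset:
    """Paired count responses plus a shared design matrix (with intercept)."""

    y1: np.ndarray
    y2: np.ndarray
    X: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.y1 = np.asarray(self.y1, dtype=np.int64)
        self.y2 = np.asarray(self.y2, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=float)
        if self.y1.ndim != 1 or self.y2.ndim != 1 or self.X.ndim != 2:
            raise ValueError("y1, y2 must be vectors and X a matrix")
        n = len(self.y1)
        if len(self.y2) != n or self.X.shape[0] != n:
            raise ValueError("y1, y2 and rows of X must all have the same length")
        if np.any(self.y1 < 0) or np.any(self.y2 < 0):
            raise ValueError("counts must be non-negative")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names must label every column of X")
        # cached indicator of the (0,0) cell
        self.both_zero = (self.y1 == 0) & (self.y2 == 0)

    @property
    def n(self) -> int:
        return len(self.y1)

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class RegressionParams:
    """Parameter state (beta, gamma, alpha, p0) of the BZIP regression."""

    beta: np.ndarray
    gamma: np.ndarray
    alpha: float
    p0: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if self.beta.shape != self.gamma.shape:
            raise ValueError("beta and gamma must have the same length")
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")

    @property
    def lambda3(self) -> float:
        return math.exp(self.alpha)


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors: N(coef_mean, coef_variance) on each coefficient and
    on alpha; Uniform(0, 1) on p0."""

    coef_mean: float = 0.0
    coef_variance: float = 1000.0

    def __post_init__(self) -> None:
        if self.coef_variance <= 0:
            raise ValueError("coef_variance must be positive")


# ---------------------------------------------------------------------------
# Likelihood building blocks
# ---------------------------------------------------------------------------

def _guarded_exp(eta: np.ndarray, label: str) -> np.ndarray:
    if np.any(np.abs(eta) > LINPRED_GUARD):
        logger.warning("linear predictor for %s exceeded +/-%g; clipping", label, LINPRED_GUARD)
        eta = np.clip(eta, -LINPRED_GUARD, LINPRED_GUARD)
    return np.exp(eta)


def compute_rates(X: np.ndarray, params: RegressionParams):
    """Per-observation (lambda1_i, lambda2_i) and the scalar lambda3.

    Applies the log link; linear predictors are clipped at +/-700 (with a
    logged warning) so the exponential cannot overflow.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(params.beta):
        raise ValueError(
            f"design matrix has {X.shape[1]} columns but beta has length {len(params.beta)}"
        )
    lam1 = _guarded_exp(X @ params.beta, "lambda1")
    lam2 = _guarded_exp(X @ params.gamma, "lambda2")
    alpha = min(max(params.alpha, -LINPRED_GUARD), LINPRED_GUARD)
    return lam1, lam2, math.exp(alpha)


def log_likelihood(data: BivariateCountDataset, params: RegressionParams) -> float:
    """BZIP regression log-likelihood: sum over observations of the joint
    log-pmf at per-observation rates.  Observations in the (0,0) cell
    contribute log[p0 + (1-p0) e^{-lambda_i}], the rest log(1-p0) plus the
    BP term."""
    if data.n == 0:
        return 0.0
    lam1, lam2, lam3 = compute_rates(data.X, params)
    ll = _bzip_log_pmf_arrays(data.y1, data.y2, params.p0, lam1, lam2, lam3)
    return float(np.sum(ll))


def log_prior(params: RegressionParams, prior: PriorSpec = PriorSpec()) -> float:
    """Sum of independent normal log-densities over beta, gamma and alpha,
    plus the Uniform(0,1) log-density of p0 (0 inside, -inf outside)."""
    if not (0.0 < params.p0 < 1.0):
        return -math.inf
    coefs = np.concatenate([params.beta, params.gamma, [params.alpha]])
    return float(_normal_logpdf_sum(coefs, prior))


def _normal_logpdf_sum(values: np.ndarray, prior: PriorSpec) -> float:
    v = prior.coef_variance
    z = np.asarray(values, dtype=float) - prior.coef_mean
    return float(-0.5 * len(z) * math.log(2 * math.pi * v) - 0.5 * np.sum(z * z) / v)


def log_posterior(
    data: BivariateCountDataset, params: RegressionParams, prior: PriorSpec = PriorSpec()
) -> float:
    """Unnormalised log posterior: log_likelihood + log_prior."""
    lp = log_prior(params, prior)
    if not math.isfinite(lp):
        return -math.inf
    return log_likelihood(data, params) + lp


# ---------------------------------------------------------------------------
# The six-model family
#
# Each model object binds a dataset and a prior and exposes a log posterior
# over its own flat parameter vector.  MCMC runs on an unconstrained scale:
# coefficients and alpha are sampled as-is, p0 through its logit (with the
# Jacobian term included in ``log_posterior_unconstrained``).  Reporting and
# DIC work on the constrained scale returned by ``to_constrained``.
# ---------------------------------------------------------------------------

def _softplus(x: float) -> float:
    return math.log1p(math.exp(-abs(x))) + max(x, 0.0)


class CountRegressionModel:
    """Base class: flat parameter vector, blocks for Metropolis-within-Gibbs."""

    family: str

    def __init__(self, data: BivariateCountDataset, prior: PriorSpec):
        self.data = data
        self.prior = prior

    # -- interface ---------------------------------------------------------
    @property
    def n_params(self) -> int:
        return len(self.param_names)

    param_names: list[str]
    #: list of (block label, index array); each block is one Metropolis update
    blocks: list[tuple[str, np.ndarray]]
    #: index of the logit-p0 coordinate, or None
    p0_index: int | None = None

    def log_likelihood_constrained(self, theta: np.ndarray) -> float:
        raise NotImplementedError

    def initial_state(self, jitter_rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def initial_proposal_chol(self, label: str, idx: np.ndarray) -> np.ndarray | None:
        """Initial proposal shape for a block (refined by burn-in adaptation).

        Coefficient blocks are preconditioned with the inverse Fisher
        information of a constant-rate Poisson fit, inv(ybar * X'X): the
        posterior scale of a log-link coefficient varies with its covariate's
        spread, and an unpreconditioned random walk mixes very slowly.
        """
        if self.data.n == 0:
            return None
        if label == "coef":
            y = self.y  # univariate models bind their own response
        elif label == "beta":
            y = self.data.y1
        elif label == "gamma":
            y = self.data.y2
        else:
            return None
        X = self.data.X
        info = max(float(y.mean()), 0.1) * (X.T @ X) + 1e-8 * np.eye(X.shape[1])
        try:
            return np.linalg.cholesky(np.linalg.inv(info))
        except np.linalg.LinAlgError:
            return None

    # -- shared machinery ---------------------------------------------------
    def to_constrained(self, z: np.ndarray) -> np.ndarray:
        """Map an unconstrained state to the reporting scale (p0 in (0,1))."""
        theta = np.array(z, dtype=float)
        if self.p0_index is not None:
            theta[self.p0_index] = expit(z[self.p0_index])
        return theta

    def _log_prior_unconstrained(self, z: np.ndarray) -> float:
        if self.p0_index is None:
            coefs = z
            jac = 0.0
        else:
            coefs = np.delete(z, self.p0_index)
            t = z[self.p0_index]
            # uniform prior on p0 plus log |dp0/dlogit(p0)|
            jac = -_softplus(t) - _softplus(-t)
        return _normal_logpdf_sum(coefs, self.prior) + jac

    def log_posterior_unconstrained(self, z: np.ndarray) -> float:
        lp = self._log_prior_unconstrained(z)
        if not math.isfinite(lp):
            return -math.inf
        return self.log_likelihood_constrained(self.to_constrained(z)) + lp

    def log_posterior(self, theta: np.ndarray) -> float:
        """Log posterior over the constrained parameter vector."""
        theta = np.asarray(theta, dtype=float)
        if self.p0_index is not None:
            p0 = theta[self.p0_index]
            if not (0.0 < p0 < 1.0):
                return -math.inf
            coefs = np.delete(theta, self.p0_index)
        else:
            coefs = theta
        return self.log_likelihood_constrained(theta) + _normal_logpdf_sum(coefs, self.prior)


def _poisson_reg_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    lam = _guarded_exp(X @ beta, "poisson rate")
    return float(np.sum(y * np.log(lam) - lam - gammaln(y + 1)))


class _PoissonModel(CountRegressionModel):
    """Univariate Poisson regression on one of the two responses."""

    def __init__(self, data, prior, which: int):
        super().__init__(data, prior)
        self.which = which
        self.family = f"poisson_y{which}"
        self.y = data.y1 if which == 1 else data.y2
        pre = "beta" if which == 1 else "gamma"
        self.param_names = [f"{pre}[{c}]" for c in data.covariate_names]
        self.blocks = [("coef", np.arange(data.p))]
        self.p0_index = None

    def log_likelihood_constrained(self, theta):
        return _poisson_reg_loglik(self.y, self.data.X, theta)

    def initial_state(self, jitter_rng=None):
        z = np.zeros(self.data.p)
        z[0] = _safe_log_mean(self.y)
        return _maybe_jitter(z, jitter_rng)


class _ZIPModel(CountRegressionModel):
    """Univariate zero-inflated Poisson regression on one response."""

    def __init__(self, data, prior, which: int):
        super().__init__(data, prior)
        self.which = which
        self.family = f"zip_y{which}"
        self.y = data.y1 if which == 1 else data.y2
        pre = "beta" if which == 1 else "gamma"
        self.param_names = [f"{pre}[{c}]" for c in data.covariate_names] + ["p0"]
        self.blocks = [("coef", np.arange(data.p)), ("p0", np.array([data.p]))]
        self.p0_index = data.p

    def log_likelihood_constrained(self, theta):
        beta = theta[: self.data.p]
        p0 = theta[self.p0_index]
        if not (0.0 < p0 < 1.0):
            return -math.inf
        lam = _guarded_exp(self.data.X @ beta, "zip rate")
        pois = self.y * np.log(lam) - lam - gammaln(self.y + 1)
        zero = np.logaddexp(math.log(p0), math.log1p(-p0) - lam)
        ll = np.where(self.y == 0, zero, math.log1p(-p0) + pois)
        return float(np.sum(ll))

    def initial_state(self, jitter_rng=None):
        z = np.zeros(self.data.p + 1)
        zero_frac = float(np.mean(self.y == 0)) if len(self.y) else 0.5
        z[0] = _safe_log_mean(self.y)
        z[-1] = _logit(min(max(zero_frac * 0.8, 0.02), 0.95))
        return _maybe_jitter(z, jitter_rng)


class _BPModel(CountRegressionModel):
    """Bivariate Poisson regression (the p0 = 0 restriction of BZIP)."""

    family = "bp"

    def __init__(self, data, prior):
        super().__init__(data, prior)
        p = data.p
        self.param_names = (
            [f"beta[{c}]" for c in data.covariate_names]
            + [f"gamma[{c}]" for c in data.covariate_names]
            + ["alpha"]
        )
        self.blocks = [
            ("beta", np.arange(p)),
            ("gamma", np.arange(p, 2 * p)),
            ("alpha", np.array([2 * p])),
        ]
        self.p0_index = None

    def _rates(self, theta):
        p = self.data.p
        lam1 = _guarded_exp(self.data.X @ theta[:p], "lambda1")
        lam2 = _guarded_exp(self.data.X @ theta[p : 2 * p], "lambda2")
        lam3 = math.exp(min(max(theta[2 * p], -LINPRED_GUARD), LINPRED_GUARD))
        return lam1, lam2, lam3

    def log_likelihood_constrained(self, theta):
        lam1, lam2, lam3 = self._rates(theta)
        return float(np.sum(_bp_log_pmf_arrays(self.data.y1, self.data.y2, lam1, lam2, lam3)))

    def initial_state(self, jitter_rng=None):
        z = np.zeros(self.n_params)
        z[0] = _safe_log_mean(self.data.y1)
        z[self.data.p] = _safe_log_mean(self.data.y2)
        z[-1] = -3.0  # small shared component to start
        return _maybe_jitter(z, jitter_rng)


class _BZIPModel(CountRegressionModel):
    """Full BZIP regression model."""

    family = "bzip"

    def __init__(self, data, prior):
        super().__init__(data, prior)
        p = data.p
        self.param_names = (
            [f"beta[{c}]" for c in data.covariate_names]
            + [f"gamma[{c}]" for c in data.covariate_names]
            + ["alpha", "p0"]
        )
        self.blocks = [
            ("beta", np.arange(p)),
            ("gamma", np.arange(p, 2 * p)),
            ("alpha", np.array([2 * p])),
            ("p0", np.array([2 * p + 1])),
        ]
        self.p0_index = 2 * p + 1

    def unpack(self, theta: np.ndarray) -> RegressionParams:
        p = self.data.p
        return RegressionParams(
            beta=theta[:p], gamma=theta[p : 2 * p], alpha=float(theta[2 * p]),
            p0=float(theta[2 * p + 1]),
        )

    def log_likelihood_constrained(self, theta):
        p = self.data.p
        p0 = theta[self.p0_index]
        if not (0.0 < p0 < 1.0):
            return -math.inf
        lam1 = _guarded_exp(self.data.X @ theta[:p], "lambda1")
        lam2 = _guarded_exp(self.data.X @ theta[p : 2 * p], "lambda2")
        lam3 = math.exp(min(max(theta[2 * p], -LINPRED_GUARD), LINPRED_GUARD))
        ll = _bzip_log_pmf_arrays(self.data.y1, self.data.y2, p0, lam1, lam2, lam3)
        return float(np.sum(ll))

    def initial_state(self, jitter_rng=None):
        data = self.data
        z = np.zeros(self.n_params)
        z[0] = _safe_log_mean(data.y1)
        z[data.p] = _safe_log_mean(data.y2)
        z[2 * data.p] = -3.0
        zero_frac = float(np.mean(data.both_zero)) if data.n else 0.5
        z[-1] = _logit(min(max(zero_frac * 0.9, 0.02), 0.95))
        return _maybe_jitter(z, jitter_rng)


def _safe_log_mean(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    return math.log(max(float(y.mean()), 0.05))


def _logit(p: float) -> float:
    return math.log(p / (1 - p))


def _maybe_jitter(z: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
    """Overdispersed start for secondary chains (needed for Gelman-Rubin)."""
    if rng is None:
        return z
    return z + rng.normal(scale=0.5, size=z.shape)


def restrict_model(
    data: BivariateCountDataset, family: str, prior: PriorSpec = PriorSpec()
) -> CountRegressionModel:
    """Build one of the six comparator models bound to ``data``.

    Families: ``poisson_y1``/``poisson_y2`` (univariate Poisson regression),
    ``zip_y1``/``zip_y2`` (univariate ZIP with a scalar zero-inflation mass),
    ``bp`` (BZIP with p0 fixed at 0), ``bzip`` (full model).  All share the
    same design matrix and priors.
    """
    if family == "poisson_y1":
        return _PoissonModel(data, prior, 1)
    if family == "poisson_y2":
        return _PoissonModel(data, prior, 2)
    if family == "zip_y1":
        return _ZIPModel(data, prior, 1)
    if family == "zip_y2":
        return _ZIPModel(data, prior, 2)
    if family == "bp":
        return _BPModel(data, prior)
    if family == "bzip":
        return _BZIPModel(data, prior)
    raise ValueError(f"unknown model family {family!r}; choose from {MODEL_FAMILIES}")


# ---------------------------------------------------------------------------
# CSV loading
# ---------------------------------------------------------------------------

def load_dataset(
    path_or_frame,
    response_cols: tuple[str, str] = ("y1", "y2"),
    covariate_cols: list[str] | None = None,
    categorical: dict[str, str] | None = None,
    center: list[str] | None = None,
) -> BivariateCountDataset:
    """Read a paired-count dataset from CSV (or a DataFrame).

    ``categorical`` maps column names to their reference level; such columns
    are expanded to 0/1 dummies against that reference (the "versus" coding
    of contrast tables).  ``center`` lists numeric columns to mean-center
    before entering the design matrix.  An intercept column is prepended.
    """
    df = path_or_frame if isinstance(path_or_frame, pd.DataFrame) else pd.read_csv(path_or_frame)
    categorical = categorical or {}
    center = center or []
    r1, r2 = response_cols
    if covariate_cols is None:
        covariate_cols = [c for c in df.columns if c not in (r1, r2, "id")]

    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for c in covariate_cols:
        if c in categorical:
            ref = categorical[c]
            levels = [str(v) for v in pd.unique(df[c].astype(str))]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in column {c!r}")
            for lev in sorted(set(levels) - {ref}):
                cols.append((df[c].astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev} vs {ref}]")
        else:
            v = pd.to_numeric(df[c], errors="raise").to_numpy(dtype=float)
            if c in center:
                v = v - v.mean()
                names.append(f"{c} - mean({c})")
            else:
                names.append(c)
            cols.append(v)
    X = np.column_stack(cols)
    return BivariateCountDataset(
        y1=df[r1].to_numpy(), y2=df[r2].to_numpy(), X=X, covariate_names=names
    )
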