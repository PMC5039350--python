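"""Bivariate Poisson (BP) and bivariate zero-inflated Poisson (BZIP) distributions.

The BP distribution arises by trivariate reduction: with ``Z1, Z2, Z3``
independent Poisson variables with rates ``lambda1, lambda2, lambda3``, the
pair ``(Y1, Y2) = (Z1 + Z3, Z2 + Z3)`` has Poisson marginals with rates
``lambda1 + lambda3`` and ``lambda2 + lambda3`` and covariance ``lambda3``.
The BZIP distribution mixes a BP component (weight ``1 - p0``) with a point
mass at ``(0, 0)`` (weight ``p0``), modelling structural zeros — subjects for
whom both counts are zero for reasons outside the count process.

All probability mass functions are exposed in log form and evaluated in log
space (log-factorials plus log-sum-exp over the shared-component index), so
that rates of order 50 and counts of order 200 neither overflow nor
underflow.  Natural-scale values are ``exp`` of the returned log values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "BPRates",
    "BZIPParamsCore",
    "BZIPMoments",
    "bp_log_pmf",
    "bzip_log_pmf",
    "zip_marginal_log_pmf",
    "bp_correlation",
    "bzip_moments",
    "sample_bp",
    "sample_bzip",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BPRates:
    """Rates of the bivariate Poisson distribution.

    ``lambda3`` is the rate of the shared latent component and equals the
    covariance of the pair; ``lambda3 = 0`` gives two independent Poisson
    variables (the double-Poisson model).
    """

    lambda1: float
    lambda2: float
    lambda3: float = 0.0

    def __post_init__(self) -> None:
        if not (self.lambda1 > 0 and math.isfinite(self.lambda1)):
            raise ValueError(f"lambda1 must be positive and finite, got {self.lambda1}")
        if not (self.lambda2 > 0 and math.isfinite(self.lambda2)):
            raise ValueError(f"lambda2 must be positive and finite, got {self.lambda2}")
        if not (self.lambda3 >= 0 and math.isfinite(self.lambda3)):
            raise ValueError(f"lambda3 must be non-negative and finite, got {self.lambda3}")


@dataclass(frozen=True)
class BZIPParamsCore:
    """Zero-inflation mass ``p0`` plus the BP rates of the count component."""

    p0: float
    rates: BPRates

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 < 1.0):
            raise ValueError(f"p0 must lie in the open interval (0, 1), got {self.p0}")

    @property
    def lambda_total(self) -> float:
        """Total rate lambda1 + lambda2 + lambda3 of the BP component."""
        r = self.rates
        return r.lambda1 + r.lambda2 + r.lambda3


@dataclass(frozen=True)
class BZIPMoments:
    """First and second moments of a BZIP pair."""

    mean1: float
    mean2: float
    var1: float
    var2: float
    cov: float
    corr: float = field(default=float("nan"))


# ---------------------------------------------------------------------------
# Log probability mass functions
# ---------------------------------------------------------------------------

def _validate_counts(y1: np.ndarray, y2: np.ndarray) -> None:
    for name, y in (("y1", y1), ("y2", y2)):
        if np.any(y < 0):
            raise ValueError(f"{name} contains negative counts")
        if not np.all(np.equal(np.mod(y, 1), 0)):
            raise ValueError(f"{name} contains non-integer counts")


def _bp_log_pmf_arrays(y1, y2, lam1, lam2, lam3):
    """Vectorised BP log-pmf; ``lam1``/``lam2`` broadcast, ``lam3`` scalar.

    The inner sum over the shared-component index k = 0..min(y1, y2) is done
    with log-sum-exp; at lam3 = 0 only the k = 0 term contributes and the
    result reduces exactly to the sum of two Poisson log-pmfs.
    """
    y1 = np.asarray(y1, dtype=np.int64)
    y2 = np.asarray(y2, dtype=np.int64)
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    lam3 = float(lam3)

    base = (
        -(lam1 + lam2 + lam3)
        + y1 * np.log(lam1) - gammaln(y1 + 1)
        + y2 * np.log(lam2) - gammaln(y2 + 1)
    )
    m = np.minimum(y1, y2)
    kmax = int(m.max()) if m.size else 0
    if kmax == 0 or lam3 == 0.0:
        return base  # only the k = 0 term (empty product equals 1)

    k = np.arange(kmax + 1)
    # log[C(y1,k) C(y2,k) k! (lam3/(lam1 lam2))^k]; shape (..., kmax+1)
    y1e, y2e, me = y1[..., None], y2[..., None], m[..., None]
    log_ratio = np.log(lam3) - np.log(lam1)[..., None] - np.log(lam2)[..., None]
    with np.errstate(invalid="ignore"):
        terms = (
            gammaln(y1e + 1) - gammaln(np.maximum(y1e - k, 0) + 1)
            + gammaln(y2e + 1) - gammaln(np.maximum(y2e - k, 0) + 1)
            - gammaln(k + 1)
            + k * log_ratio
        )
    terms = np.where(k <= me, terms, -np.inf)
    return base + logsumexp(terms, axis=-1)


def bp_log_pmf(y1, y2, rates: BPRates):
    """Log joint pmf of the bivariate Poisson distribution.

    Accepts scalar or array counts (broadcast together); returns log
    probabilities of the same shape.
    """
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    _validate_counts(y1, y2)
    y1b, y2b = np.broadcast_arrays(y1, y2)
    out = _bp_log_pmf_arrays(y1b, y2b, rates.lambda1, rates.lambda2, rates.lambda3)
    return float(out) if out.ndim == 0 else out


def _bzip_log_pmf_arrays(y1, y2, p0, lam1, lam2, lam3):
    """Vectorised BZIP log-pmf (mixture of BP and a point mass at (0,0))."""
    y1 = np.asarray(y1, dtype=np.int64)
    y2 = np.asarray(y2, dtype=np.int64)
    bp = _bp_log_pmf_arrays(y1, y2, lam1, lam2, lam3)
    log_one_minus_p0 = math.log1p(-p0)
    lam_total = np.broadcast_to(
        np.asarray(lam1, float) + np.asarray(lam2, float) + lam3, bp.shape
    )
    both_zero = (y1 == 0) & (y2 == 0)
    # (0,0) cell: log[p0 + (1-p0) e^{-lambda}] via log-sum-exp for stability
    zero_cell = np.logaddexp(math.log(p0), log_one_minus_p0 - lam_total)
    return np.where(both_zero, zero_cell, log_one_minus_p0 + bp)


def bzip_log_pmf(y1, y2, params: BZIPParamsCore):
    """Log joint pmf of the bivariate zero-inflated Poisson distribution."""
    y1 = np.asarray(y1)
    y2 = np.asarray(y2)
    _validate_counts(y1, y2)
    y1b, y2b = np.broadcast_arrays(y1, y2)
    r = params.rates
    out = _bzip_log_pmf_arrays(y1b, y2b, params.p0, r.lambda1, r.lambda2, r.lambda3)
    return float(out) if out.ndim == 0 else out


def zip_marginal_log_pmf(y, which: int, params: BZIPParamsCore):
    """Log pmf of the ZIP marginal of a BZIP pair.

    The marginal of ``Y_which`` is zero-inflated Poisson with count rate
    ``lambda_which + lambda3`` and zero-inflation mass ``p0``.
    """
    if which not in (1, 2):
        raise ValueError(f"which must be 1 or 2, got {which}")
    y = np.asarray(y)
    _validate_counts(y, np.asarray(0))
    r = params.rates
    lam = (r.lambda1 if which == 1 else r.lambda2) + r.lambda3
    p0 = params.p0
    y = np.asarray(y, dtype=np.int64)
    pois = y * np.log(lam) - gammaln(y + 1) - lam
    zero = np.logaddexp(math.log(p0), math.log1p(-p0) - lam)
    out = np.where(y == 0, zero, math.log1p(-p0) + pois)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Moments and correlation
# ---------------------------------------------------------------------------

def bp_correlation(rates: BPRates) -> float:
    """Correlation lambda3 / sqrt((lambda1+lambda3)(lambda2+lambda3)) of a BP pair.

    Always in [0, 1): the trivariate-reduction construction only produces
    non-negative dependence.
    """
    v1 = rates.lambda1 + rates.lambda3
    v2 = rates.lambda2 + rates.lambda3
    if v1 <= 0 or v2 <= 0:
        raise ValueError("both marginal rates must be positive")
    return rates.lambda3 / math.sqrt(v1 * v2)


def bzip_moments(params: BZIPParamsCore) -> BZIPMoments:
    """Means, variances, covariance and correlation of a BZIP pair.

    E(Yk) = (1-p0)(lambda_k + lambda3);
    Var(Yk) = E(Yk)[1 + p0 (lambda_k + lambda3)];
    Cov(Y1,Y2) = (1-p0)[lambda3 + p0 (lambda1+lambda3)(lambda2+lambda3)].
    The ZIP marginals are overdispersed (Var >= mean) whenever p0 > 0.
    """
    r = params.rates
    p0 = params.p0
    mu1 = r.lambda1 + r.lambda3
    mu2 = r.lambda2 + r.lambda3
    mean1 = (1 - p0) * mu1
    mean2 = (1 - p0) * mu2
    var1 = mean1 * (1 + p0 * mu1)
    var2 = mean2 * (1 + p0 * mu2)
    cov = (1 - p0) * (r.lambda3 + p0 * mu1 * mu2)
    corr = cov / math.sqrt(var1 * var2) if var1 > 0 and var2 > 0 else float("nan")
    return BZIPMoments(mean1=mean1, mean2=mean2, var1=var1, var2=var2, cov=cov, corr=corr)


# ---------------------------------------------------------------------------
# Random generation (trivariate reduction)
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_bp(n: int, rates: BPRates, seed) -> np.ndarray:
    """Draw ``n`` BP pairs by trivariate reduction; returns an (n, 2) array.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    z1 = rng.poisson(rates.lambda1, size=n)
    z2 = rng.poisson(rates.lambda2, size=n)
    z3 = rng.poisson(rates.lambda3, size=n)
    return np.column_stack([z1 + z3, z2 + z3])


def _sample_bzip_arrays(p0, lam1, lam2, lam3, n, rng) -> np.ndarray:
    """BZIP draws with (possibly per-observation) rates; (n, 2) int array."""
    lam1 = np.broadcast_to(np.asarray(lam1, float), (n,))
    lam2 = np.broadcast_to(np.asarray(lam2, float), (n,))
    z1 = rng.poisson(lam1)
    z2 = rng.poisson(lam2)
    z3 = rng.poisson(lam3, size=n)
    pairs = np.column_stack([z1 + z3, z2 + z3])
    structural = rng.random(n) < p0
    pairs[structural] = 0
    return pairs


def sample_bzip(n: int, params: BZIPParamsCore, seed) -> np.ndarray:
    """Draw ``n`` BZIP pairs: with probability ``p0`` a structural (0, 0),
    otherwise a trivariate-reduction BP draw.  Returns an (n, 2) array."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = _as_rng(seed)
    r = params.rates
    return _sample_bzip_arrays(params.p0, r.lambda1, r.lambda2, r.lambda3, n, rng)
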