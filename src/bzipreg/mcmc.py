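"""Posterior simulation and diagnostics.

The sampler is adaptive random-walk Metropolis-within-Gibbs on an
unconstrained scale: regression coefficient vectors are updated as blocks
with multivariate normal proposals, alpha (= log lambda3) and logit(p0) as
scalars.  Proposal scales — and, for coefficient blocks, the proposal
covariance — adapt during burn-in toward a 20-45% acceptance rate and are
frozen afterwards, which keeps the post-burn-in chain a genuine Markov
chain.  The default chain protocol is two parallel chains, 5000 burn-in
iterations, 30000 post-burn-in iterations with every 20th draw retained.

Diagnostics: the corrected (df-adjusted) Gelman-Rubin potential scale
reduction factor, a batch-means Monte-Carlo standard error with the
"MC error < 0.1 x posterior SD" rule, posterior summary tables
(mean / median / SD / equal-tailed 95% credible interval), and the sample
autocorrelation function.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "PosteriorSamples",
    "ConvergenceReport",
    "InitializationError",
    "run_chains",
    "gelman_rubin",
    "mc_error",
    "summarize",
    "autocorrelation",
]

#: Target acceptance band for proposal-scale adaptation.
ACCEPT_TARGET = 0.3
#: PSRF threshold operationalising "close to one".
PSRF_THRESHOLD = 1.1


class InitializationError(RuntimeError):
    """Raised when a chain cannot start (non-finite posterior at the start)."""


@dataclass(frozen=True)
class ChainConfig:
    """Chain protocol: chains, burn-in, post-burn-in length, thinning, seed."""

    n_chains: int = 2
    burn_in: int = 5000
    n_iter: int = 30000
    thin: int = 20
    seed: int = 0
    adapt_window: int = 100

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter < 1 or self.thin < 1 or self.burn_in < 0:
            raise ValueError("invalid chain configuration")

    @property
    def n_retained(self) -> int:
        return self.n_iter // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws, organised chain x draw x parameter.

    Draws are stored on the reporting scale (p0 in (0,1); coefficients and
    alpha as sampled).
    """

    draws: np.ndarray
    parameter_names: list[str]
    config: ChainConfig
    acceptance_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be a chain x draw x parameter array")
        if self.draws.shape[2] != len(self.parameter_names):
            raise ValueError("parameter_names must label the last axis of draws")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def pooled(self) -> np.ndarray:
        """All chains concatenated: (n_chains * n_draws, n_params)."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.parameter_names.index(name)]


@dataclass
class ConvergenceReport:
    """Per-parameter PSRF and Monte-Carlo error with the 0.1-SD rule."""

    psrf: pd.Series
    mc_error: pd.Series
    mc_error_ok: pd.Series
    max_psrf: float

    def converged(self, threshold: float = PSRF_THRESHOLD) -> bool:
        return bool(self.max_psrf < threshold and self.mc_error_ok.all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"psrf": self.psrf, "mc_error": self.mc_error, "mc_error_ok": self.mc_error_ok}
        )


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

class _BlockProposal:
    """Random-walk proposal for one parameter block, adaptive during burn-in."""

    def __init__(self, indices: np.ndarray, label: str, chol: np.ndarray | None = None):
        self.idx = indices
        self.label = label
        d = len(indices)
        self.scale = 2.4 / math.sqrt(d)
        self.chol = np.eye(d) * 0.1 if chol is None else chol
        self.accepts = 0
        self.tries = 0
        self.post_accepts = 0
        self.post_tries = 0

    def propose(self, z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        step = self.scale * (self.chol @ rng.standard_normal(len(self.idx)))
        znew = z.copy()
        znew[self.idx] += step
        return znew

    def adapt_scale(self) -> None:
        if self.tries == 0:
            return
        rate = self.accepts / self.tries
        self.scale *= math.exp(0.66 * (rate - ACCEPT_TARGET))
        self.scale = min(max(self.scale, 1e-6), 1e3)
        self.accepts = 0
        self.tries = 0

    def adapt_covariance(self, history: np.ndarray) -> None:
        """Refresh the proposal shape from burn-in history (blocks of dim > 1)."""
        d = len(self.idx)
        if d == 1 or history.shape[0] < 10 * d:
            return
        cov = np.cov(history[:, self.idx], rowvar=False)
        cov += 1e-8 * np.eye(d)
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:  # keep previous shape on failure
            pass


def _run_single_chain(
    model, config: ChainConfig, z0: np.ndarray, rng, overdisperse: bool = False
) -> tuple[np.ndarray, dict]:
    precond = getattr(model, "initial_proposal_chol", lambda label, idx: None)
    blocks = [_BlockProposal(idx, label, precond(label, idx)) for label, idx in model.blocks]
    if overdisperse:
        # overdispersed start, scaled per block so the jitter is large relative
        # to the posterior spread but not astronomically far in flat directions
        z0 = z0.copy()
        for b in blocks:
            z0[b.idx] += 4.0 * b.scale * (b.chol @ rng.standard_normal(len(b.idx)))
    lp = model.log_posterior_unconstrained(z0)
    if not math.isfinite(lp):
        raise InitializationError(
            f"non-finite log posterior ({lp}) at the initial state {z0!r}; "
            "check the data and starting values"
        )
    z = z0.copy()
    kept = np.empty((config.n_retained, model.n_params))
    n_total = config.burn_in + config.n_iter
    hist_len = min(config.burn_in, 2000)
    history = np.empty((hist_len, model.n_params)) if config.burn_in else None
    hist_fill = 0
    k = 0
    for it in range(n_total):
        burn = it < config.burn_in
        for b in blocks:
            znew = b.propose(z, rng)
            lpnew = model.log_posterior_unconstrained(znew)
            accept = math.log(rng.random()) < lpnew - lp if math.isfinite(lpnew) else False
            if accept:
                z, lp = znew, lpnew
            if burn:
                b.tries += 1
                b.accepts += accept
            else:
                b.post_tries += 1
                b.post_accepts += accept
        if burn and history is not None:
            history[hist_fill % hist_len] = z
            hist_fill += 1
            if (it + 1) % config.adapt_window == 0:
                filled = history[: min(hist_fill, hist_len)]
                for b in blocks:
                    b.adapt_scale()
                    b.adapt_covariance(filled)
        if not burn and (it - config.burn_in) % config.thin == config.thin - 1:
            kept[k] = model.to_constrained(z)
            k += 1
    rates = {
        b.label: (b.post_accepts / b.post_tries if b.post_tries else float("nan"))
        for b in blocks
    }
    return kept[:k], rates


def run_chains(model, config: ChainConfig = ChainConfig()) -> PosteriorSamples:
    """Run independent chains from overdispersed starts; fully seed-reproducible.

    ``model`` is any object with ``n_params``, ``param_names``, ``blocks``,
    ``initial_state``, ``to_constrained`` and ``log_posterior_unconstrained``
    (see ``regression.restrict_model``).  Chain 1 starts at data-informed
    values; later chains at overdispersed jitters of them, which makes the
    Gelman-Rubin diagnostic meaningful.
    """
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.n_chains)
    all_draws = []
    rates_acc: dict[str, list[float]] = {}
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        z0 = model.initial_state()
        kept, rates = _run_single_chain(model, config, z0, rng, overdisperse=c > 0)
        all_draws.append(kept)
        for lab, r in rates.items():
            rates_acc.setdefault(lab, []).append(r)
    draws = np.stack(all_draws)
    mean_rates = {lab: float(np.nanmean(v)) for lab, v in rates_acc.items()}
    return PosteriorSamples(
        draws=draws,
        parameter_names=list(model.param_names),
        config=config,
        acceptance_rates=mean_rates,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def _psrf_one(chains: np.ndarray) -> float:
    """Corrected (df-adjusted) potential scale reduction factor.

    ``chains``: (m, n) array.  Uses the between/within variance ratio with
    the Brooks-Gelman degrees-of-freedom correction sqrt((d+3)/(d+1) * Vhat/W).
    """
    m, n = chains.shape
    means = chains.mean(axis=1)
    variances = chains.var(axis=1, ddof=1)
    W = variances.mean()
    B_over_n = np.var(means, ddof=1)  # = B / n
    vhat = (n - 1) / n * W + (1 + 1 / m) * B_over_n
    if W <= 0:
        return 1.0 if vhat <= 0 else float("inf")
    # method-of-moments df of the pooled variance estimate
    var_w = np.var(variances, ddof=1) / m if m > 1 else 0.0
    var_b = 2 * B_over_n**2 / (m - 1)
    cov_wb = (n / m) * (
        _cov(variances, means**2) - 2 * means.mean() * _cov(variances, means)
    )
    var_vhat = (
        ((n - 1) / n) ** 2 * var_w
        + ((m + 1) / m) ** 2 * var_b
        + 2 * ((m + 1) * (n - 1) / (m * n)) * cov_wb / n
    )
    d = 2 * vhat**2 / var_vhat if var_vhat > 0 else math.inf
    correction = (d + 3) / (d + 1) if math.isfinite(d) else 1.0
    return float(math.sqrt(max(correction * vhat / W, 0.0)))


def _cov(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2:
        return 0.0
    return float(np.cov(a, b, ddof=1)[0, 1])


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """Per-parameter corrected scale reduction factor; near 1 at convergence."""
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    if samples.n_draws < 10:
        raise ValueError("Gelman-Rubin diagnostic needs at least 10 retained draws")
    vals = [_psrf_one(samples.draws[:, :, j]) for j in range(len(samples.parameter_names))]
    return pd.Series(vals, index=samples.parameter_names, name="psrf")


def _batch_means_se(x: np.ndarray) -> float:
    """Batch-means MC standard error of the mean of one series."""
    n = len(x)
    b = max(int(math.ceil(math.sqrt(n))), 2)
    nb = n // b
    if nb < 2:
        return float(np.std(x, ddof=1) / math.sqrt(n))
    means = x[: nb * b].reshape(nb, b).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(nb))


def mc_error(samples: PosteriorSamples) -> ConvergenceReport:
    """Batch-means Monte-Carlo standard errors plus the PSRF report.

    The rule of thumb ``mc_error < 0.1 x posterior SD`` is evaluated per
    parameter.  Uses ceil(sqrt(N)) batches per chain; chain-level standard
    errors combine as for a mean of independent chain means.
    """
    if samples.n_chains * samples.n_draws < 30:
        raise ValueError("MC error estimation needs at least 30 retained draws")
    names = samples.parameter_names
    se = np.empty(len(names))
    for j in range(len(names)):
        per_chain = [_batch_means_se(samples.draws[c, :, j]) for c in range(samples.n_chains)]
        se[j] = math.sqrt(float(np.mean(np.square(per_chain))) / samples.n_chains)
    sd = samples.pooled().std(axis=0, ddof=1)
    mc = pd.Series(se, index=names, name="mc_error")
    ok = pd.Series(se < 0.1 * np.maximum(sd, 1e-300), index=names, name="mc_error_ok")
    if samples.n_chains >= 2 and samples.n_draws >= 10:
        psrf = gelman_rubin(samples)
    else:
        psrf = pd.Series(np.nan, index=names, name="psrf")
    psrf_vals = psrf.to_numpy()
    max_psrf = float(np.nanmax(psrf_vals)) if np.any(np.isfinite(psrf_vals)) else float("nan")
    return ConvergenceReport(psrf=psrf, mc_error=mc, mc_error_ok=ok, max_psrf=max_psrf)


def summarize(samples: PosteriorSamples, derived: dict | None = None) -> pd.DataFrame:
    """Posterior summary table: mean, median, SD, 2.5% and 97.5% percentiles.

    Chains are pooled after thinning.  ``derived`` maps names to callables
    that receive a dict of parameter-name -> pooled draw vector and return a
    per-draw vector; derived quantities are summarised from their per-draw
    transforms, never from transformed summaries.
    """
    pooled = samples.pooled()
    if pooled.size == 0:
        raise ValueError("cannot summarise empty samples")
    columns = {name: pooled[:, j] for j, name in enumerate(samples.parameter_names)}
    if derived:
        for name, fn in derived.items():
            columns[name] = np.asarray(fn(columns), dtype=float)
    rows = []
    for name, x in columns.items():
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "median": float(np.median(x)),
                "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                "q2.5": float(np.percentile(x, 2.5)),
                "q97.5": float(np.percentile(x, 97.5)),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def autocorrelation(samples: PosteriorSamples, parameter: str, max_lag: int) -> np.ndarray:
    """Sample ACF at lags 0..max_lag, computed per chain then averaged."""
    if max_lag >= samples.n_draws:
        raise ValueError("max_lag must be smaller than the number of retained draws")
    acfs = []
    for c in range(samples.n_chains):
        x = samples.parameter(parameter)[c]
        x = x - x.mean()
        denom = float(np.dot(x, x))
        if denom == 0.0:
            raise ValueError(f"parameter {parameter!r} is constant; ACF undefined")
        full = np.correlate(x, x, mode="full")[len(x) - 1 :]
        acfs.append(full[: max_lag + 1] / denom)
    return np.mean(acfs, axis=0)
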