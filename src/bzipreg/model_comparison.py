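"""Deviance information criterion (DIC) and model comparison.

DIC = Dbar + pD, where the deviance is D(theta) = -2 log L(data | theta),
Dbar is its posterior mean over retained draws, and the effective number of
parameters pD = Dbar - D(theta_bar) plugs in the posterior mean of each
parameter on its reporting scale (coefficients and alpha as sampled, p0 on
(0, 1)).  Deviances use the full log-likelihood including the y! terms, so
DIC values are comparable across all six model families on the same data.
Lower DIC is better.  Two independently fitted univariate models are
combined by summing their (pD, Dbar, DIC) component-wise, which is how a
double-Poisson or double-ZIP fit is scored against the bivariate models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples

logger = logging.getLogger(__name__)

__all__ = ["DICResult", "compute_dic", "sum_independent_dics", "comparison_table"]


@dataclass(frozen=True)
class DICResult:
    """(pD, Dbar, DIC) triple for one fitted model."""

    model_label: str
    p_d: float
    d_bar: float
    dic: float

    def to_dict(self) -> dict:
        return {"model": self.model_label, "pD": self.p_d, "Dbar": self.d_bar, "DIC": self.dic}


def compute_dic(samples: PosteriorSamples, model, label: str | None = None) -> DICResult:
    """DIC of a fitted model from its posterior draws.

    ``model`` must expose ``log_likelihood_constrained`` over the same
    parameter vector layout as ``samples`` (the object that generated the
    draws).  A negative pD is reported with a warning — it signals a poorly
    behaved posterior (e.g. multimodality), not an arithmetic error.
    """
    pooled = samples.pooled()
    if list(samples.parameter_names) != list(model.param_names):
        raise ValueError("samples and model disagree on the parameter layout")
    deviances = np.array(
        [-2.0 * model.log_likelihood_constrained(theta) for theta in pooled]
    )
    d_bar = float(np.mean(deviances))
    theta_bar = pooled.mean(axis=0)
    d_at_mean = -2.0 * model.log_likelihood_constrained(theta_bar)
    p_d = d_bar - d_at_mean
    if p_d < 0:
        logger.warning("negative effective number of parameters pD=%.3f for %s", p_d, label)
    return DICResult(
        model_label=label or getattr(model, "family", "model"),
        p_d=p_d,
        d_bar=d_bar,
        dic=d_bar + p_d,
    )


def sum_independent_dics(results: list[DICResult], label: str | None = None) -> DICResult:
    """Combine independently fitted models by component-wise summation."""
    if not results:
        raise ValueError("need at least one DICResult to sum")
    return DICResult(
        model_label=label or " + ".join(r.model_label for r in results),
        p_d=sum(r.p_d for r in results),
        d_bar=sum(r.d_bar for r in results),
        dic=sum(r.dic for r in results),
    )


def comparison_table(results: list[DICResult]) -> pd.DataFrame:
    """Comparison table sorted ascending by DIC (ties broken by label).

    The lowest-DIC row is flagged as preferred.
    """
    if not results:
        raise ValueError("need at least one DICResult")
    df = pd.DataFrame([r.to_dict() for r in results])
    df = df.sort_values(["DIC", "model"], kind="mergesort").reset_index(drop=True)
    df["preferred"] = False
    df.loc[0, "preferred"] = True
    return df
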