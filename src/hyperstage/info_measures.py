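"""Information-theoretic quantities driving structure learning.

Per-gene mutual information with the stage label ranks single variables for
hyperedge sampling; the Gaussian total correlation (multi-information) of a
member set, and its class-conditional expectation, yield the multivariate
mutual information (MMI) used for initial hyperedge weights.

All quantities are in nats.  The default estimator is the moment-matched
Gaussian closed form on (ridge-regularized) sample covariances — fast,
deterministic and exact for Gaussian data; an equal-frequency-binning
plug-in estimator is available for the per-gene MI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_RIDGE_EPS,
    DEFAULT_SIGMA_MIN,
    DegenerateStageError,
    ParameterError,
    StageLabelError,
)

__all__ = [
    "MIVector",
    "gene_stage_mi",
    "selection_distribution",
    "gaussian_total_correlation",
    "multivariate_mi_with_class",
]


@dataclass
class MIVector:
    """Per-feature MI with the stage label, aligned with feature ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids and values must have equal length")
        self.values = np.maximum(self.values, 0.0)


def _check_labels(labels: np.ndarray) -> list:
    stages = sorted(set(labels))
    if len(stages) < 2:
        raise StageLabelError("need at least two stages to compute MI")
    return stages


def gene_stage_mi(
    values,
    labels,
    *,
    backend: str = "gaussian",
    bins: int = 8,
    sigma_min: float = DEFAULT_SIGMA_MIN,
) -> float:
    """Mutual information I(X;Y) between one gene and the stage label.

    Gaussian backend (default): moment-matched closed form
    ``0.5*ln(var_marginal) - sum_y p(y)*0.5*ln(var_y)`` with variances
    floored at ``sigma_min**2``; negative estimates are clamped to 0.
    ``backend="binning"``: equal-frequency discretization into ``bins``
    bins followed by the discrete plug-in MI.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(l) for l in np.asarray(labels)])
    stages = _check_labels(labels)
    n = values.shape[0]
    if backend == "gaussian":
        floor = sigma_min**2
        h_marg = 0.5 * np.log(max(values.var(ddof=0), floor))
        h_cond = 0.0
        for y in stages:
            sel = values[labels == y]
            if sel.shape[0] < 2:
                raise DegenerateStageError(f"stage {y!r} has < 2 samples")
            h_cond += (sel.shape[0] / n) * 0.5 * np.log(max(sel.var(ddof=0), floor))
        return max(h_marg - h_cond, 0.0)
    if backend == "binning":
        binned = pd.qcut(values, q=min(bins, n), labels=False, duplicates="drop")
        if np.unique(binned[~np.isnan(binned)]).size < 2:
            return 0.0  # constant (or near-constant) gene carries no information
        from sklearn.metrics import mutual_info_score

        return max(float(mutual_info_score(labels, binned)), 0.0)
    raise ParameterError(f"unknown MI backend {backend!r}")


def selection_distribution(mi: MIVector | np.ndarray, eta: float) -> np.ndarray:
    """Gene-selection probabilities P_I(X_i) = I(X_i;Y)^eta / sum_j I(X_j;Y)^eta.

    ``eta`` regularizes how strongly MI biases the sampling; eta = 0 gives
    the uniform distribution (so does an all-zero MI vector).
    """
    if eta < 0:
        raise ParameterError(f"eta must be non-negative, got {eta}")
    values = mi.values if isinstance(mi, MIVector) else np.asarray(mi, dtype=float)
    if values.size == 0:
        raise ParameterError("empty MI vector")
    values = np.maximum(values, 0.0)
    if eta == 0 or not np.any(values > 0):
        return np.full(values.shape, 1.0 / values.size)
    powered = values**eta
    return powered / powered.sum()


def gaussian_total_correlation(cov: np.ndarray) -> float:
    """Total correlation of a Gaussian: TC = 0.5*ln(prod_i cov_ii / det cov).

    Depends only on the correlation structure (invariant to per-variable
    rescaling); clamped at 0 against numerical round-off.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got shape {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    diag = np.diag(cov)
    if np.any(diag <= 0):
        raise ValueError("covariance must have positive diagonal")
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise ValueError("covariance must be positive definite (after ridge)")
    return max(0.5 * (np.log(diag).sum() - logdet), 0.0)


def multivariate_mi_with_class(
    submatrix: np.ndarray,
    labels,
    *,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
) -> float:
    """Multivariate MI of a member set with the class:

    I(X_1..X_k; Y) = I(X_1..X_k) - E_Y[ I(X_1..X_k) | Y ],

    i.e. the marginal total correlation minus its class-conditional
    expectation, both under the Gaussian plug-in estimator with empirical
    class priors.  May be negative (interaction-information style) and is
    deliberately not clamped.
    """
    sub = np.asarray(submatrix, dtype=float)
    if sub.ndim != 2 or sub.shape[1] < 2:
        raise ValueError("need a samples x (>=2 members) matrix")
    labels = np.asarray([str(l) for l in np.asarray(labels)])
    if labels.shape[0] != sub.shape[0]:
        raise ValueError("labels length must match the number of samples")
    stages = _check_labels(labels)
    n, k = sub.shape
    eye = ridge_eps * np.eye(k)
    marg = np.cov(sub.T, ddof=0) + eye
    tc = gaussian_total_correlation((marg + marg.T) / 2.0)
    cond = 0.0
    for y in stages:
        sel = sub[labels == y]
        if sel.shape[0] < k + 1:
            warnings.warn(
                f"stage {y!r} has {sel.shape[0]} samples for {k} members; "
                "the ridge term dominates the conditional covariance",
                stacklevel=2,
            )
        c = np.cov(sel.T, ddof=0) + eye
        cond += (sel.shape[0] / n) * gaussian_total_correlation((c + c.T) / 2.0)
    return float(tc - cond)
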