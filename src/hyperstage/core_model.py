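"""Hypergraph data model and the forward (classification) path.

A hypergraph-based model is a population of *hyperedges*.  Each hyperedge
joins a small set of miRNAs and mRNAs and carries, for every cancer stage
``y``, the stage-conditional mean vector, per-variable standard deviations,
full covariance of its members, and a scalar weight ``w(e_i|y)``.  A profile
``(x, z)`` is scored against a stage by summing, over all hyperedges, the
product of the stage weight and a Gaussian-kernel *matching probability*

    P(u=1 | x, z, e_i|y) = exp(-beta * d(x, z, e_i|y)),

where ``d`` is the normalized subdimensional distance between the profile
and the hyperedge's stage statistics.  The predicted stage is the argmax of
the stage scores; a posterior is obtained by a sigmoid of the mean-centered
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "StageStats",
    "Hyperedge",
    "Hypergraph",
    "MatchResult",
    "UnknownFeatureError",
    "DegenerateStageError",
    "StageLabelError",
    "ParameterError",
    "fit_hyperedge_stats",
    "match_probability",
    "stage_score",
    "predict_stage",
    "stage_posterior",
]

DEFAULT_SIGMA_MIN = 1e-6
DEFAULT_RIDGE_EPS = 1e-6


class UnknownFeatureError(KeyError):
    """A referenced feature identifier does not exist in the dataset."""


class DegenerateStageError(ValueError):
    """A stage has too few samples to estimate the required statistics."""


class StageLabelError(KeyError):
    """A stage label is not part of the model's (or dataset's) stage set."""


class ParameterError(ValueError):
    """A tunable parameter is outside its admissible range."""


@dataclass
class ExpressionDataset:
    """Matched miRNA/mRNA expression matrices with per-sample stage labels.

    Both matrices are features x samples :class:`pandas.DataFrame` objects
    sharing the same sample columns (same order); ``labels`` is indexed by
    sample id.  Stage labels are coerced to ``str`` so they survive JSON
    round-trips unchanged.
    """

    mirna: pd.DataFrame
    mrna: pd.DataFrame
    labels: pd.Series

    _row_of: dict[str, tuple[str, int]] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )
    _values: np.ndarray | None = field(
        init=False, repr=False, compare=False, default=None
    )

    def __post_init__(self) -> None:
        if list(self.mirna.columns) != list(self.mrna.columns):
            raise ValueError(
                "miRNA and mRNA matrices must share the same samples in the "
                "same order; align them with io.read_expression_pair"
            )
        if len(self.labels) != self.mirna.shape[1]:
            raise ValueError(
                f"label count ({len(self.labels)}) does not match sample "
                f"count ({self.mirna.shape[1]})"
            )
        self.labels = self.labels.astype(str)
        if list(self.labels.index) != list(self.mirna.columns):
            raise ValueError("labels must be indexed by the matrix sample ids")
        dup = set(self.mirna.index) & set(self.mrna.index)
        if dup:
            raise ValueError(f"feature ids shared between blocks: {sorted(dup)[:5]}")
        for df in (self.mirna, self.mrna):
            if df.index.has_duplicates:
                raise ValueError("duplicate feature ids within a block")
        # note: a container may legitimately hold a single stage (e.g. the
        # literal threshold-rule draw is ~all one class); operations that
        # need >= 2 stages (MI, fitting, training) enforce it themselves

    # -- lookup helpers -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.mirna.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mirna.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.mirna.index)

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.mrna.index)

    @property
    def stages(self) -> list[str]:
        """Stage label set Y in its fixed (sorted) order."""
        return sorted(set(self.labels))

    def _ensure_index(self) -> None:
        if not self._row_of:
            for i, fid in enumerate(self.mirna.index):
                self._row_of[str(fid)] = ("miRNA", i)
            off = self.mirna.shape[0]
            for i, fid in enumerate(self.mrna.index):
                self._row_of[str(fid)] = ("mRNA", off + i)

    def block_of(self, feature_id: str) -> str:
        """Return ``"miRNA"`` or ``"mRNA"`` for a feature id."""
        self._ensure_index()
        try:
            return self._row_of[str(feature_id)][0]
        except KeyError:
            raise UnknownFeatureError(feature_id) from None

    def row_index(self, feature_id: str) -> int:
        """Row of the feature in the stacked (miRNA above mRNA) matrix."""
        self._ensure_index()
        try:
            return self._row_of[str(feature_id)][1]
        except KeyError:
            raise UnknownFeatureError(feature_id) from None

    @property
    def values(self) -> np.ndarray:
        """Stacked expression values, samples x (miRNA + mRNA features)."""
        if self._values is None:
            self._values = np.vstack(
                [self.mirna.to_numpy(float), self.mrna.to_numpy(float)]
            ).T.copy()
        return self._values

    def submatrix(self, members: Sequence[str]) -> np.ndarray:
        """samples x members value matrix for the given feature ids."""
        idx = [self.row_index(m) for m in members]
        return self.values[:, idx]

    def profile(self, sample: int | str) -> pd.Series:
        """A single sample's paired expression vector, indexed by feature id."""
        if isinstance(sample, str):
            sample = self.sample_ids.index(sample)
        ids = self.mirna_ids + self.mrna_ids
        return pd.Series(self.values[sample], index=ids)

    def subset(self, sample_indices: Sequence[int]) -> "ExpressionDataset":
        """Dataset restricted to the given sample positions (e.g. a CV fold)."""
        cols = [self.sample_ids[i] for i in sample_indices]
        return ExpressionDataset(
            mirna=self.mirna[cols],
            mrna=self.mrna[cols],
            labels=self.labels.loc[cols],
        )


@dataclass
class StageStats:
    """Stage-conditional statistics of a hyperedge's member variables."""

    mean: np.ndarray
    sd: np.ndarray
    cov: np.ndarray


@dataclass
class Hyperedge:
    """A candidate miRNA-mRNA module: members, per-stage statistics, weights."""

    mirna_members: tuple[str, ...]
    mrna_members: tuple[str, ...]
    stats: dict[str, StageStats]
    weights: dict[str, float]
    mmi: float = 0.0

    def __post_init__(self) -> None:
        members = self.members
        if len(members) < 2:
            raise ValueError("a hyperedge needs at least two member variables")
        if len(set(members)) != len(members):
            raise ValueError("hyperedge members must be unique")

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.mirna_members) + tuple(self.mrna_members)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)

    @property
    def degree(self) -> int:
        return len(self.members)


@dataclass
class Hypergraph:
    """The classifier: a population of hyperedges over a fixed stage set."""

    hyperedges: list[Hyperedge]
    stages: list[str]
    config: Any = None

    def __post_init__(self) -> None:
        for e in self.hyperedges:
            missing = set(self.stages) - set(e.stats)
            if missing:
                raise ValueError(f"hyperedge missing stats for stages {missing}")

    def __len__(self) -> int:
        return len(self.hyperedges)

    @property
    def beta(self) -> float:
        return getattr(self.config, "beta", 1.0)


@dataclass(frozen=True)
class MatchResult:
    """Normalized subdimensional distance and the matching probability."""

    distance: float
    probability: float


def _profile_value(profile: Mapping[str, float] | pd.Series, member: str) -> float:
    try:
        return float(profile[member])
    except KeyError:
        raise UnknownFeatureError(member) from None


def fit_hyperedge_stats(
    dataset: ExpressionDataset,
    mirna_members: Iterable[str],
    mrna_members: Iterable[str],
    *,
    sigma_min: float = DEFAULT_SIGMA_MIN,
    ridge_eps: float = DEFAULT_RIDGE_EPS,
) -> Hyperedge:
    """Estimate a hyperedge's per-stage mean/SD/covariance from a dataset.

    Statistics are computed on each stage's samples only, with the population
    (n-denominator) SD estimator.  SDs are floored at ``sigma_min`` and the
    covariance is ridge-regularized with ``ridge_eps * I`` so the matching
    distance and the Gaussian information measures stay finite on degenerate
    features.  Weights are initialized to zero; the learner assigns them.
    """
    mirna_members = tuple(str(m) for m in mirna_members)
    mrna_members = tuple(str(m) for m in mrna_members)
    for m in mirna_members:
        if dataset.block_of(m) != "miRNA":
            raise UnknownFeatureError(f"{m} is not a miRNA feature")
    for m in mrna_members:
        if dataset.block_of(m) != "mRNA":
            raise UnknownFeatureError(f"{m} is not an mRNA feature")
    members = mirna_members + mrna_members
    sub = dataset.submatrix(members)  # samples x k
    labels = dataset.labels.to_numpy()
    k = len(members)
    stats: dict[str, StageStats] = {}
    weights: dict[str, float] = {}
    for stage in dataset.stages:
        sel = sub[labels == stage]
        if sel.shape[0] < 2:
            raise DegenerateStageError(
                f"stage {stage!r} has {sel.shape[0]} sample(s); need >= 2"
            )
        mean = sel.mean(axis=0)
        sd = np.maximum(sel.std(axis=0, ddof=0), sigma_min)
        cov = np.cov(sel.T, ddof=0).reshape(k, k) + ridge_eps * np.eye(k)
        cov = (cov + cov.T) / 2.0
        stats[stage] = StageStats(mean=mean, sd=sd, cov=cov)
        weights[stage] = 0.0
    return Hyperedge(
        mirna_members=mirna_members,
        mrna_members=mrna_members,
        stats=stats,
        weights=weights,
    )


def match_probability(
    profile: Mapping[str, float] | pd.Series,
    edge: Hyperedge,
    stage: str,
    beta: float,
) -> MatchResult:
    """Gaussian-kernel matching probability of a profile against a hyperedge.

    d = (1/|e_i|) * sqrt( sum_j ((v_j - mu_j) / sigma_j|y)^2 ) over the
    hyperedge's members, and P(u=1) = exp(-beta * d).  The 1/|e_i|
    normalizer multiplies outside the square root.
    """
    if beta <= 0:
        raise ParameterError(f"beta must be positive, got {beta}")
    stage = str(stage)
    if stage not in edge.stats:
        raise StageLabelError(stage)
    st = edge.stats[stage]
    v = np.array([_profile_value(profile, m) for m in edge.members])
    z = (v - st.mean) / st.sd
    d = math.sqrt(float(np.dot(z, z))) / edge.degree
    return MatchResult(distance=d, probability=math.exp(-beta * d))


def stage_score(
    profile: Mapping[str, float] | pd.Series,
    model: Hypergraph,
    stage: str,
    beta: float | None = None,
) -> float:
    """Evidence for a stage: c_y = sum_i w(e_i|y) * P(u=1|x,z,e_i|y)."""
    if not model.hyperedges:
        raise ValueError("model has no hyperedges")
    stage = str(stage)
    if stage not in model.stages:
        raise StageLabelError(stage)
    b = model.beta if beta is None else beta
    return float(
        sum(
            e.weights[stage] * match_probability(profile, e, stage, b).probability
            for e in model.hyperedges
        )
    )


def predict_stage(
    profile: Mapping[str, float] | pd.Series,
    model: Hypergraph,
    beta: float | None = None,
) -> str:
    """argmax stage score; exact ties go to the first stage in Y's order."""
    scores = [stage_score(profile, model, y, beta) for y in model.stages]
    return model.stages[int(np.argmax(scores))]


def stage_posterior(
    profile: Mapping[str, float] | pd.Series,
    model: Hypergraph,
    stage: str,
    beta: float | None = None,
) -> float:
    """P(y|x,z,H) = logistic(c_y - mean_y' c_y'), strictly inside (0,1).

    The sigmoid is oriented so that more evidence for a stage yields a
    larger posterior; mean-centering makes it invariant to adding a
    constant to every stage score.
    """
    scores = np.array([stage_score(profile, model, y, beta) for y in model.stages])
    stage = str(stage)
    c = scores[model.stages.index(stage)]
    from scipy.special import expit

    return float(expit(c - scores.mean()))
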