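"""Two-phase iterative learning of the hypergraph-based model.

Structure learning is evolutionary: hyperedges are sampled with per-gene
MI-biased selection probabilities, receive an initial weight combining the
multivariate MI of their member set with the class and the sum of
stage-conditional inverse variances, and the lowest-weight fraction of the
population is replaced each iteration at a rate decaying from ``R_max`` to
``R_min``.  Parameter learning refines the per-stage weights by batch
gradient descent on the squared posterior error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

from .core_model import (
    ExpressionDataset,
    Hyperedge,
    Hypergraph,
    ParameterError,
    StageLabelError,
    fit_hyperedge_stats,
)
from .info_measures import (
    MIVector,
    gene_stage_mi,
    multivariate_mi_with_class,
    selection_distribution,
)

__all__ = [
    "LearningConfig",
    "TrainTrace",
    "sample_hyperedge",
    "initial_weight",
    "parameter_update_epoch",
    "replacement_ratio",
    "replace_hyperedges",
    "train",
    "predict_dataset",
    "compute_mi_vectors",
]


@dataclass
class LearningConfig:
    """All tunables of the learner.

    ``l`` and ``m`` are the miRNA/mRNA degrees of every hyperedge; with
    ``pooled_selection`` the two pools are merged and only the total degree
    ``l + m`` is fixed (the per-edge split floats), which suits data whose
    miRNA/mRNA partition is nominal — e.g. the threshold-rule simulation.
    """

    l: int = 3
    m: int = 5
    n_hyperedges: int = 200
    structure_epochs: int = 100
    parameter_epochs: int = 20
    beta: float = 1.0
    eta: float = 1.0
    kappa: float = 1.0
    gamma: float = 1.0
    r_max: float = 0.9
    r_min: float = 0.5
    sigma_min: float = 1e-6
    ridge_eps: float = 1e-6
    mi_backend: str = "gaussian"
    mi_bins: int = 8
    batch_updates: bool = True
    pooled_selection: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= self.r_max <= 1):
            raise ParameterError(
                f"need 0 < r_min <= r_max <= 1, got {self.r_min}, {self.r_max}"
            )
        if self.l + self.m < 2:
            raise ParameterError("hyperedge degree l + m must be >= 2")
        if self.beta <= 0:
            raise ParameterError("beta must be positive")
        for name in ("eta", "kappa", "gamma"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class TrainTrace:
    """Per-structure-iteration diagnostics of a training run.

    ``initial_mean_mmi`` is the population mean MMI right after
    initialization, before any replacement, the baseline against which the
    per-iteration ``mean_mmi`` trace shows the effect of structure search.
    """

    mean_mmi: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    replacement_ratio: list[float] = field(default_factory=list)
    initial_mean_mmi: float = float("nan")


# ---------------------------------------------------------------------------
# vectorized forward path (shared by training and batch prediction)
# ---------------------------------------------------------------------------


def _member_index_matrix(model: Hypergraph, dataset: ExpressionDataset) -> np.ndarray:
    return np.array(
        [[dataset.row_index(m) for m in e.members] for e in model.hyperedges]
    )


def _stat_arrays(model: Hypergraph, dataset: ExpressionDataset):
    """(mu, sd, w) arrays: mu/sd are (stages, edges, degree), w is (edges, stages)."""
    stages = model.stages
    mu = np.array([[e.stats[y].mean for e in model.hyperedges] for y in stages])
    sd = np.array([[e.stats[y].sd for e in model.hyperedges] for y in stages])
    w = np.array([[e.weights[y] for y in stages] for e in model.hyperedges])
    return mu, sd, w


def _match_matrix(
    X: np.ndarray, idx: np.ndarray, mu: np.ndarray, sd: np.ndarray, beta: float
) -> np.ndarray:
    """P[s, n, e] = exp(-beta * d) for every stage, sample and hyperedge."""
    V = X[:, idx]  # n x E x k
    k = idx.shape[1]
    P = np.empty((mu.shape[0], X.shape[0], idx.shape[0]))
    for s in range(mu.shape[0]):
        Z = (V - mu[s][None, :, :]) / sd[s][None, :, :]
        D = np.sqrt((Z**2).sum(axis=2)) / k
        P[s] = np.exp(-beta * D)
    return P


def _scores(P: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stage scores C[n, y] = sum_e w[e, y] * P[y, n, e]."""
    return np.stack([P[s] @ w[:, s] for s in range(P.shape[0])], axis=1)


def _posteriors(C: np.ndarray) -> np.ndarray:
    return expit(C - C.mean(axis=1, keepdims=True))


def predict_dataset(model: Hypergraph, dataset: ExpressionDataset) -> np.ndarray:
    """Vectorized prediction of every sample's stage (first-wins ties)."""
    idx = _member_index_matrix(model, dataset)
    mu, sd, w = _stat_arrays(model, dataset)
    P = _match_matrix(dataset.values, idx, mu, sd, model.beta)
    C = _scores(P, w)
    return np.array([model.stages[i] for i in C.argmax(axis=1)])


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------


def compute_mi_vectors(
    dataset: ExpressionDataset, config: LearningConfig
) -> tuple[MIVector, MIVector]:
    """Per-gene MI with the stage label for each block (computed once)."""
    labels = dataset.labels.to_numpy()

    def block(ids: list[str]) -> MIVector:
        vals = np.array(
            [
                gene_stage_mi(
                    dataset.submatrix([fid])[:, 0],
                    labels,
                    backend=config.mi_backend,
                    bins=config.mi_bins,
                    sigma_min=config.sigma_min,
                )
                for fid in ids
            ]
        )
        return MIVector(ids=ids, values=vals)

    return block(dataset.mirna_ids), block(dataset.mrna_ids)


def sample_hyperedge(
    mirna_dist: np.ndarray,
    mrna_dist: np.ndarray,
    l: int,
    m: int,
    rng: np.random.Generator,
    *,
    mirna_ids: Sequence[str],
    mrna_ids: Sequence[str],
    existing: Iterable[frozenset] = (),
    pooled: bool = False,
    max_tries: int = 20000,
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Draw one hyperedge's member set, without replacement, MI-biased.

    The distributions need not be normalized; they are renormalized per
    block (fixed split) or jointly (``pooled``).  Resamples while the exact
    member set already occurs in ``existing``.
    """
    if l > len(mirna_ids) or m > len(mrna_ids):
        raise ParameterError(
            f"degrees (l={l}, m={m}) exceed pool sizes "
            f"({len(mirna_ids)} miRNAs, {len(mrna_ids)} mRNAs)"
        )
    mirna_ids = list(mirna_ids)
    mrna_ids = list(mrna_ids)
    n_mi = len(mirna_ids)
    all_ids = mirna_ids + mrna_ids
    idx_of = {fid: i for i, fid in enumerate(all_ids)}
    existing_idx = {frozenset(idx_of[fid] for fid in fs) for fs in existing}
    p_mi = np.asarray(mirna_dist, dtype=float)
    p_mr = np.asarray(mrna_dist, dtype=float)

    def norm(p: np.ndarray) -> np.ndarray:
        s = p.sum()
        p = np.full(p.shape, 1.0 / p.size) if s <= 0 else p / s
        # keep zero-probability features reachable: tiny floor, renormalize
        p = np.maximum(p, 1e-12)
        return p / p.sum()

    def draw_wor(logp: np.ndarray, k: int, batch: int) -> np.ndarray:
        # Efraimidis-Spirakis via Gumbel keys: the top-k of log(p)+Gumbel
        # noise is distributed as k successive weighted draws without
        # replacement -- O(n) and vectorized over a batch of candidates
        keys = logp[None, :] - np.log(-np.log(rng.random((batch, logp.size))))
        return np.argpartition(-keys, k - 1, axis=1)[:, :k]

    if pooled:
        logp = np.log(norm(np.concatenate([p_mi, p_mr])))
    else:
        log_mi = np.log(norm(p_mi))
        log_mr = np.log(norm(p_mr))
    B = 64
    for _ in range(0, max_tries, B):
        if pooled:
            picks = draw_wor(logp, l + m, B)
        else:
            parts = []
            if l:
                parts.append(draw_wor(log_mi, l, B))
            if m:
                parts.append(draw_wor(log_mr, m, B) + n_mi)
            picks = np.hstack(parts)
        for row in picks:
            if frozenset(row.tolist()) in existing_idx:
                continue
            mirna = tuple(sorted(all_ids[i] for i in row if i < n_mi))
            mrna = tuple(sorted(all_ids[i] for i in row if i >= n_mi))
            return mirna, mrna
    raise RuntimeError(
        f"could not sample a new unique hyperedge in {max_tries} tries; "
        "the combinatorial pool is likely exhausted"
    )


def initial_weight(edge: Hyperedge, stage: str, kappa: float, mmi: float) -> float:
    """w0(e_i|y) = kappa * I(e_i) + sum_members 1 / sigma^2_{member|y}.

    ``kappa`` balances the MMI term against the inverse-variance term;
    small stage-conditional variances mark discriminative members.
    """
    st = edge.stats[str(stage)]
    return float(kappa * mmi + (1.0 / st.sd**2).sum())


def _new_edge(
    dataset: ExpressionDataset,
    config: LearningConfig,
    mirna_dist: np.ndarray,
    mrna_dist: np.ndarray,
    rng: np.random.Generator,
    existing: set[frozenset],
    cache: dict | None = None,
) -> Hyperedge:
    mirna, mrna = sample_hyperedge(
        mirna_dist,
        mrna_dist,
        config.l,
        config.m,
        rng,
        mirna_ids=dataset.mirna_ids,
        mrna_ids=dataset.mrna_ids,
        existing=existing,
        pooled=config.pooled_selection,
    )
    key = (mirna, mrna)
    hit = cache.get(key) if cache is not None else None
    if hit is not None:
        # stats and MMI depend only on (dataset, members): reuse them, but
        # give the edge its own weights dict (weights are mutable state)
        stats, mmi = hit
        edge = Hyperedge(
            mirna_members=mirna,
            mrna_members=mrna,
            stats=stats,
            weights={y: 0.0 for y in dataset.stages},
            mmi=mmi,
        )
    else:
        edge = fit_hyperedge_stats(
            dataset, mirna, mrna, sigma_min=config.sigma_min, ridge_eps=config.ridge_eps
        )
        edge.mmi = multivariate_mi_with_class(
            dataset.submatrix(edge.members),
            dataset.labels.to_numpy(),
            ridge_eps=config.ridge_eps,
        )
        if cache is not None:
            cache[key] = (edge.stats, edge.mmi)
    for y in dataset.stages:
        edge.weights[y] = initial_weight(edge, y, config.kappa, edge.mmi)
    return edge


def replacement_ratio(t: int, r_max: float, r_min: float) -> float:
    """Fraction replaced at iteration t: (R_max - R_min)*exp(-t) + R_min."""
    if r_min > r_max:
        raise ParameterError(f"R_min ({r_min}) must not exceed R_max ({r_max})")
    if t < 0:
        raise ParameterError("iteration index must be non-negative")
    return (r_max - r_min) * math.exp(-t) + r_min


def replace_hyperedges(
    model: Hypergraph,
    ratio: float,
    dataset: ExpressionDataset,
    mirna_dist: np.ndarray,
    mrna_dist: np.ndarray,
    rng: np.random.Generator,
    config: LearningConfig | None = None,
    _cache: dict | None = None,
) -> Hypergraph:
    """Replace the lowest-weight fraction of the population in place.

    The ``ceil(ratio * |H|)`` hyperedges with the smallest max-over-stages
    weight are dropped and replaced by freshly sampled, freshly fitted,
    initial-weighted ones; the population size never changes.
    """
    if not (0 <= ratio <= 1):
        raise ParameterError(f"ratio must lie in [0, 1], got {ratio}")
    config = config or model.config
    if config is None:
        raise ParameterError("replace_hyperedges needs a LearningConfig")
    n_replace = math.ceil(ratio * len(model))
    if n_replace == 0:
        return model
    max_w = np.array([max(e.weights.values()) for e in model.hyperedges])
    order = np.argsort(max_w, kind="stable")
    drop = set(order[:n_replace].tolist())
    survivors = [e for i, e in enumerate(model.hyperedges) if i not in drop]
    existing = {e.member_set for e in survivors}
    fresh: list[Hyperedge] = []
    for _ in range(n_replace):
        e = _new_edge(dataset, config, mirna_dist, mrna_dist, rng, existing, _cache)
        existing.add(e.member_set)
        fresh.append(e)
    model.hyperedges = survivors + fresh
    return model


# ---------------------------------------------------------------------------
# parameter learning
# ---------------------------------------------------------------------------


def _weight_deltas(P: np.ndarray, w: np.ndarray, labels_onehot: np.ndarray, gamma: float) -> np.ndarray:
    """Batch gradient accumulated over all samples with pre-update posteriors.

    delta_w[e, y] = gamma * sum_n P(y|n)(1-P(y|n)) (delta(y~, y) - P(y|n)) * P(u=1|n, e, y)
    """
    C = _scores(P, w)
    post = _posteriors(C)
    G = post * (1.0 - post) * (labels_onehot - post)  # n x Y
    return gamma * np.stack(
        [P[s].T @ G[:, s] for s in range(P.shape[0])], axis=1
    )


def parameter_update_epoch(
    model: Hypergraph,
    dataset: ExpressionDataset,
    gamma: float,
    *,
    batch: bool = True,
) -> Hypergraph:
    """One gradient-descent epoch over all training samples (in place).

    Batch mode (default) computes every sample's posterior with the
    pre-update weights, sums the per-sample deltas and applies them once;
    online mode applies each sample's delta immediately.
    """
    for y in set(dataset.labels) - set(model.stages):
        raise StageLabelError(f"dataset stage {y!r} absent from the model")
    idx = _member_index_matrix(model, dataset)
    mu, sd, w = _stat_arrays(model, dataset)
    P = _match_matrix(dataset.values, idx, mu, sd, model.beta)
    labels = dataset.labels.to_numpy()
    onehot = np.array([[1.0 if l == y else 0.0 for y in model.stages] for l in labels])
    if batch:
        w = w + _weight_deltas(P, w, onehot, gamma)
    else:
        for n in range(P.shape[1]):
            Pn = P[:, n : n + 1, :]
            w = w + _weight_deltas(Pn, w, onehot[n : n + 1], gamma)
    for i, e in enumerate(model.hyperedges):
        for s, y in enumerate(model.stages):
            e.weights[y] = float(w[i, s])
    return model


# ---------------------------------------------------------------------------
# the full two-phase loop
# ---------------------------------------------------------------------------


def train(
    dataset: ExpressionDataset,
    config: LearningConfig,
    progress: Callable[[int, float, float, float], None] | None = None,
) -> tuple[Hypergraph, TrainTrace]:
    """Learn a hypergraph-based model from a (normalized) training dataset.

    Initializes ``n_hyperedges`` by MI-biased sampling with MMI/variance
    initial weights, then for each structure iteration t runs
    ``parameter_epochs`` batch gradient epochs followed by replacement of
    the lowest-weight hyperedges at rate ``replacement_ratio(t)``.  The
    trace records the population's mean MMI (after replacement), the
    training accuracy (after the parameter epochs) and the replacement
    ratio, one entry per iteration.  Fully reproducible given the seed.
    """
    rng = np.random.default_rng(config.seed)
    mi_mirna, mi_mrna = compute_mi_vectors(dataset, config)
    if config.pooled_selection:
        joint = selection_distribution(
            np.concatenate([mi_mirna.values, mi_mrna.values]), config.eta
        )
        d_mirna, d_mrna = joint[: len(mi_mirna.ids)], joint[len(mi_mirna.ids) :]
    else:
        d_mirna = selection_distribution(mi_mirna, config.eta)
        d_mrna = selection_distribution(mi_mrna, config.eta)

    cache: dict = {}
    existing: set[frozenset] = set()
    edges: list[Hyperedge] = []
    for _ in range(config.n_hyperedges):
        e = _new_edge(dataset, config, d_mirna, d_mrna, rng, existing, cache)
        existing.add(e.member_set)
        edges.append(e)
    model = Hypergraph(hyperedges=edges, stages=dataset.stages, config=config)

    trace = TrainTrace(
        initial_mean_mmi=float(np.mean([e.mmi for e in model.hyperedges]))
    )
    labels = dataset.labels.to_numpy()
    onehot = np.array([[1.0 if l == y else 0.0 for y in model.stages] for l in labels])
    X = dataset.values

    def run_parameter_phase() -> tuple[np.ndarray, np.ndarray]:
        idx = _member_index_matrix(model, dataset)
        mu, sd, w = _stat_arrays(model, dataset)
        # stats are fixed during parameter learning: reuse the match matrix
        P = _match_matrix(X, idx, mu, sd, config.beta)
        if config.batch_updates:
            for _ in range(config.parameter_epochs):
                w = w + _weight_deltas(P, w, onehot, config.gamma)
        else:
            for _ in range(config.parameter_epochs):
                for n in range(P.shape[1]):
                    w = w + _weight_deltas(
                        P[:, n : n + 1, :], w, onehot[n : n + 1], config.gamma
                    )
        for i, e in enumerate(model.hyperedges):
            for s, y in enumerate(model.stages):
                e.weights[y] = float(w[i, s])
        return P, w

    for t in range(config.structure_epochs):
        P, w = run_parameter_phase()
        pred = _scores(P, w).argmax(axis=1)
        acc = float(np.mean([model.stages[c] == l for c, l in zip(pred, labels)]))
        ratio = replacement_ratio(t, config.r_max, config.r_min)
        replace_hyperedges(model, ratio, dataset, d_mirna, d_mrna, rng, config, _cache=cache)
        mean_mmi = float(np.mean([e.mmi for e in model.hyperedges]))
        trace.mean_mmi.append(mean_mmi)
        trace.train_accuracy.append(acc)
        trace.replacement_ratio.append(ratio)
        if progress is not None:
            progress(t, mean_mmi, acc, ratio)
    if config.structure_epochs > 0:
        # a final parameter phase so the hyperedges introduced by the last
        # replacement carry gradient-refined (not just initial) weights
        run_parameter_phase()
    return model, trace
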