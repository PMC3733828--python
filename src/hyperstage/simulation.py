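"""Synthetic expression data generators.

Two generators are provided:

* :func:`generate_threshold_rule_dataset` — the threshold-rule verification dataset:
  7 independent standard-normal variables, with class 1 defined by
  ``x2, x3, x4 > threshold``, class 2 by ``x5, x6, x7 < -threshold`` and
  class 3 otherwise.  With sd = 1 and threshold = 2 the literal process is
  extremely imbalanced — the tail probability of class 1 or 2 is
  ``(1 - Phi(2))^3 ~= 1.18e-5`` — so a *balanced* variant draws the three
  defining coordinates of classes 1 and 2 from conditioned (truncated)
  normals to hit exact per-class targets.  Both variants are kept so the
  imbalance of the literal rule is inspectable.

* :func:`generate_planted_expression` — a stage-labelled miRNA/mRNA matrix
  pair with planted co-regulated modules: background features are
  independent Gaussian noise in every stage, while each planted module's
  features share a stage-specific mean shift and a common latent factor
  (inducing within-module correlation) only in its designated stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_model import ExpressionDataset

__all__ = ["SimulationSpec", "PlantedModule", "generate_threshold_rule_dataset", "generate_planted_expression"]


@dataclass
class SimulationSpec:
    """Parameters of the threshold-rule verification dataset.

    ``variant="literal"`` samples unconditionally; ``"balanced"`` (the
    default, used for model verification) hits ``balance_targets`` class
    counts exactly by conditioning the defining coordinates.
    """

    n_instances: int = 500
    n_variables: int = 7
    sd: float = 1.0
    threshold: float = 2.0
    variant: str = "balanced"
    balance_targets: tuple[int, int, int] = (100, 100, 300)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variables < 7:
            raise ValueError("the threshold rule needs at least 7 variables")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.variant not in ("literal", "balanced"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "balanced" and sum(self.balance_targets) != self.n_instances:
            raise ValueError("balance targets must sum to n_instances")


def _classify(x: np.ndarray, thr: float) -> np.ndarray:
    """Apply the threshold rule row-wise (columns are x1..x7, 0-based)."""
    c1 = (x[:, 1] > thr) & (x[:, 2] > thr) & (x[:, 3] > thr)
    c2 = (x[:, 4] < -thr) & (x[:, 5] < -thr) & (x[:, 6] < -thr)
    labels = np.full(x.shape[0], "3", dtype=object)
    labels[c1] = "1"
    labels[c2 & ~c1] = "2"
    return labels.astype(str)


def _as_dataset(x: np.ndarray, labels: np.ndarray) -> ExpressionDataset:
    n, p = x.shape
    samples = [f"s{i}" for i in range(n)]
    # arbitrary block split exercising the paired-matrix interface:
    # x1..x3 play the miRNA role, x4..x7 (and any extras) the mRNA role
    var_ids = [f"x{i + 1}" for i in range(p)]
    mirna = pd.DataFrame(x[:, :3].T, index=var_ids[:3], columns=samples)
    mrna = pd.DataFrame(x[:, 3:].T, index=var_ids[3:], columns=samples)
    return ExpressionDataset(mirna=mirna, mrna=mrna, labels=pd.Series(labels, index=samples))


def _truncated(rng: np.random.Generator, lower: bool, thr: float, sd: float, size) -> np.ndarray:
    """Draw N(0, sd^2) conditioned above +thr (lower=False) or below -thr."""
    a, b = (thr / sd, np.inf) if not lower else (-np.inf, -thr / sd)
    return sps.truncnorm.rvs(a, b, scale=sd, size=size, random_state=rng)


def generate_threshold_rule_dataset(spec: SimulationSpec) -> ExpressionDataset:
    """Generate the threshold-rule dataset according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    p, thr, sd = spec.n_variables, spec.threshold, spec.sd
    if spec.n_instances == 0:
        x = np.empty((0, p))
        return _as_dataset(x, np.empty(0, dtype=str))
    if spec.variant == "literal":
        x = rng.normal(0.0, sd, size=(spec.n_instances, p))
        return _as_dataset(x, _classify(x, thr))

    n1, n2, n3 = spec.balance_targets
    rows: list[np.ndarray] = []
    labels: list[str] = []
    # classes 1 and 2: condition the defining coordinates (rejection
    # sampling on the literal path would need ~1/1.18e-5 draws per hit)
    for target, lower, cols in ((n1, False, (1, 2, 3)), (n2, True, (4, 5, 6))):
        got = 0
        while got < target:
            x = rng.normal(0.0, sd, size=(target - got, p))
            x[:, cols] = _truncated(rng, lower, thr, sd, (x.shape[0], 3))
            lab = _classify(x, thr)
            want = "1" if not lower else "2"
            keep = x[lab == want]  # guard against the ~1e-5 double-rule overlap
            rows.append(keep)
            labels.extend([want] * keep.shape[0])
            got += keep.shape[0]
    # class 3: rejection-sample the (overwhelmingly likely) "otherwise" case
    got = 0
    while got < n3:
        x = rng.normal(0.0, sd, size=(max(n3 - got, 16), p))
        keep = x[_classify(x, thr) == "3"][: n3 - got]
        rows.append(keep)
        labels.extend(["3"] * keep.shape[0])
        got += keep.shape[0]
    x = np.vstack(rows)
    lab = np.array(labels, dtype=str)
    perm = rng.permutation(x.shape[0])
    return _as_dataset(x[perm], lab[perm])


@dataclass
class PlantedModule:
    """A co-regulated module planted into one stage of the synthetic data."""

    mirna_members: tuple[str, ...]
    mrna_members: tuple[str, ...]
    stage: str
    effect_size: float = 3.0


def generate_planted_expression(
    n_per_stage: dict[str, int] | int,
    n_mirna: int,
    n_mrna: int,
    planted_modules: Sequence[PlantedModule | tuple],
    noise_sd: float = 1.0,
    seed: int = 0,
    module_correlation: float = 0.5,
) -> ExpressionDataset:
    """Stage-labelled miRNA/mRNA matrices with planted co-expressed modules.

    Background features are N(0, noise_sd^2) everywhere.  In a module's
    designated stage its members get a mean shift (miRNA members -effect,
    mRNA members +effect, the repression motif) and share a per-sample
    latent factor that replaces part of the noise, giving within-module
    correlation ``module_correlation`` while keeping each member's total
    variance at noise_sd^2 (co-regulation changes the covariance
    structure, not the noise level, of the planted genes).
    """
    rng = np.random.default_rng(seed)
    modules = [m if isinstance(m, PlantedModule) else PlantedModule(*m) for m in planted_modules]
    if isinstance(n_per_stage, int):
        stage_names = sorted({m.stage for m in modules}) or ["A", "B"]
        n_per_stage = {s: n_per_stage for s in stage_names}
    mirna_ids = [f"mir{i + 1}" for i in range(n_mirna)]
    mrna_ids = [f"gene{i + 1}" for i in range(n_mrna)]
    known = set(mirna_ids) | set(mrna_ids)
    used: set[str] = set()
    for mod in modules:
        mem = set(mod.mirna_members) | set(mod.mrna_members)
        if not mem <= known:
            raise ValueError(f"unknown planted members: {sorted(mem - known)}")
        if mem & used:
            raise ValueError(f"planted features overlap across modules: {sorted(mem & used)}")
        if mod.stage not in n_per_stage:
            raise ValueError(f"module stage {mod.stage!r} not among stages")
        used |= mem

    stages = sorted(n_per_stage)
    n_total = sum(n_per_stage[s] for s in stages)
    labels = np.concatenate([[s] * n_per_stage[s] for s in stages])
    x = rng.normal(0.0, noise_sd, size=(n_total, n_mirna + n_mrna))
    col = {fid: i for i, fid in enumerate(mirna_ids + mrna_ids)}
    if not (0 <= module_correlation < 1):
        raise ValueError("module_correlation must lie in [0, 1)")
    for mod in modules:
        sel = labels == mod.stage
        n_sel = int(sel.sum())
        factor = rng.normal(0.0, noise_sd, size=n_sel)
        lam = np.sqrt(module_correlation)
        res = np.sqrt(1.0 - module_correlation)
        for fid in mod.mirna_members + mod.mrna_members:
            shift = -mod.effect_size if fid in mod.mirna_members else mod.effect_size
            fresh = rng.normal(0.0, noise_sd, size=n_sel)
            x[sel, col[fid]] = shift + lam * factor + res * fresh
    samples = [f"s{i}" for i in range(n_total)]
    mirna = pd.DataFrame(x[:, :n_mirna].T, index=mirna_ids, columns=samples)
    mrna = pd.DataFrame(x[:, n_mirna:].T, index=mrna_ids, columns=samples)
    return ExpressionDataset(mirna=mirna, mrna=mrna, labels=pd.Series(labels, index=samples))
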