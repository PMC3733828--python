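import numpy as np
import pandas as pd
import pytest

from hyperstage import (
    ExpressionDataset,
    Hyperedge,
    Hypergraph,
    LearningConfig,
    PlantedModule,
    StageStats,
)

PLANTED_MODULES = [
    PlantedModule(("mir1",), ("gene1", "gene2"), "A"),
    PlantedModule(("mir2",), ("gene3", "gene4"), "B"),
]
PLANTED_SET_A = {"mir1", "gene1", "gene2"}
PLANTED_SET_B = {"mir2", "gene3", "gene4"}
PLANTED_FEATURES = PLANTED_SET_A | PLANTED_SET_B
# study conditions of the planted-module experiments: a 200-feature pool so
# the initial MI-biased population has room to improve, 60 samples per stage
PLANTED_KW = dict(n_per_stage=60, n_mirna=50, n_mrna=150, planted_modules=PLANTED_MODULES)
PLANTED_CONFIG = dict(l=2, m=3, n_hyperedges=60, structure_epochs=50, parameter_epochs=10)


def make_dataset(mirna_values, mrna_values, labels, mirna_ids=None, mrna_ids=None):
    """Build an ExpressionDataset from plain nested lists (features x samples)."""
    mirna_values = np.atleast_2d(np.asarray(mirna_values, float))
    mrna_values = np.atleast_2d(np.asarray(mrna_values, float))
    samples = [f"s{i}" for i in range(mirna_values.shape[1])]
    mirna_ids = mirna_ids or [f"mir{i+1}" for i in range(mirna_values.shape[0])]
    mrna_ids = mrna_ids or [f"gene{i+1}" for i in range(mrna_values.shape[0])]
    return ExpressionDataset(
        mirna=pd.DataFrame(mirna_values, index=mirna_ids, columns=samples),
        mrna=pd.DataFrame(mrna_values, index=mrna_ids, columns=samples),
        labels=pd.Series(list(labels), index=samples),
    )


def make_edge(mirna_members, mrna_members, stages, means, sds, weights, mmi=0.0):
    """Build a hyperedge with hand-specified per-stage statistics."""
    k = len(mirna_members) + len(mrna_members)
    stats = {}
    for y in stages:
        mean = np.asarray(means[y], float)
        sd = np.asarray(sds[y], float)
        stats[y] = StageStats(mean=mean, sd=sd, cov=np.diag(sd**2) + 1e-6 * np.eye(k))
    return Hyperedge(
        mirna_members=tuple(mirna_members),
        mrna_members=tuple(mrna_members),
        stats=stats,
        weights={y: float(weights[y]) for y in stages},
        mmi=mmi,
    )


@pytest.fixture
def toy_dataset():
    """2 miRNAs + 3 mRNAs, 6 samples, 2 stages, hand-pickable values."""
    rng = np.random.default_rng(42)
    mirna = rng.normal(0, 1, size=(2, 6))
    mrna = rng.normal(0, 1, size=(3, 6))
    return make_dataset(mirna, mrna, ["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def tiny_config():
    return LearningConfig(
        l=1, m=2, n_hyperedges=4, structure_epochs=3, parameter_epochs=2, seed=0
    )
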