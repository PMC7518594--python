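import numpy as np
import pytest

from omicmodules import (
    OmicMatrix,
    SampleRegistry,
    WeightingConfig,
    build_graphs,
    consensus_edge_weights,
    gmm_edge_weights,
)


class ScriptedClusterer:
    """Returns a fixed sequence of labelings, one per consensus run."""

    def __init__(self, patterns):
        self.patterns = patterns
        self.calls = 0

    def cluster(self, X, seed):
        lab = np.asarray(self.patterns[self.calls % len(self.patterns)])
        self.calls += 1
        return lab


def _single_omic(n=20, seed=0, omic_id="omic1"):
    rng = np.random.default_rng(seed)
    om = OmicMatrix(omic_id, rng.normal(size=(5, n)),
                    [f"f{i}" for i in range(5)], [f"s{i}" for i in range(n)])
    reg = SampleRegistry.from_omics([om])
    return om, reg


def _labels_from_groups(n, groups):
    lab = np.empty(n, dtype=int)
    for g, members in enumerate(groups):
        lab[list(members)] = g
    return lab


def test_consensus_weight_formula_co_clustered_pair():
    """Pair co-clustered in 40/50 runs with per-run avg 0.30, C=0.2 -> w=0.3."""
    n = 20
    # groups of sizes 9/6/4/1 -> 57 co-clustered pairs of 190 -> avg = 0.30
    A = _labels_from_groups(n, [range(0, 9), range(9, 15), range(15, 19), [19]])
    # same sizes but sample 1 swapped out of the 9-group: (0,1) separated
    B = _labels_from_groups(n, [[0, *range(2, 9), 9], [1, *range(10, 15)],
                                range(15, 19), [19]])
    om, reg = _single_omic(n)
    cfg = WeightingConfig(R=50, subsample_fraction=1.0, C=0.2,
                          base_clusterer=ScriptedClusterer([A] * 40 + [B] * 10))
    g = consensus_edge_weights(om, reg, cfg)
    assert g.weights[0, 1] == pytest.approx(0.3, abs=1e-12)


def test_consensus_weight_formula_never_co_clustered_pair():
    """Pair never co-clustered with per-run avg 0.5, C=0.2 -> w=-0.7."""
    n = 20
    # sizes 14/3/2/1 -> 95 of 190 pairs co-clustered -> avg = 0.5
    A = _labels_from_groups(n, [range(2, 16), [1, 16, 17], [0, 18], [19]])
    om, reg = _single_omic(n)
    cfg = WeightingConfig(R=50, subsample_fraction=1.0, C=0.2,
                          base_clusterer=ScriptedClusterer([A]))
    g = consensus_edge_weights(om, reg, cfg)
    assert g.weights[0, 1] == pytest.approx(-0.7, abs=1e-12)


def test_consensus_requires_min_samples():
    om, reg = _single_omic(12)
    with pytest.raises(ValueError, match=">= 20 measured"):
        consensus_edge_weights(om, reg, WeightingConfig(R=2))


def test_unmeasured_samples_have_zero_rows():
    rng = np.random.default_rng(0)
    ids_a = [f"s{i}" for i in range(25)]
    ids_b = [f"s{i}" for i in range(5, 30)]
    a = OmicMatrix("omic1", rng.normal(size=(6, 25)), [f"f{i}" for i in range(6)], ids_a)
    b = OmicMatrix("omic2", rng.normal(size=(6, 25)), [f"f{i}" for i in range(6)], ids_b)
    reg = SampleRegistry.from_omics([a, b])
    cfg = WeightingConfig(R=5, rng_seed=1)
    graphs, _ = build_graphs([a, b], reg, cfg)
    g2 = graphs[1]
    absent = ~reg.measured("omic2")
    assert absent.sum() == 5
    assert np.abs(g2.weights[absent, :]).max() == 0


def test_build_graphs_deterministic_and_shiftable(blob_dataset):
    omics, registry, labels, _ = blob_dataset
    # subsample_fraction=1 so every pair is jointly sampled in every run
    cfg = WeightingConfig(R=5, rng_seed=11, subsample_fraction=1.0)
    g1, _ = build_graphs(omics, registry, cfg)
    g2, _ = build_graphs(omics, registry, cfg)
    assert len(g1) == len(omics)
    for a, b in zip(g1, g2):
        assert a.omic_id == b.omic_id
        np.testing.assert_array_equal(a.weights, b.weights)
    shifted, _ = build_graphs(
        omics, registry,
        WeightingConfig(R=5, rng_seed=11, subsample_fraction=1.0, global_shift=0.1),
    )
    off = ~np.eye(registry.n, dtype=bool)
    np.testing.assert_allclose(shifted[0].weights[off] - g1[0].weights[off], 0.1, atol=1e-12)


def test_consensus_weight_bounds_and_blob_separation(blob_graphs):
    graphs, labels = blob_graphs
    C = 0.2
    for g in graphs:
        off = g.weights[~np.eye(g.n, dtype=bool)]
        assert off.min() >= -1 - C - 1e-12 and off.max() <= 1 - C + 1e-12
    W = graphs[0].weights
    within = W[np.ix_(labels == 0, labels == 0)]
    within = within[~np.eye(within.shape[0], dtype=bool)]
    between = W[np.ix_(labels == 0, labels == 1)]
    assert within.min() > between.max()


def test_gmm_one_hot_posterior_weights():
    """Two far blobs, uniform mixing, C=0: within-pair 0.5, across-pair -0.5."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-100, 0.1, size=(10, 4)), rng.normal(100, 0.1, size=(10, 4))])
    om = OmicMatrix("omic1", X.T, [f"f{i}" for i in range(4)], [f"s{i}" for i in range(20)])
    reg = SampleRegistry.from_omics([om])
    g, model = gmm_edge_weights(om, reg, WeightingConfig(scheme="gmm", C=0.0, n_pcs=2))
    assert model.gmm.n_components == 2
    assert g.weights[0, 1] == pytest.approx(0.5, abs=1e-3)
    assert g.weights[0, 19] == pytest.approx(-0.5, abs=1e-3)


def test_gmm_mean_weight_near_minus_C(blob_dataset):
    """Mean pair similarity ~ sum(pi^2), so the mean weight sits near -C."""
    omics, registry, labels, _ = blob_dataset
    g, model = gmm_edge_weights(omics[0], registry,
                                WeightingConfig(scheme="gmm", C=0.2, rng_seed=3))
    off = g.weights[np.triu_indices(g.n, k=1)]
    assert off.mean() == pytest.approx(-0.2, abs=0.02)


def test_gmm_frozen_model_scores_new_samples(blob_dataset):
    """A 'new' sample identical to a fitted one reproduces its weight row."""
    omics, registry, labels, _ = blob_dataset
    cfg = WeightingConfig(scheme="gmm", rng_seed=3)
    g, model = gmm_edge_weights(omics[0], registry, cfg)
    X = omics[0].samples_by_features()
    w_new = model.weights_to_train(X[:3])
    np.testing.assert_allclose(
        w_new[:, 3:], g.weights[np.ix_(model.train_idx[:3], model.train_idx[3:])], atol=1e-9
    )


def test_signed_weights_warning_on_positive_only_graph():
    from omicmodules import OmicGraph

    W = np.abs(np.random.default_rng(0).normal(size=(5, 5)))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    with pytest.warns(UserWarning, match="not signed"):
        OmicGraph("x", W, np.ones(5, dtype=bool))
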