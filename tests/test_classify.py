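import numpy as np
import pytest

from omicmodules import (
    Module,
    OmicGraph,
    SampleRegistry,
    Solution,
    WeightingConfig,
    classify_new_samples,
    classify_sample,
    gmm_edge_weights,
    sample_module_score,
    simulate,
    SimSpec,
)


def _graph(pairs, n, omic_id="omic1", measured=None):
    W = np.zeros((n, n))
    for (u, v), w in pairs.items():
        W[u, v] = W[v, u] = w
    if measured is None:
        measured = np.ones(n, dtype=bool)
    return OmicGraph(omic_id, W, measured)


def test_hand_score():
    g = _graph({(3, 0): 0.2, (3, 1): 0.1, (2, 4): -0.5}, 5)
    mod = Module({0, 1}, {"omic1"})
    assert sample_module_score(3, mod, [g]) == pytest.approx(0.3)
    parts = sample_module_score(3, mod, [g], per_omic=True)
    assert parts == {"omic1": pytest.approx(0.3)}


def test_unmeasured_sample_scores_zero():
    measured = np.array([True, True, True, False, True])
    g = _graph({(0, 1): 0.5}, 5, measured=measured)
    assert sample_module_score(3, Module({0, 1}, {"omic1"}), [g]) == 0.0


def test_member_score_equals_add_gain():
    """Scoring a member equals the gain of re-adding it after removal."""
    rng = np.random.default_rng(0)
    W = rng.normal(size=(8, 8))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    g = OmicGraph("omic1", W, np.ones(8, dtype=bool))
    mod = Module({0, 1, 2, 3}, {"omic1"})
    u = 2
    score = sample_module_score(u, mod, [g])
    assert score == pytest.approx(W[u, [0, 1, 3]].sum())


def test_classify_argmax_negative_and_zero_conventions():
    g = _graph({(4, 0): 0.2, (4, 1): 0.1, (4, 2): -0.1, (0, 2): -0.4}, 6)
    sol = Solution(6, [Module({0, 1}, {"omic1"}), Module({2, 3}, {"omic1"})], {4, 5})
    assert classify_sample(4, sol, [g]) == 0  # scores (0.3, -0.1) -> module 0
    assert classify_sample(5, sol, [g]) == 0  # score exactly 0 -> still classified
    g2 = _graph({(4, 0): -0.2, (4, 1): -0.3, (4, 2): -0.5, (0, 2): 0.4}, 6)
    sol2 = Solution(6, [Module({0, 1}, {"omic1"}), Module({2, 3}, {"omic1"})], {4, 5})
    assert classify_sample(4, sol2, [g2]) == -1  # all negative -> lonely


def test_classify_new_samples_recovers_holdout_modules():
    """Held-out samples classify to the module holding their co-members."""
    spec = SimSpec(module_sizes=[30, 30], n_outliers=0,
                   omic_names=["omic1"], features_per_omic=[60],
                   informative_features=[25], rng_seed=11)
    omics, labels, _ = simulate(spec)
    hold = [0, 1, 30, 31]
    train_ids = [s for i, s in enumerate(omics[0].sample_ids) if i not in hold]
    train = [om.subset_samples(train_ids) for om in omics]
    reg = SampleRegistry.from_omics(train)
    cfg = WeightingConfig(scheme="gmm", rng_seed=2)
    g, model = gmm_edge_weights(train[0], reg, cfg)
    lab_train = labels[[i for i in range(60) if i not in hold]]
    sol = Solution(reg.n,
                   [Module(set(np.flatnonzero(lab_train == j).tolist()), {"omic1"})
                    for j in (0, 1)],
                   set())
    hold_ids = [omics[0].sample_ids[i] for i in hold]
    new = [om.subset_samples(hold_ids) for om in omics]
    table = classify_new_samples(new, sol, [model], reg)
    assert table["module_id"].tolist() == [0, 0, 1, 1]


def test_classify_new_samples_rejects_unknown_features(blob_dataset):
    omics, registry, labels, _ = blob_dataset
    cfg = WeightingConfig(scheme="gmm", rng_seed=2)
    g, model = gmm_edge_weights(omics[0], registry, cfg)
    sol = Solution(registry.n, [Module(set(range(10)), {"omic1"})],
                   set(range(10, registry.n)))
    bad = omics[0].subset_samples(omics[0].sample_ids[:2])
    bad.feature_ids = list(reversed(bad.feature_ids))
    with pytest.raises(ValueError, match="feature ids"):
        classify_new_samples([bad], sol, [model], registry)
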