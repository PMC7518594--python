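import numpy as np
import pytest

from omicmodules import (
    SampleRegistry,
    SimSpec,
    make_partial,
    sim1_preset,
    sim2_preset,
    simulate,
)


def test_shapes_and_labels():
    spec = SimSpec(module_sizes=[10, 20], n_outliers=3, rng_seed=0)
    omics, labels, coverage = simulate(spec)
    assert labels.shape == (33,)
    assert (labels == -1).sum() == 3
    for om, p in zip(omics, spec.features_per_omic):
        assert om.values.shape == (p, 33)
    assert coverage.shape == (2, 2)


def test_planted_mean_shift_recoverable():
    """Within-module informative features sit ~effect_size*sd from background."""
    spec = SimSpec(module_sizes=[200], n_outliers=0, omic_names=["omic1"],
                   features_per_omic=[50], informative_features=[20], rng_seed=1)
    omics, labels, _ = simulate(spec)
    X = omics[0].samples_by_features()
    informative_means = np.abs(X[:, :20].mean(axis=0))
    se = spec.noise_sd / np.sqrt(200)
    assert np.all(np.abs(informative_means - spec.effect_size) < 4 * se)
    background_means = X[:, 20:].mean(axis=0)
    assert np.all(np.abs(background_means) < 4 * se)


def test_seeds_change_values_not_structure():
    a, la, _ = simulate(sim1_preset(rng_seed=1))
    b, lb, _ = simulate(sim1_preset(rng_seed=2))
    np.testing.assert_array_equal(la, lb)
    assert a[0].values.shape == b[0].values.shape
    assert not np.allclose(a[0].values, b[0].values)
    a2, _, _ = simulate(sim1_preset(rng_seed=1))
    np.testing.assert_array_equal(a[0].values, a2[0].values)


def test_sim1_preset_matches_design():
    spec = sim1_preset()
    assert spec.n_samples == 305
    assert spec.module_sizes == [60] * 5 and spec.n_outliers == 5
    np.testing.assert_array_equal(
        spec.coverage,
        [[True, False], [False, True], [True, True], [True, True], [True, True]],
    )


def test_sim2_preset_omic_counts():
    assert len(sim2_preset(True).omic_names) == 3
    assert len(sim2_preset(False).omic_names) == 2
    spec = sim2_preset(True)
    assert spec.module_sizes == [30] * 5
    assert spec.weak_omics == (1,)
    assert spec.shared_mean_groups[0] == [[0], [1, 2, 3, 4]]


def test_sim2_shared_mean_makes_modules_indistinguishable_in_omic1():
    omics, labels, _ = simulate(sim2_preset(True, rng_seed=3))
    X = omics[0].samples_by_features()
    centroids = np.stack([X[labels == j].mean(axis=0) for j in range(5)])
    d_2345 = np.linalg.norm(centroids[1] - centroids[2])
    d_1_2 = np.linalg.norm(centroids[0] - centroids[1])
    assert d_2345 < d_1_2 / 3  # modules 2-5 share one centre in omic 1


def test_make_partial_tcga_style_counts():
    spec = SimSpec(module_sizes=[100, 100, 100], n_outliers=0,
                   omic_names=["a", "b", "c"], features_per_omic=[30] * 3,
                   informative_features=[10] * 3, rng_seed=4)
    omics, labels, _ = simulate(spec)
    reg = SampleRegistry.from_omics(omics)
    new_omics, new_reg = make_partial(omics, reg, "tcga_style", 0.4, rng_seed=5)
    removed = [300 - int(new_reg.measured(o).sum()) for o in ("a", "b", "c")]
    assert removed == [40, 40, 40]
    # each removed sample lost exactly one omic
    total_measurements = sum(int(v.sum()) for v in new_reg.membership.values())
    assert total_measurements == 3 * 300 - 120
    new_reg.validate()


def test_make_partial_independent():
    spec = SimSpec(module_sizes=[50, 50], n_outliers=0, rng_seed=6)
    omics, labels, _ = simulate(spec)
    reg = SampleRegistry.from_omics(omics)
    new_omics, new_reg = make_partial(omics, reg, "independent", 0.2, rng_seed=7)
    for om in new_omics:
        assert int(new_reg.measured(om.omic_id).sum()) == 80
    anywhere = np.logical_or.reduce(list(new_reg.membership.values()))
    assert anywhere.all()  # nobody measured nowhere


def test_make_partial_fraction_zero_is_identity():
    spec = SimSpec(module_sizes=[30, 30], n_outliers=0, rng_seed=8)
    omics, labels, _ = simulate(spec)
    reg = SampleRegistry.from_omics(omics)
    new_omics, new_reg = make_partial(omics, reg, "independent", 0.0, rng_seed=9)
    for om, new in zip(omics, new_omics):
        assert om.sample_ids == new.sample_ids
        np.testing.assert_array_equal(reg.measured(om.omic_id),
                                      new_reg.measured(om.omic_id))


def test_make_partial_infeasible_removal_raises():
    spec = SimSpec(module_sizes=[30], n_outliers=0, omic_names=["only"],
                   features_per_omic=[10], informative_features=[5], rng_seed=10)
    omics, labels, _ = simulate(spec)
    reg = SampleRegistry.from_omics(omics)
    with pytest.raises(ValueError, match="no omic"):
        make_partial(omics, reg, "independent", 0.5, rng_seed=11)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="positive"):
        SimSpec(module_sizes=[0, 10])
    with pytest.raises(ValueError, match="cover at least one omic"):
        SimSpec(module_sizes=[10], coverage=np.array([[False, False]]))
    with pytest.raises(ValueError, match="informative"):
        SimSpec(module_sizes=[10], features_per_omic=[5, 5],
                informative_features=[6, 3])
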