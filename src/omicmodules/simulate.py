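"""Synthetic multi-omic datasets with planted modules and per-module omic coverage.

The generator plants modules of samples whose informative features, in the
omics the module covers, are drawn around a module-specific mean offset of
``effect_size`` noise standard deviations (a random +/- sign pattern over the
informative features). Omics a module does *not* cover carry no shared
structure for its samples: each such sample draws its informative features
around an independent, sample-specific random offset of the same magnitude,
so these samples are mutually dissimilar — a deliberate modelling choice,
since drawing them all from one fixed background distribution would itself
create a tight background cluster and hence genuine (unintended) structure.
Outliers are unstructured in every omic. Non-informative features are plain
noise for everyone.

Modules may be forced to share a mean in an omic (``shared_mean_groups``),
making them indistinguishable there, and omics can be flagged *weak* (few
informative features, smaller effect). Two presets reproduce the simulation
designs used throughout the test-suite and acceptance runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import OmicMatrix, SampleRegistry

__all__ = ["SimSpec", "simulate", "sim1_preset", "sim2_preset", "make_partial"]

_SEED_MOD = 2**31 - 1


@dataclass
class SimSpec:
    """Generative description of a planted-module multi-omic dataset."""

    module_sizes: list[int]
    n_outliers: int = 0
    omic_names: list[str] = field(default_factory=lambda: ["omic1", "omic2"])
    coverage: np.ndarray | None = None  # modules x omics bool; default all-True
    features_per_omic: list[int] | None = None  # default 100 each
    informative_features: list[int] | None = None  # default 30 each
    effect_size: float = 2.5  # mean separation, in units of noise sd
    noise_sd: float = 1.0
    weak_effect_size: float = 1.0
    weak_omics: tuple[int, ...] = ()  # omic indices flagged weak
    shared_mean_groups: dict[int, list[list[int]]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.omic_names)
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) == 0:
            raise ValueError("module sizes sum to 0")
        if self.coverage is None:
            self.coverage = np.ones((len(self.module_sizes), L), dtype=bool)
        self.coverage = np.asarray(self.coverage, dtype=bool)
        if self.coverage.shape != (len(self.module_sizes), L):
            raise ValueError("coverage must be modules x omics")
        if not self.coverage.any(axis=1).all():
            raise ValueError("every module must cover at least one omic")
        if self.features_per_omic is None:
            self.features_per_omic = [100] * L
        if self.informative_features is None:
            self.informative_features = [30] * L
        for q, p in zip(self.informative_features, self.features_per_omic):
            if q > p:
                raise ValueError("informative features cannot exceed total features")

    @property
    def n_samples(self) -> int:
        return sum(self.module_sizes) + self.n_outliers

    def omic_effect(self, l: int) -> float:
        return self.weak_effect_size if l in self.weak_omics else self.effect_size


def simulate(spec: SimSpec) -> tuple[list[OmicMatrix], np.ndarray, np.ndarray]:
    """Draw one dataset: (omic matrices, labels with outliers = -1, coverage)."""
    rng = np.random.default_rng(int(spec.rng_seed) % _SEED_MOD)
    n = spec.n_samples
    k = len(spec.module_sizes)
    labels = np.concatenate(
        [np.full(s, j, dtype=int) for j, s in enumerate(spec.module_sizes)]
        + [np.full(spec.n_outliers, -1, dtype=int)]
    )
    sample_ids = [f"s{i:04d}" for i in range(n)]
    omics = []
    for l, name in enumerate(spec.omic_names):
        p = spec.features_per_omic[l]
        q = spec.informative_features[l]
        eff = spec.omic_effect(l) * spec.noise_sd
        X = rng.normal(0.0, spec.noise_sd, size=(n, p))
        # module means for covering modules; groups share one mean
        groups = spec.shared_mean_groups.get(l, [[j] for j in range(k)])
        grouped = {j for grp in groups for j in grp}
        groups = groups + [[j] for j in range(k) if j not in grouped]
        for grp in groups:
            covering = [j for j in grp if spec.coverage[j, l]]
            if not covering:
                continue
            mu = eff * rng.choice([-1.0, 1.0], size=q)
            for j in covering:
                X[labels == j, :q] += mu
        # unstructured samples: per-sample independent offsets
        unstructured = np.flatnonzero(
            (labels == -1) | np.array([lab >= 0 and not spec.coverage[lab, l] for lab in labels])
        )
        if unstructured.size:
            X[np.ix_(unstructured, np.arange(q))] += eff * rng.choice(
                [-1.0, 1.0], size=(unstructured.size, q)
            )
        feature_ids = [f"{name}_f{j}" for j in range(p)]
        omics.append(OmicMatrix(name, X.T, feature_ids, sample_ids))
    return omics, labels, spec.coverage.copy()


def sim1_preset(rng_seed: int = 0) -> SimSpec:
    """Five 60-sample modules over two omics, plus five outliers.

    Module 1 is structured only in omic 1, module 2 only in omic 2, and
    modules 3-5 in both; outliers belong to no module (305 samples total).
    """
    coverage = np.array(
        [[True, False], [False, True], [True, True], [True, True], [True, True]]
    )
    return SimSpec(
        module_sizes=[60] * 5,
        n_outliers=5,
        omic_names=["omic1", "omic2"],
        coverage=coverage,
        rng_seed=rng_seed,
    )


def sim2_preset(include_omic3: bool = True, rng_seed: int = 0) -> SimSpec:
    """Five 30-sample modules over three omics (150 samples, no outliers).

    Module 1 is distinct everywhere. Modules 2-5 share one mean in omic 1
    (indistinguishable there), are only weakly separated in omic 2 (few
    informative features, small effect) and clearly separated in omic 3.
    ``include_omic3=False`` drops omic 3 — the condition under which modules
    2-5 are expected to collapse into a single omic-1 module.
    """
    names = ["omic1", "omic2", "omic3"]
    spec = SimSpec(
        module_sizes=[30] * 5,
        n_outliers=0,
        omic_names=names,
        coverage=np.ones((5, 3), dtype=bool),
        features_per_omic=[100, 100, 100],
        informative_features=[30, 5, 30],
        weak_omics=(1,),
        shared_mean_groups={0: [[0], [1, 2, 3, 4]]},
        rng_seed=rng_seed,
    )
    if not include_omic3:
        spec = replace(
            spec,
            omic_names=names[:2],
            coverage=spec.coverage[:, :2],
            features_per_omic=spec.features_per_omic[:2],
            informative_features=spec.informative_features[:2],
        )
    return spec


def make_partial(
    omics: list[OmicMatrix],
    registry: SampleRegistry,
    protocol: str,
    fraction: float = 0.2,
    rng_seed: int = 0,
) -> tuple[list[OmicMatrix], SampleRegistry]:
    """Hide samples from some omics, emulating partial multi-omic datasets.

    ``"tcga_style"`` (needs exactly 3 omics): sample a ``fraction`` of all
    samples, split them into three equal groups and remove group g from omic
    g. ``"independent"``: remove ``fraction`` of each omic's samples,
    independently per omic, never leaving a sample measured nowhere (removal
    candidates are restricted to samples still measured elsewhere; raises if
    that is infeasible). Returns new matrices and a registry that keeps the
    original global sample ordering.
    """
    rng = np.random.default_rng(int(rng_seed) % _SEED_MOD)
    n = registry.n
    removed: dict[str, set[str]] = {om.omic_id: set() for om in omics}
    if protocol == "tcga_style":
        if len(omics) != 3:
            raise ValueError("tcga_style protocol requires exactly 3 omics")
        n_rm = int(np.floor(fraction * n))
        n_rm -= n_rm % 3
        chosen = rng.choice(n, size=n_rm, replace=False)
        for g in range(3):
            ids = {registry.all_sample_ids[i] for i in chosen[g::3]}
            removed[omics[g].omic_id] = ids
    elif protocol == "independent":
        membership = {om.omic_id: registry.measured(om.omic_id).copy() for om in omics}
        for om in omics:
            mask = membership[om.omic_id]
            measured_elsewhere = np.zeros(n, dtype=int)
            for oid, other in membership.items():
                if oid != om.omic_id:
                    measured_elsewhere += other.astype(int)
            eligible = np.flatnonzero(mask & (measured_elsewhere > 0))
            target = int(np.floor(fraction * mask.sum()))
            if target > eligible.size:
                raise ValueError(
                    f"omic {om.omic_id!r}: removing {target} samples would leave "
                    "some measured in no omic"
                )
            drop = rng.choice(eligible, size=target, replace=False)
            mask[drop] = False
            removed[om.omic_id] = {registry.all_sample_ids[i] for i in drop}
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    new_omics = []
    for om in omics:
        keep = [s for s in om.sample_ids if s not in removed[om.omic_id]]
        new_omics.append(om.subset_samples(keep))
    new_reg = SampleRegistry(list(registry.all_sample_ids))
    for om in new_omics:
        mask = np.zeros(n, dtype=bool)
        mask[[new_reg.index_of(s) for s in om.sample_ids]] = True
        new_reg.membership[om.omic_id] = mask
    new_reg.validate()
    return new_omics, new_reg
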