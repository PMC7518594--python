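"""Classify unseen samples into previously detected modules.

Uses the Gaussian-mixture weighting scheme, whose frozen per-omic models can
compute edge weights to *new* samples. A new sample joins the module with the
highest weight gain (sum of its edge weights to the module's members over the
module's covered omics); if every gain is negative it stays lonely.
"""

from omicmodules import (
    SampleRegistry,
    SearchParams,
    SimSpec,
    WeightingConfig,
    classify_new_samples,
    detect_modules,
    simulate,
)

spec = SimSpec(module_sizes=[40, 40, 40], n_outliers=0, rng_seed=3)
omics, labels, _ = simulate(spec)

# hold out 4 samples from each planted module; fit on the rest
hold_idx = [j for m in range(3) for j in range(40 * m, 40 * m + 4)]
hold_ids = [omics[0].sample_ids[j] for j in hold_idx]
train_ids = [s for s in omics[0].sample_ids if s not in set(hold_ids)]
train = [om.subset_samples(train_ids) for om in omics]
registry = SampleRegistry.from_omics(train)

solution, diag = detect_modules(
    train, registry,
    WeightingConfig(scheme="gmm", rng_seed=11),
    SearchParams(restarts=3, rng_seed=13),
)
print(f"fitted {len(solution.modules)} modules on {registry.n} training samples")

new = [om.subset_samples(hold_ids) for om in omics]
table = classify_new_samples(new, solution, diag["models"], registry)
print(table[["sample_id", "module_id"]].to_string(index=False))
truth = dict(zip(omics[0].sample_ids, labels))
train_truth = {registry.index_of(s): truth[s] for s in train_ids}
hits = 0
for row in table.itertuples():
    if row.module_id < 0:
        continue
    member_labels = {train_truth[v] for v in solution.modules[row.module_id].samples}
    hits += truth[row.sample_id] in member_labels
print(f"{hits}/{len(table)} held-out samples joined the module of their planted co-members")
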