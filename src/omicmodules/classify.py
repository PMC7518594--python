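"""Assigning samples to existing modules by weight gain.

The association score of sample u with module M is the gain in weight(M) from
adding u: the sum of edge weights between u and every member of M over the
omics M covers. A new sample is classified to the module of maximal score, or
left lonely when every score is negative (a score of exactly zero still
classifies). For samples outside the fitted dataset this needs edge weights to
new points, which only the frozen Gaussian-mixture weighting models provide —
the consensus scheme would require re-clustering and is deliberately
unsupported here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import OmicMatrix, SampleRegistry
from .graphs import GmmOmicModel, OmicGraph
from .solution import Module, Solution

__all__ = [
    "sample_module_score",
    "classify_sample",
    "new_sample_weights",
    "classify_new_samples",
]


def sample_module_score(u: int, module: Module, graphs: list[OmicGraph],
                        per_omic: bool = False):
    """Score = sum over covered omics of summed weight from u to the members.

    ``per_omic=True`` returns a dict omic -> contribution (diagnostic view of
    which omics tie the sample to the module).
    """
    by_id = {g.omic_id: g.weights for g in graphs}
    mem = module.sample_array()
    mem = mem[mem != u]
    parts = {o: float(by_id[o][u, mem].sum()) for o in module.omics}
    if per_omic:
        return parts
    return float(sum(parts.values()))


def classify_sample(u: int, solution: Solution, graphs: list[OmicGraph]) -> int:
    """Module index of maximal score, or -1 (lonely) if every score is negative.

    Ties resolve to the lowest module index; a zero score classifies.
    """
    if not solution.modules:
        return -1
    scores = np.array([sample_module_score(u, m, graphs) for m in solution.modules])
    j = int(np.argmax(scores))
    return j if scores[j] >= 0 else -1


def new_sample_weights(new_omics: list[OmicMatrix], models: list[GmmOmicModel],
                       registry: SampleRegistry) -> tuple[list[str], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Edge weights from new samples to every fitted sample, per omic.

    ``new_omics`` holds the new samples' feature matrices (same feature ids
    and order as at fit time); new samples may be missing from some omics.
    Returns the union of new sample ids plus, per omic, a (n_new, n_fitted)
    weight matrix over global fitted indices and a measured mask for the new
    samples.
    """
    by_id = {m.omic_id: m for m in models}
    new_ids: dict[str, None] = {}
    for om in new_omics:
        for s in om.sample_ids:
            new_ids.setdefault(s)
    ids = list(new_ids)
    pos = {s: i for i, s in enumerate(ids)}
    n = registry.n
    weights: dict[str, np.ndarray] = {}
    measured: dict[str, np.ndarray] = {}
    for om in new_omics:
        model = by_id[om.omic_id]
        if om.feature_ids != model.feature_ids:
            raise ValueError(f"omic {om.omic_id!r}: feature ids differ from the fitted model")
        w_train = model.weights_to_train(om.samples_by_features())
        W = np.zeros((len(ids), n))
        rows = [pos[s] for s in om.sample_ids]
        W[np.ix_(rows, model.train_idx)] = w_train
        mask = np.zeros(len(ids), dtype=bool)
        mask[rows] = True
        weights[om.omic_id] = W
        measured[om.omic_id] = mask
    return ids, weights, measured


def classify_new_samples(new_omics: list[OmicMatrix], solution: Solution,
                         models: list[GmmOmicModel], registry: SampleRegistry) -> pd.DataFrame:
    """Classify unseen samples into the fitted modules.

    Returns a frame with one row per new sample: the assigned module id (-1 =
    lonely) and the score against every module. A sample unmeasured in all of
    a module's covered omics scores 0 against it; a sample with no computable
    weight for any omic raises.
    """
    ids, weights, measured = new_sample_weights(new_omics, models, registry)
    any_measured = np.zeros(len(ids), dtype=bool)
    for mask in measured.values():
        any_measured |= mask
    if not any_measured.all():
        missing = [s for s, ok in zip(ids, any_measured) if not ok]
        raise ValueError(f"samples with no measured omic: {missing[:5]}")
    rows = []
    for i, sid in enumerate(ids):
        scores = []
        for mod in solution.modules:
            mem = mod.sample_array()
            s = 0.0
            for o in mod.omics:
                if o in weights and measured[o][i]:
                    s += float(weights[o][i, mem].sum())
            scores.append(s)
        if scores:
            j = int(np.argmax(scores))
            assigned = j if scores[j] >= 0 else -1
        else:
            assigned = -1
        rows.append({"sample_id": sid, "module_id": assigned,
                     **{f"score_module_{j}": s for j, s in enumerate(scores)}})
    return pd.DataFrame(rows)
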