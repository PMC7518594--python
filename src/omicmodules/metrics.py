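"""Scoring utilities: ARI with lonely-sample conventions, coverage recovery,
and the unsupervised cross-validation harness.

The Adjusted Rand Index (Hubert-Arabie) is chance-corrected pair-counting
agreement between two partitions; it handles differing cluster counts and
sizes. Module solutions are not full partitions — lonely samples belong to no
module — so three conventions are provided for label vectors that use -1 for
lonely/outlier samples:

``own_cluster``
    all lonely samples pooled into one extra cluster (headline convention),
``singleton_cluster``
    each lonely sample becomes its own cluster,
``exclude``
    samples lonely in either labelling are dropped before comparing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = ["adjusted_rand_index", "coverage_accuracy", "match_modules", "cross_validate"]

_SEED_MOD = 2**31 - 1


def _apply_lonely(labels: np.ndarray, mode: str) -> np.ndarray:
    lab = labels.copy()
    lonely = lab < 0
    if mode == "own_cluster":
        lab[lonely] = lab.max(initial=0) + 1  # one shared extra label
    elif mode == "singleton_cluster":
        fresh = lab.max(initial=0) + 1 + np.arange(lonely.sum())
        lab[lonely] = fresh
    else:
        raise ValueError(f"unknown lonely_mode {mode!r}")
    return lab


def adjusted_rand_index(labels_a, labels_b, lonely_mode: str = "own_cluster") -> float:
    """Hubert-Arabie ARI between two labelings with lonely samples marked -1."""
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    if lonely_mode == "exclude":
        keep = (a >= 0) & (b >= 0)
        if keep.sum() < 2:
            raise ValueError("fewer than 2 samples remain after excluding lonely")
        a, b = a[keep], b[keep]
    else:
        a = _apply_lonely(a, lonely_mode)
        b = _apply_lonely(b, lonely_mode)
    return float(adjusted_rand_score(a, b))


def match_modules(found_labels: np.ndarray, truth_labels: np.ndarray,
                  n_found: int, n_truth: int) -> dict[int, int]:
    """Match found modules to truth modules by maximal sample overlap (Hungarian).

    Returns a mapping truth module -> found module; truth modules with no
    overlapping partner stay unmapped.
    """
    if n_found == 0 or n_truth == 0:
        return {}
    overlap = np.zeros((n_truth, n_found), dtype=int)
    for t in range(n_truth):
        sel = found_labels[truth_labels == t]
        sel = sel[sel >= 0]
        if sel.size:
            counts = np.bincount(sel, minlength=n_found)
            overlap[t] = counts
    rows, cols = linear_sum_assignment(-overlap)
    return {int(t): int(f) for t, f in zip(rows, cols) if overlap[t, f] > 0}


def coverage_accuracy(found_labels: np.ndarray, found_coverage: np.ndarray,
                      truth_labels: np.ndarray, truth_coverage: np.ndarray) -> float:
    """Fraction of (truth module, omic) cells whose coverage was recovered.

    Found modules are matched to truth modules by maximal sample overlap;
    every cell of an unmatched truth module counts as wrong.
    """
    truth_coverage = np.asarray(truth_coverage, dtype=bool)
    found_coverage = np.asarray(found_coverage, dtype=bool)
    n_truth, n_omics = truth_coverage.shape
    if found_coverage.shape[0] == 0:
        raise ValueError("no found modules")
    if found_coverage.shape[1] != n_omics:
        raise ValueError("omic count mismatch")
    mapping = match_modules(found_labels, truth_labels, found_coverage.shape[0], n_truth)
    correct = 0
    for t in range(n_truth):
        if t in mapping:
            correct += int((found_coverage[mapping[t]] == truth_coverage[t]).sum())
    return correct / float(n_truth * n_omics)


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate(omics, registry, wcfg, params, truth_labels=None, folds: int = 10,
                   rng_seed: int = 0) -> pd.DataFrame:
    """Unsupervised 10-fold cross-validation of module detection + classification.

    For each fold i the detector runs on the other folds' samples (solution
    Sol_i), then the held-out samples are classified into Sol_i's modules
    using the frozen mixture models (solution Sol_i^). Per fold this reports:

    * ``stability``  = ARI(Sol_all, Sol_i) over the samples both solutions share,
    * ``rfc``        = ARI(Sol_all, Sol_i^) over all samples,
    * ``preca``      = ARI(truth, Sol_i) over Sol_i's samples (NaN without truth),
    * ``postca``     = ARI(truth, Sol_i^) over all samples (NaN without truth),
    * ``holdout_match`` = fraction of held-out samples classified into the found
      module their ground-truth module maps to (overlap matching; NaN without
      truth).

    Requires the gmm weighting scheme (classification needs frozen models).
    """
    from .classify import classify_new_samples
    from .search import detect_modules

    if wcfg.scheme != "gmm":
        raise ValueError("cross_validate requires the gmm weighting scheme")
    n = registry.n
    sol_all, _ = detect_modules(omics, registry, wcfg, params)
    all_labels = sol_all.labels()
    rng = np.random.default_rng(int(rng_seed) % _SEED_MOD)
    rows = []
    for i, fold in enumerate(_fold_indices(n, folds, rng)):
        train = np.setdiff1d(np.arange(n), fold)
        train_ids = [registry.all_sample_ids[j] for j in train]
        fold_ids = [registry.all_sample_ids[j] for j in fold]
        train_omics = [om.subset_samples(train_ids) for om in omics]
        train_omics = [om for om in train_omics if om.n_samples > 0]
        from .data import SampleRegistry

        train_reg = SampleRegistry.from_omics(train_omics)
        sol_i, diag = detect_modules(train_omics, train_reg, wcfg, params)
        # lift fold solution labels back to global indexing
        lab_i = np.full(n, -2, dtype=int)  # -2 = absent from the fold solution
        li = sol_i.labels()
        for local, sid in enumerate(train_reg.all_sample_ids):
            lab_i[registry.index_of(sid)] = li[local]
        shared = lab_i > -2
        stability = adjusted_rand_index(all_labels[shared], lab_i[shared])
        # classify the held-out samples
        fold_omics = [om.subset_samples(fold_ids) for om in omics]
        fold_omics = [om for om in fold_omics if om.n_samples > 0]
        assigned = classify_new_samples(fold_omics, sol_i, diag["models"], train_reg)
        lab_hat = lab_i.copy()
        by_sid = dict(zip(assigned["sample_id"], assigned["module_id"]))
        for sid in fold_ids:
            lab_hat[registry.index_of(sid)] = by_sid.get(sid, -1)
        rfc = adjusted_rand_index(all_labels, lab_hat)
        preca = postca = holdout = np.nan
        if truth_labels is not None:
            truth = np.asarray(truth_labels, dtype=int)
            preca = adjusted_rand_index(truth[shared], lab_i[shared])
            postca = adjusted_rand_index(truth, lab_hat)
            mapping = match_modules(li, truth[train], len(sol_i.modules),
                                    int(truth.max()) + 1)
            hits = total = 0
            for sid in fold_ids:
                g = registry.index_of(sid)
                t = truth[g]
                if t < 0:
                    continue
                total += 1
                if t in mapping and lab_hat[g] == mapping[t]:
                    hits += 1
            holdout = hits / total if total else np.nan
        rows.append({"fold": i, "stability": stability, "rfc": rfc,
                     "preca": preca, "postca": postca, "holdout_match": holdout})
    return pd.DataFrame(rows)
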