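"""Empirical significance filtering of detected modules.

A converged module may still be an artefact of the greedy search, so each
module is compared against random modules of identical size and covered-omic
set: ``n_null`` uniform sample subsets are drawn from the full sample universe
and scored with the module's omics. The module is kept only if its weight
strictly exceeds the ``keep_quantile`` empirical quantile of the null weights
(the 495th order statistic under the 500-null / 1% defaults). Samples of
removed modules become lonely. No multiple-testing correction is applied
across modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphs import OmicGraph
from .solution import Solution, module_weight

__all__ = ["NullTestConfig", "filter_modules", "null_weights"]

_SEED_MOD = 2**31 - 1


@dataclass
class NullTestConfig:
    n_null: int = 500
    keep_quantile: float = 0.99
    test_scope: str = "all_modules"  # "all_modules" | "minimal_size_only"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.keep_quantile < 1:
            raise ValueError("keep_quantile must be in (0, 1)")
        if self.n_null < 100:
            raise ValueError("n_null must be >= 100")
        if self.test_scope not in ("all_modules", "minimal_size_only"):
            raise ValueError(f"unknown test_scope {self.test_scope!r}")


def null_weights(graphs: list[OmicGraph], size: int, omics: set[str],
                 n_null: int, rng: np.random.Generator) -> np.ndarray:
    """Weights of ``n_null`` uniform random size-``size`` modules with ``omics``."""
    n = graphs[0].n
    by_id = {g.omic_id: g.weights for g in graphs}
    idx = np.argsort(rng.random((n_null, n)), axis=1)[:, :size]
    out = np.zeros(n_null)
    for o in omics:
        W = by_id[o]
        out += W[idx[:, :, None], idx[:, None, :]].sum(axis=(1, 2)) / 2.0
    return out


def filter_modules(solution: Solution, graphs: list[OmicGraph], cfg: NullTestConfig,
                   eta: int | None = None) -> tuple[Solution, pd.DataFrame]:
    """Drop modules whose weight is not in the top (1 - keep_quantile) of nulls.

    With ``test_scope="minimal_size_only"`` only modules of size <= ``eta``
    are tested (the practical setting: larger modules essentially never fail).
    Retained modules are untouched; removed modules' samples become lonely.
    Deterministic given ``cfg.rng_seed``.
    """
    if cfg.test_scope == "minimal_size_only" and eta is None:
        raise ValueError("minimal_size_only scope requires eta")
    rng = np.random.default_rng(int(cfg.rng_seed) % _SEED_MOD)
    order_stat = int(np.ceil(cfg.keep_quantile * cfg.n_null)) - 1
    rows = []
    kept = []
    out = Solution(n=solution.n, modules=[], lonely=set(solution.lonely))
    for i, mod in enumerate(solution.modules):
        obs = module_weight(mod, graphs)
        tested = cfg.test_scope == "all_modules" or mod.size <= eta
        if tested:
            nulls = np.sort(null_weights(graphs, mod.size, mod.omics, cfg.n_null, rng))
            thresh = float(nulls[order_stat])
            keep = obs > thresh
        else:
            thresh = np.nan
            keep = True
        rows.append({
            "module_id": i,
            "size": mod.size,
            "omics": ";".join(sorted(mod.omics)),
            "observed_weight": obs,
            "null_quantile": thresh,
            "tested": tested,
            "kept": bool(keep),
        })
        if keep:
            out.modules.append(mod.copy())
        else:
            out.lonely.update(mod.samples)
        kept.append(keep)
    report = pd.DataFrame(rows)
    out.validate()
    return out, report
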