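"""Readers and writers for solutions, coverage tables and diagnostics.

All artefacts are plain text: TSV for tables, JSON for diagnostics, YAML for
configs. Graph caches are NumPy ``.npz`` files (runtime artefacts only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import SampleRegistry
from .graphs import OmicGraph
from .solution import Module, Solution, module_weight

__all__ = [
    "write_solution",
    "read_solution",
    "write_module_table",
    "write_coverage",
    "write_edge_list",
    "write_graph_cache",
    "read_graph_cache",
    "write_diagnostics",
    "write_matrix",
    "load_config",
]


def write_solution(path, solution: Solution, registry: SampleRegistry) -> None:
    """TSV with one row per sample: sample_id, module_id (int or "lonely")."""
    lab = solution.labels()
    df = pd.DataFrame({
        "sample_id": registry.all_sample_ids,
        "module_id": [str(l) if l >= 0 else "lonely" for l in lab],
    })
    df.to_csv(path, sep="\t", index=False)


def read_solution(path, registry: SampleRegistry,
                  omic_ids_by_module: dict[int, list[str]] | None = None) -> Solution:
    """Rebuild a :class:`Solution` from a solution TSV.

    Module omic sets are not stored in the per-sample table; supply them via
    ``omic_ids_by_module`` or they default to a placeholder single omic.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "module_id": str})
    n = registry.n
    groups: dict[int, set[int]] = {}
    lonely: set[int] = set()
    for _, row in df.iterrows():
        gi = registry.index_of(row["sample_id"])
        if row["module_id"] == "lonely":
            lonely.add(gi)
        else:
            groups.setdefault(int(row["module_id"]), set()).add(gi)
    modules = []
    for mid in sorted(groups):
        omics = (omic_ids_by_module or {}).get(mid, ["unknown"])
        modules.append(Module(groups[mid], set(omics)))
    sol = Solution(n=n, modules=modules, lonely=lonely)
    sol.validate()
    return sol


def write_module_table(path, solution: Solution, graphs: list[OmicGraph]) -> None:
    """TSV: module_id, size, covered omics (semicolon-joined), weight."""
    omic_order = [g.omic_id for g in graphs]
    rows = [
        {
            "module_id": i,
            "size": mod.size,
            "omics": ";".join(o for o in omic_order if o in mod.omics),
            "weight": module_weight(mod, graphs),
        }
        for i, mod in enumerate(solution.modules)
    ]
    pd.DataFrame(rows, columns=["module_id", "size", "omics", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_coverage(path, coverage: np.ndarray, omic_ids: list[str]) -> None:
    """TSV coverage table, modules x omics, 0/1 cells."""
    df = pd.DataFrame(np.asarray(coverage, dtype=int), columns=omic_ids)
    df.insert(0, "module_id", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_edge_list(path, graphs: list[OmicGraph], registry: SampleRegistry) -> None:
    """TSV edge list (sample_u, sample_v, omic, weight) over measured pairs."""
    frames = []
    ids = np.array(registry.all_sample_ids)
    for g in graphs:
        iu, iv = np.triu_indices(g.n, k=1)
        keep = g.measured[iu] & g.measured[iv]
        frames.append(pd.DataFrame({
            "sample_u": ids[iu[keep]],
            "sample_v": ids[iv[keep]],
            "omic": g.omic_id,
            "weight": g.weights[iu[keep], iv[keep]],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_graph_cache(path, graphs: list[OmicGraph]) -> None:
    arrays = {}
    for g in graphs:
        arrays[f"weights_{g.omic_id}"] = g.weights
        arrays[f"measured_{g.omic_id}"] = g.measured
    np.savez_compressed(path, omic_ids=np.array([g.omic_id for g in graphs]), **arrays)


def read_graph_cache(path) -> list[OmicGraph]:
    data = np.load(path, allow_pickle=False)
    return [
        OmicGraph(str(oid), data[f"weights_{oid}"], data[f"measured_{oid}"])
        for oid in data["omic_ids"]
    ]


def write_diagnostics(path, diagnostics: dict) -> None:
    """JSON diagnostics (per-restart objectives, action counts, epochs...)."""
    keep = {
        "per_restart_objectives": [float(x) for x in diagnostics["per_restart_objectives"]],
        "best_restart": int(diagnostics["best_restart"]),
        "best_objective": float(diagnostics["best_objective"]),
        "action_counts": {k: int(v) for k, v in diagnostics["action_counts"].items()},
        "epochs": int(diagnostics["epochs"]),
        "n_actions_applied": sum(len(seg) - 1 for seg in diagnostics["history"]),
        "omic_ids": list(diagnostics["omic_ids"]),
    }
    with open(path, "w") as fh:
        json.dump(keep, fh, indent=2)


def write_matrix(path, matrix) -> None:
    """Write an OmicMatrix as TSV (features x samples, labelled)."""
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.sample_ids)
    df.to_csv(path, sep="\t", index_label="feature_id")


def load_config(path) -> dict:
    """Flat key-value YAML config; raises with the offending key on bad types."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def dump_config(path: Path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
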