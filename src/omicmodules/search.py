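"""Greedy heavy-module search.

The optimization problem — partition samples into disjoint modules, each with
its own covered-omic set, maximizing the summed within-module edge weight — is
NP-hard already for a single graph, so the search is a restarted greedy local
search. Each restart builds seed modules around random anchors and then
repeatedly applies, per module, the best strictly-improving action among:

* add / remove / move samples (batched up to ``batch_cap``),
* add / remove an omic,
* merge two modules (four covered-omic options),
* split a module (heavy subgraph of its internal summed graph),
* split by adding an omic / split with an omic,
* discard a module, reassigning its samples,
* create a new module from lonely samples.

Every applied action strictly increases the objective, so the search
terminates; the best restart is kept. Heavy subgraphs are found with a
min-weighted-degree peeling heuristic in the spirit of Charikar's densest-
subgraph 2-approximation: peel the minimum-degree node, and return the
heaviest of the nested subgraphs visited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .graphs import OmicGraph
from .solution import Module, Solution, cross_sum, module_weight, objective, pair_sum

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "ActionRecord",
    "heavy_subgraph",
    "find_seeds",
    "evaluate_actions",
    "best_action",
    "apply_action",
    "optimize",
    "detect_modules",
]

_SEED_MOD = 2**31 - 1

# Fixed enumeration order; equal-gain ties resolve to the earlier kind.
ACTION_KINDS = (
    "add_samples",
    "remove_sample",
    "move_samples",
    "add_omic",
    "remove_omic",
    "merge",
    "split",
    "discard",
    "new_module",
    "split_by_adding_omic",
    "split_with_omic",
)


@dataclass
class SearchParams:
    """Tunables of the greedy search.

    ``S`` seeds of up to ``k + 1`` samples initialise each restart; ``eta`` is
    the minimum module size a converged solution may contain; batched
    add/move actions take at most ``batch_cap`` samples at a time. ``None``
    fields are resolved from the sample count n: k = floor(n/15),
    eta = max(round(n/30), 10), batch_cap = 10 (n//50 when n > 1000).
    """

    S: int = 15
    k: int | None = None
    eta: int | None = None
    batch_cap: int | None = None
    restarts: int = 15
    max_epochs: int = 10_000
    rng_seed: int = 0

    def resolve(self, n: int) -> "SearchParams":
        k = self.k if self.k is not None else max(int(np.floor(n / 15)), 1)
        eta = self.eta if self.eta is not None else max(int(round(n / 30)), 10)
        cap = self.batch_cap if self.batch_cap is not None else (10 if n <= 1000 else n // 50)
        out = replace(self, k=k, eta=eta, batch_cap=cap)
        if out.S < 1:
            raise ValueError("S must be >= 1")
        if out.eta < 2:
            raise ValueError("eta must be >= 2")
        return out


@dataclass
class ActionRecord:
    """One candidate (or applied) action and its exact objective gain."""

    kind: str
    module: int | None = None  # index of the acted-on module
    other: int | None = None  # merge partner / move partner
    samples: list[int] = field(default_factory=list)
    omics: list[str] = field(default_factory=list)
    payload: Any = None  # kind-specific details (moves, assignments, parts)
    gain: float = 0.0


def heavy_subgraph(W: np.ndarray) -> np.ndarray:
    """Heaviest prefix of the min-degree peeling order of a signed graph.

    Iteratively removes the node of minimum weighted degree (ties: lowest
    index) and returns, among all nested subgraphs visited (full set down to
    the empty set), the one of maximum total edge weight; weight ties prefer
    the larger node set. An all-negative graph yields the empty set.
    """
    W = np.asarray(W, dtype=float)
    m = W.shape[0]
    if m == 0:
        return np.empty(0, dtype=int)
    deg = W.sum(axis=1).astype(float)
    active = np.ones(m, dtype=bool)
    total = float(W.sum()) / 2.0
    totals = np.empty(m + 1)
    totals[0] = total
    removal = np.empty(m, dtype=int)
    for t in range(m):
        masked = np.where(active, deg, np.inf)
        i = int(np.argmin(masked))
        total -= deg[i]
        active[i] = False
        deg -= W[i]
        removal[t] = i
        totals[t + 1] = total
    # numerical guard: the empty set has exactly weight 0
    totals[m] = 0.0
    best_t = int(np.argmax(totals))  # argmax keeps the earliest (= largest set)
    if totals[best_t] <= 0.0:
        # no positive structure: edgeless prefixes tie at 0, return nothing
        return np.empty(0, dtype=int)
    return np.sort(removal[best_t:])


def find_seeds(graphs: list[OmicGraph], params: SearchParams, rng: np.random.Generator) -> Solution:
    """Seed modules: random anchor plus its top-k strictly positive neighbours.

    Seeds are carved from the omic-summed graph iteratively; each seed covers
    all omics. Samples in no seed start lonely.
    """
    n = graphs[0].n
    Wsum = np.sum([g.weights for g in graphs], axis=0)
    all_omics = [g.omic_id for g in graphs]
    if n < params.S:
        warnings.warn(f"n={n} < S={params.S}: fewer seeds will be produced", stacklevel=2)
    mask = np.ones(n, dtype=bool)
    modules: list[Module] = []
    for _ in range(params.S):
        rem = np.flatnonzero(mask)
        if rem.size == 0:
            break
        anchor = int(rng.choice(rem))
        w = Wsum[anchor, rem]
        order = np.argsort(-w, kind="stable")
        nbrs = [int(rem[j]) for j in order if w[j] > 0 and int(rem[j]) != anchor]
        chosen = {anchor, *nbrs[: params.k]}
        modules.append(Module(chosen, set(all_omics)))
        mask[list(chosen)] = False
    return Solution(n=n, modules=modules, lonely=set(np.flatnonzero(mask).tolist()))


class _Engine:
    """Evaluates candidate actions on the current solution."""

    def __init__(self, graphs: list[OmicGraph], params: SearchParams):
        self.omic_ids = [g.omic_id for g in graphs]
        self.W = {g.omic_id: g.weights for g in graphs}
        self.n = graphs[0].n
        self.params = params

    # ---- helpers -------------------------------------------------------
    def scores_to(self, omics: set[str], members: np.ndarray, nodes: np.ndarray) -> np.ndarray:
        """Summed weight from each node to all members under the given omics."""
        if members.size == 0 or nodes.size == 0:
            return np.zeros(nodes.size)
        out = np.zeros(nodes.size)
        for o in omics:
            out += self.W[o][np.ix_(nodes, members)].sum(axis=1)
        return out

    def _pairs(self, omics: set[str], idx: np.ndarray) -> float:
        return float(sum(pair_sum(self.W[o], idx) for o in omics))

    def _cross(self, omics: set[str], a: np.ndarray, b: np.ndarray) -> float:
        return float(sum(cross_sum(self.W[o], a, b) for o in omics))

    def _ordered_omics(self, omics: set[str]) -> list[str]:
        return [o for o in self.omic_ids if o in omics]

    # ---- per-kind candidate evaluation ---------------------------------
    def add_samples(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        lon = np.fromiter(sorted(sol.lonely), dtype=int, count=len(sol.lonely))
        if lon.size == 0:
            return None
        mem = mod.sample_array()
        gains = self.scores_to(mod.omics, mem, lon)
        active = np.ones(lon.size, dtype=bool)
        chosen: list[int] = []
        total = 0.0
        for _ in range(self.params.batch_cap):
            masked = np.where(active, gains, -np.inf)
            j = int(np.argmax(masked))
            if masked[j] <= 0:
                break
            total += float(masked[j])
            chosen.append(int(lon[j]))
            active[j] = False
            for o in mod.omics:
                gains += self.W[o][lon, lon[j]]
        if not chosen or total <= 0:
            return None
        return ActionRecord("add_samples", module=ai, samples=chosen, gain=total)

    def remove_sample(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        if mod.size - 1 < self.params.eta:
            return None
        mem = mod.sample_array()
        scores = self.scores_to(mod.omics, mem, mem)
        j = int(np.argmin(scores))
        if scores[j] >= 0:
            return None
        return ActionRecord("remove_sample", module=ai, samples=[int(mem[j])], gain=float(-scores[j]))

    def move_samples(self, sol: Solution, ai: int) -> ActionRecord | None:
        k = len(sol.modules)
        if k < 2:
            return None
        members = {i: set(m.samples) for i, m in enumerate(sol.modules)}
        allnodes = np.arange(self.n)
        Sc = {
            i: self.scores_to(m.omics, m.sample_array(), allnodes)
            for i, m in enumerate(sol.modules)
        }
        moves: list[tuple[int, int, int]] = []  # (sample, src, dst)
        total = 0.0
        for _ in range(self.params.batch_cap):
            best = None  # (gain, sample, src, dst)
            for bi in range(k):
                if bi == ai:
                    continue
                for src, dst in ((ai, bi), (bi, ai)):
                    if len(members[src]) - 1 < self.params.eta:
                        continue
                    arr = np.fromiter(sorted(members[src]), dtype=int, count=len(members[src]))
                    diff = Sc[dst][arr] - Sc[src][arr]
                    j = int(np.argmax(diff))
                    if best is None or diff[j] > best[0]:
                        best = (float(diff[j]), int(arr[j]), src, dst)
            if best is None or best[0] <= 0:
                break
            g, u, src, dst = best
            members[src].remove(u)
            members[dst].add(u)
            for o in sol.modules[src].omics:
                Sc[src] -= self.W[o][:, u]
            for o in sol.modules[dst].omics:
                Sc[dst] += self.W[o][:, u]
            moves.append((u, src, dst))
            total += g
        if not moves or total <= 0:
            return None
        return ActionRecord("move_samples", module=ai, payload=moves, gain=total)

    def add_omic(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        mem = mod.sample_array()
        best = None
        for o in self.omic_ids:
            if o in mod.omics:
                continue
            g = pair_sum(self.W[o], mem)
            if g > 0 and (best is None or g > best[1]):
                best = (o, g)
        if best is None:
            return None
        return ActionRecord("add_omic", module=ai, omics=[best[0]], gain=float(best[1]))

    def remove_omic(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        if len(mod.omics) < 2:
            return None
        mem = mod.sample_array()
        best = None
        for o in self._ordered_omics(mod.omics):
            g = -pair_sum(self.W[o], mem)
            if g > 0 and (best is None or g > best[1]):
                best = (o, g)
        if best is None:
            return None
        return ActionRecord("remove_omic", module=ai, omics=[best[0]], gain=float(best[1]))

    def merge(self, sol: Solution, ai: int) -> ActionRecord | None:
        A = sol.modules[ai]
        arrA = A.sample_array()
        best = None
        for bi, B in enumerate(sol.modules):
            if bi == ai:
                continue
            arrB = B.sample_array()
            involved = A.omics | B.omics
            pa = {o: pair_sum(self.W[o], arrA) for o in involved}
            pb = {o: pair_sum(self.W[o], arrB) for o in involved}
            cx = {o: cross_sum(self.W[o], arrA, arrB) for o in involved}
            old = sum(pa[o] for o in A.omics) + sum(pb[o] for o in B.omics)
            options = [A.omics | B.omics, A.omics & B.omics, set(A.omics), set(B.omics)]
            for opt in options:
                if not opt:
                    continue
                new = sum(pa[o] + pb[o] + cx[o] for o in opt)
                g = new - old
                if g > 0 and (best is None or g > best[0]):
                    best = (float(g), bi, opt)
        if best is None:
            return None
        g, bi, opt = best
        return ActionRecord("merge", module=ai, other=bi, omics=self._ordered_omics(opt), gain=g)

    def split(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        if mod.size < 2 * self.params.eta:
            return None
        mem = mod.sample_array()
        Wc = np.zeros((mem.size, mem.size))
        for o in mod.omics:
            Wc += self.W[o][np.ix_(mem, mem)]
        loc = heavy_subgraph(Wc)
        if loc.size < self.params.eta or mem.size - loc.size < self.params.eta:
            return None
        rest_loc = np.setdiff1d(np.arange(mem.size), loc)
        g = -float(Wc[np.ix_(loc, rest_loc)].sum())
        if g <= 0:
            return None
        return ActionRecord("split", module=ai, samples=[int(s) for s in mem[loc]],
                            omics=self._ordered_omics(mod.omics), gain=g)

    def discard(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        mem = mod.sample_array()
        others = [bi for bi in range(len(sol.modules)) if bi != ai]
        # per-sample score to each other module (static, as of current state)
        assign: dict[int, list[int]] = {}
        if others:
            score_mat = np.stack(
                [
                    self.scores_to(sol.modules[bi].omics, sol.modules[bi].sample_array(), mem)
                    for bi in others
                ]
            )
            best_bi = np.argmax(score_mat, axis=0)  # first max -> lowest module id
            best_val = score_mat[best_bi, np.arange(mem.size)]
            for j, u in enumerate(mem):
                if best_val[j] >= 0:
                    assign.setdefault(others[int(best_bi[j])], []).append(int(u))
        # exact gain: receivers gain cross + internal pairs among co-moved samples
        gain = -self._pairs(mod.omics, mem)
        for bi, moved in assign.items():
            marr = np.array(moved, dtype=int)
            B = sol.modules[bi]
            gain += self._cross(B.omics, marr, B.sample_array())
            gain += self._pairs(B.omics, marr)
        if gain <= 0:
            return None
        return ActionRecord("discard", module=ai, payload=assign, gain=float(gain))

    def new_module(self, sol: Solution, ai: int | None = None) -> ActionRecord | None:
        lon = np.fromiter(sorted(sol.lonely), dtype=int, count=len(sol.lonely))
        if lon.size < self.params.eta:
            return None
        best = None
        for o in self.omic_ids:
            loc = heavy_subgraph(self.W[o][np.ix_(lon, lon)])
            if loc.size < self.params.eta:
                continue
            sub = lon[loc]
            w = pair_sum(self.W[o], sub)
            if w > 0 and (best is None or w > best[0]):
                best = (float(w), o, sub)
        if best is None:
            return None
        w, o, sub = best
        return ActionRecord("new_module", samples=[int(s) for s in sub], omics=[o], gain=w)

    def split_by_adding_omic(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        mem = mod.sample_array()
        best = None
        for o in self.omic_ids:
            if o in mod.omics:
                continue
            loc = heavy_subgraph(self.W[o][np.ix_(mem, mem)])
            if loc.size < self.params.eta:
                continue
            rest_loc = np.setdiff1d(np.arange(mem.size), loc)
            if 0 < rest_loc.size < self.params.eta:
                continue
            U, rest = mem[loc], mem[rest_loc]
            g = pair_sum(self.W[o], U) - self._cross(mod.omics, U, rest)
            if g > 0 and (best is None or g > best[0]):
                best = (float(g), o, U)
        if best is None:
            return None
        g, o, U = best
        return ActionRecord("split_by_adding_omic", module=ai,
                            samples=[int(s) for s in U], omics=[o], gain=g)

    def split_with_omic(self, sol: Solution, ai: int) -> ActionRecord | None:
        mod = sol.modules[ai]
        mem = mod.sample_array()
        old = self._pairs(mod.omics, mem)
        best = None
        for o in self._ordered_omics(mod.omics):
            loc = heavy_subgraph(self.W[o][np.ix_(mem, mem)])
            if loc.size < self.params.eta:
                continue
            rest_loc = np.setdiff1d(np.arange(mem.size), loc)
            if 0 < rest_loc.size < self.params.eta:
                continue
            U, rest = mem[loc], mem[rest_loc]
            new = self._pairs(mod.omics, rest) + pair_sum(self.W[o], U)
            g = new - old
            if g > 0 and (best is None or g > best[0]):
                best = (float(g), o, U)
        if best is None:
            return None
        g, o, U = best
        return ActionRecord("split_with_omic", module=ai,
                            samples=[int(s) for s in U], omics=[o], gain=g)


def evaluate_actions(sol: Solution, graphs: list[OmicGraph], params: SearchParams,
                     module_index: int) -> list[ActionRecord]:
    """Best candidate per action kind for one module (empty list if none apply)."""
    eng = _Engine(graphs, params)
    out = []
    for kind in ACTION_KINDS:
        rec = getattr(eng, kind)(sol, module_index)
        if rec is not None:
            out.append(rec)
    return out


def best_action(sol: Solution, graphs: list[OmicGraph], params: SearchParams,
                module_index: int) -> ActionRecord | None:
    """Highest-gain candidate; equal gains resolve by action-kind order."""
    best = None
    for rec in evaluate_actions(sol, graphs, params, module_index):
        if best is None or rec.gain > best.gain:
            best = rec
    return best


def apply_action(sol: Solution, rec: ActionRecord) -> None:
    """Mutate ``sol`` according to the action record."""
    kind = rec.kind
    if kind == "add_samples":
        mod = sol.modules[rec.module]
        mod.samples.update(rec.samples)
        sol.lonely.difference_update(rec.samples)
    elif kind == "remove_sample":
        mod = sol.modules[rec.module]
        mod.samples.difference_update(rec.samples)
        sol.lonely.update(rec.samples)
    elif kind == "move_samples":
        for u, src, dst in rec.payload:
            sol.modules[src].samples.discard(u)
            sol.modules[dst].samples.add(u)
    elif kind == "add_omic":
        sol.modules[rec.module].omics.update(rec.omics)
    elif kind == "remove_omic":
        sol.modules[rec.module].omics.difference_update(rec.omics)
    elif kind == "merge":
        A, B = sol.modules[rec.module], sol.modules[rec.other]
        A.samples.update(B.samples)
        A.omics = set(rec.omics)
        del sol.modules[rec.other]
    elif kind == "split":
        mod = sol.modules[rec.module]
        U = set(rec.samples)
        rest = mod.samples - U
        mod.samples = U
        sol.modules.append(Module(rest, set(rec.omics)))
    elif kind == "discard":
        mod = sol.modules[rec.module]
        placed: set[int] = set()
        for bi, moved in rec.payload.items():
            sol.modules[bi].samples.update(moved)
            placed.update(moved)
        sol.lonely.update(mod.samples - placed)
        del sol.modules[rec.module]
    elif kind == "new_module":
        sol.modules.append(Module(set(rec.samples), set(rec.omics)))
        sol.lonely.difference_update(rec.samples)
    elif kind == "split_by_adding_omic":
        mod = sol.modules[rec.module]
        U = set(rec.samples)
        rest = mod.samples - U
        new_omics = set(mod.omics) | set(rec.omics)
        if rest:
            sol.modules.append(Module(U, new_omics))
            mod.samples = rest
        else:
            mod.samples = U
            mod.omics = new_omics
    elif kind == "split_with_omic":
        mod = sol.modules[rec.module]
        U = set(rec.samples)
        rest = mod.samples - U
        if rest:
            sol.modules.append(Module(U, set(rec.omics)))
            mod.samples = rest
        else:
            mod.samples = U
            mod.omics = set(rec.omics)
    else:
        raise ValueError(f"unknown action kind {kind!r}")


def _force_discard_small(sol: Solution, graphs: list[OmicGraph], params: SearchParams) -> bool:
    """Dissolve converged modules smaller than eta (hard feasibility constraint).

    Samples go to the best-scoring surviving module (score >= 0) or lonely.
    Returns True if anything changed.
    """
    eng = _Engine(graphs, params)
    changed = False
    while True:
        small = [m for m in sol.modules if m.size < params.eta]
        if not small:
            return changed
        mod = small[0]
        ai = next(i for i, m in enumerate(sol.modules) if m is mod)
        mem = mod.sample_array()
        others = [bi for bi in range(len(sol.modules)) if bi != ai]
        assign: dict[int, list[int]] = {}
        if others:
            score_mat = np.stack(
                [eng.scores_to(sol.modules[bi].omics, sol.modules[bi].sample_array(), mem)
                 for bi in others]
            )
            best_bi = np.argmax(score_mat, axis=0)
            best_val = score_mat[best_bi, np.arange(mem.size)]
            for j, u in enumerate(mem):
                if best_val[j] >= 0:
                    assign.setdefault(others[int(best_bi[j])], []).append(int(u))
        apply_action(sol, ActionRecord("discard", module=ai, payload=assign, gain=0.0))
        changed = True


def optimize(start: Solution, graphs: list[OmicGraph], params: SearchParams,
             rng: np.random.Generator) -> tuple[Solution, dict]:
    """Greedy epochs until a full epoch applies no action.

    Each epoch walks a random permutation of the current modules and applies,
    per visited module, the single best strictly-positive-gain action. After
    convergence, modules smaller than eta are dissolved and the loop resumes
    once (actions themselves never shrink a module below eta, but undersized
    seeds can otherwise survive).
    """
    sol = start.copy()
    obj = objective(sol, graphs)
    # one objective trace per optimization round; a forced sub-eta cleanup
    # between rounds may lower the objective, so rounds are logged separately
    history: list[list[float]] = [[obj]]
    action_counts: dict[str, int] = {}
    epochs = 0
    converged = False
    for _round in range(5):
        while epochs < params.max_epochs:
            epochs += 1
            mods = list(sol.modules)
            order = rng.permutation(len(mods)) if mods else []
            applied = 0
            if not mods:
                rec = _Engine(graphs, params).new_module(sol)
                if rec is not None and rec.gain > 0:
                    apply_action(sol, rec)
                    obj += rec.gain
                    history[-1].append(obj)
                    action_counts[rec.kind] = action_counts.get(rec.kind, 0) + 1
                    applied += 1
            for pi in order:
                mod = mods[pi]
                ai = next((i for i, m in enumerate(sol.modules) if m is mod), None)
                if ai is None:
                    continue
                rec = best_action(sol, graphs, params, ai)
                if rec is not None and rec.gain > 0:
                    apply_action(sol, rec)
                    obj += rec.gain
                    history[-1].append(obj)
                    action_counts[rec.kind] = action_counts.get(rec.kind, 0) + 1
                    applied += 1
            if applied == 0:
                converged = True
                break
        if not converged:
            logger.warning("optimize: max_epochs=%d reached without convergence", params.max_epochs)
            break
        if not _force_discard_small(sol, graphs, params):
            break
        obj = objective(sol, graphs)
        history.append([obj])
        converged = False
    sol.validate()
    log = {
        "objective": objective(sol, graphs),
        "history": history,
        "epochs": epochs,
        "converged": converged,
        "action_counts": action_counts,
    }
    return sol, log


def detect_modules(omics, registry, wcfg, params: SearchParams | None = None,
                   null_cfg=None) -> tuple[Solution, dict]:
    """Full pipeline: graphs -> restarted search -> significance filter.

    Restart ``i`` seeds its RNG with ``rng_seed + i``; the restart with the
    highest objective wins (ties keep the earliest restart). Returns the
    filtered solution and a diagnostics dict with per-restart objectives, the
    winning restart's action log, the module/omic coverage table, the filter
    report and (under the gmm scheme) the frozen per-omic models.
    """
    from .graphs import build_graphs
    from .significance import NullTestConfig, filter_modules

    if params is None:
        params = SearchParams()
    graphs, models = build_graphs(omics, registry, wcfg)
    p = params.resolve(registry.n)
    best_sol, best_log, best_obj, best_i = None, None, -np.inf, -1
    per_restart = []
    for i in range(p.restarts):
        rng = np.random.default_rng((p.rng_seed + i) % _SEED_MOD)
        start = find_seeds(graphs, p, rng)
        sol, log = optimize(start, graphs, p, rng)
        per_restart.append(log["objective"])
        if log["objective"] > best_obj:
            best_sol, best_log, best_obj, best_i = sol, log, log["objective"], i
    if null_cfg is None:
        null_cfg = NullTestConfig(rng_seed=p.rng_seed)
    filtered, report = filter_modules(best_sol, graphs, null_cfg, eta=p.eta)
    omic_ids = [g.omic_id for g in graphs]
    diagnostics = {
        "per_restart_objectives": per_restart,
        "best_restart": best_i,
        "best_objective": best_obj,
        "action_counts": best_log["action_counts"],
        "epochs": best_log["epochs"],
        "history": best_log["history"],
        "omic_ids": omic_ids,
        "coverage": filtered.coverage(omic_ids),
        "filter_report": report,
        "graphs": graphs,
        "models": models,
        "params": p,
    }
    return filtered, diagnostics
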