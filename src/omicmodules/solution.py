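"""Modules, solutions, and the objective they are scored by.

A *module* is a set of samples together with the subset of omics it covers;
its weight is the sum of edge weights over all unordered sample pairs in every
covered omic. A *solution* is a set of disjoint modules plus the remaining
"lonely" samples, and the global objective is the sum of module weights
(lonely samples contribute nothing). Each unordered pair is counted once; an
ordered-pair convention would only rescale the objective by 2 and cannot
change the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import OmicGraph

__all__ = ["Module", "Solution", "module_weight", "objective", "pair_sum", "cross_sum"]


def pair_sum(W: np.ndarray, idx: np.ndarray) -> float:
    """Sum of W over unordered pairs within ``idx`` (zero diagonal assumed)."""
    if len(idx) < 2:
        return 0.0
    return float(W[np.ix_(idx, idx)].sum()) / 2.0


def cross_sum(W: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Sum of W over pairs with one endpoint in ``a`` and one in ``b``."""
    if len(a) == 0 or len(b) == 0:
        return 0.0
    return float(W[np.ix_(a, b)].sum())


@dataclass
class Module:
    """Sample set plus the non-empty set of omic ids it covers."""

    samples: set[int]
    omics: set[str]

    def __post_init__(self) -> None:
        self.samples = set(int(s) for s in self.samples)
        self.omics = set(self.omics)
        if not self.omics:
            raise ValueError("a module must cover at least one omic")

    @property
    def size(self) -> int:
        return len(self.samples)

    def sample_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.samples), dtype=int, count=len(self.samples))

    def copy(self) -> "Module":
        return Module(set(self.samples), set(self.omics))


@dataclass
class Solution:
    """Disjoint modules plus lonely samples, partitioning ``0..n-1``."""

    n: int
    modules: list[Module] = field(default_factory=list)
    lonely: set[int] = field(default_factory=set)

    def validate(self) -> None:
        counts = np.zeros(self.n, dtype=int)
        for mod in self.modules:
            arr = mod.sample_array()
            if arr.size and (arr.min() < 0 or arr.max() >= self.n):
                raise ValueError("sample index out of range")
            counts[arr] += 1
        counts[list(self.lonely)] += 1
        if (counts > 1).any():
            raise ValueError("modules/lonely overlap")
        if (counts == 0).any():
            raise ValueError("modules and lonely do not cover all samples")

    def labels(self) -> np.ndarray:
        """Per-sample module index; lonely samples get -1."""
        lab = np.full(self.n, -1, dtype=int)
        for i, mod in enumerate(self.modules):
            lab[mod.sample_array()] = i
        return lab

    def coverage(self, omic_ids: list[str]) -> np.ndarray:
        """Boolean modules x omics coverage table in the given omic order."""
        cov = np.zeros((len(self.modules), len(omic_ids)), dtype=bool)
        for i, mod in enumerate(self.modules):
            for j, oid in enumerate(omic_ids):
                cov[i, j] = oid in mod.omics
        return cov

    def copy(self) -> "Solution":
        return Solution(self.n, [m.copy() for m in self.modules], set(self.lonely))

    @classmethod
    def all_lonely(cls, n: int) -> "Solution":
        return cls(n=n, modules=[], lonely=set(range(n)))


def module_weight(module: Module, graphs: list[OmicGraph]) -> float:
    """weight(M) = sum over covered omics of the within-module pair sums."""
    by_id = {g.omic_id: g for g in graphs}
    arr = module.sample_array()
    return float(sum(pair_sum(by_id[o].weights, arr) for o in module.omics))


def objective(solution: Solution, graphs: list[OmicGraph]) -> float:
    """Sum of module weights; lonely samples contribute 0. Errors on overlap."""
    solution.validate()
    return float(sum(module_weight(m, graphs) for m in solution.modules))
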