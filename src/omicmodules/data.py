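"""Omic matrices and the shared sample registry.

An *omic* is one genome-wide data type (expression, methylation, ...) measured
over a common set of samples. Each omic arrives as a features x samples numeric
matrix. Samples may be missing from some omics ("partial" datasets); the
:class:`SampleRegistry` fixes one global sample ordering and records, per omic,
which of the global samples were actually measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicMatrix", "SampleRegistry", "load_omics"]


@dataclass
class OmicMatrix:
    """A single omic: real-valued matrix of shape (features, samples).

    Parameters
    ----------
    omic_id:
        Short identifier for the omic (e.g. ``"expression"``).
    values:
        Array of shape ``(n_features, n_samples)``. Must be finite; missing
        entries are rejected at construction.
    feature_ids, sample_ids:
        Row and column labels. Sample ids must be unique within the omic.
    """

    omic_id: str
    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"omic {self.omic_id!r}: values must be 2-D")
        if self.values.size == 0:
            raise ValueError(f"omic {self.omic_id!r}: empty matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"omic {self.omic_id!r}: non-finite entries (missing values "
                "must be imputed or the samples dropped before loading)"
            )
        p, m = self.values.shape
        if len(self.feature_ids) != p or len(self.sample_ids) != m:
            raise ValueError(f"omic {self.omic_id!r}: label/shape mismatch")
        if len(set(self.sample_ids)) != m:
            raise ValueError(f"omic {self.omic_id!r}: duplicated sample ids")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_by_features(self) -> np.ndarray:
        """Return the transposed (samples x features) view used by clusterers."""
        return self.values.T

    def subset_samples(self, keep: list[str]) -> "OmicMatrix":
        """Return a copy restricted to ``keep`` (sample ids, kept in given order)."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [pos[s] for s in keep if s in pos]
        ids = [self.sample_ids[c] for c in cols]
        return OmicMatrix(self.omic_id, self.values[:, cols], list(self.feature_ids), ids)

    def standardize(self, drop_constant: bool = True) -> "OmicMatrix":
        """Per-feature z-scoring; optionally drops all-constant features."""
        vals = self.values
        sd = vals.std(axis=1)
        if drop_constant:
            keep = sd > 0
            vals = vals[keep]
            sd = sd[keep]
            feats = [f for f, k in zip(self.feature_ids, keep) if k]
        else:
            feats = list(self.feature_ids)
            sd = np.where(sd > 0, sd, 1.0)
        vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
        return OmicMatrix(self.omic_id, vals, feats, list(self.sample_ids))


@dataclass
class SampleRegistry:
    """Global sample index shared across omics.

    ``all_sample_ids`` fixes the global ordering (indices ``0..n-1``);
    ``membership[omic_id]`` is a boolean vector over the global indices that is
    true where the sample was measured in that omic. Samples absent from an
    omic get zero-weight rows in that omic's graph and therefore never
    influence module decisions through it.
    """

    all_sample_ids: list[str]
    membership: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.all_sample_ids)) != len(self.all_sample_ids):
            raise ValueError("duplicated global sample ids")
        self._index = {s: i for i, s in enumerate(self.all_sample_ids)}

    @property
    def n(self) -> int:
        return len(self.all_sample_ids)

    def index_of(self, sample_id: str) -> int:
        return self._index[sample_id]

    def measured(self, omic_id: str) -> np.ndarray:
        return self.membership[omic_id]

    def global_indices(self, omic: OmicMatrix) -> np.ndarray:
        """Global index of each column of ``omic``, in column order."""
        return np.array([self._index[s] for s in omic.sample_ids], dtype=int)

    def validate(self) -> None:
        masks = list(self.membership.values())
        if masks:
            anywhere = np.logical_or.reduce(masks)
            if not bool(anywhere.all()):
                orphans = [s for s, a in zip(self.all_sample_ids, anywhere) if not a]
                raise ValueError(f"samples measured in no omic: {orphans[:5]}")

    @classmethod
    def from_omics(cls, omics: list[OmicMatrix]) -> "SampleRegistry":
        """Union of sample ids across omics, in first-seen order."""
        seen: dict[str, None] = {}
        for om in omics:
            for s in om.sample_ids:
                seen.setdefault(s)
        reg = cls(list(seen))
        for om in omics:
            mask = np.zeros(reg.n, dtype=bool)
            mask[[reg.index_of(s) for s in om.sample_ids]] = True
            reg.membership[om.omic_id] = mask
        reg.validate()
        return reg


def _read_matrix(path: str, transpose: bool) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    # check sample-id duplicates before pandas mangles them
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = header[1:]
    if not transpose and len(set(labels)) != len(labels):
        dup = sorted({s for s in labels if labels.count(s) > 1})
        raise ValueError(f"{path}: duplicated sample id(s) {dup}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.size == 0:
        raise ValueError(f"{path}: empty matrix")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: non-numeric cell ({err})") from None
    if transpose:
        df = df.T
        if len(set(df.columns)) != len(df.columns):
            raise ValueError(f"{path}: duplicated sample id(s) after transpose")
    return df


def load_omics(
    paths: list[str],
    omic_ids: list[str] | None = None,
    transpose: bool = False,
    standardize: bool = False,
) -> tuple[list[OmicMatrix], SampleRegistry]:
    """Load delimited omic matrices and build the shared registry.

    Files are TSV (or CSV by ``.csv`` extension) with a header row of sample
    ids and a first column of feature ids; ``transpose=True`` for
    samples x features files. The registry holds the union of sample ids in
    first-seen order.
    """
    if omic_ids is None:
        omic_ids = [f"omic{i + 1}" for i in range(len(paths))]
    omics = []
    for path, oid in zip(paths, omic_ids):
        df = _read_matrix(path, transpose)
        om = OmicMatrix(oid, df.to_numpy(), [str(f) for f in df.index],
                        [str(s) for s in df.columns])
        if standardize:
            om = om.standardize()
        omics.append(om)
    return omics, SampleRegistry.from_omics(omics)
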