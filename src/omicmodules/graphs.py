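"""Edge-weighted per-omic sample graphs.

Each omic is turned into a full graph on the global sample set: nodes are
samples, the signed edge weight w_l(u, v) measures how strongly samples u and v
co-vary in omic l. Weighting schemes must produce both positive and negative
weights — positive edges reward putting two samples in the same module for that
omic, negative edges penalise it; without negative weights a single all-sample
module covering every omic would be trivially optimal.

Two schemes are provided:

``consensus``
    Subsampled consensus clustering. The omic is clustered R times, each time
    on a random fraction of the samples, with a pluggable single-omic
    clusterer. For a pair (u, v) jointly sampled in a run, the run's vote is
    the co-clustering indicator minus the run's mean co-clustering rate; the
    edge weight is the mean vote across shared runs, minus a constant C that
    trades off single-omic versus multi-omic modules.

``gmm``
    Gaussian-mixture posterior similarity on a PCA projection. The edge weight
    is the probability that u and v share a mixture component minus its value
    under independent component draws, minus C. The fitted model is frozen so
    weights involving *new* samples can be computed later — this is the scheme
    used for classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .data import OmicMatrix, SampleRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "OmicGraph",
    "WeightingConfig",
    "SingleOmicClusterer",
    "SpectralEigengapClusterer",
    "consensus_edge_weights",
    "gmm_edge_weights",
    "build_graphs",
    "GmmOmicModel",
]

_SEED_MOD = 2**31 - 1


class SingleOmicClusterer(Protocol):
    """Pluggable base clusterer consumed by the consensus scheme."""

    def cluster(self, X: np.ndarray, seed: int) -> np.ndarray:
        """Cluster rows of ``X`` (samples x features); return integer labels."""
        ...


@dataclass
class SpectralEigengapClusterer:
    """Spectral clustering on a kNN Gaussian-kernel affinity.

    The kernel bandwidth is global: sigma is the median over samples of the
    distance to the ``scale_k``-th neighbour. A global bandwidth (rather than
    per-point local scaling) is deliberate: local scaling adapts to each
    point's own density and thereby welds diffuse, mutually dissimilar samples
    into a spurious "background" cluster, whereas under a global bandwidth
    such samples attach inconsistently to whichever real cluster is nearest —
    exactly the run-to-run instability the consensus weighting turns into
    negative edge weights. Each call also works on a random
    ``feature_fraction`` of the features (seeded): on structureless data the
    dominant chance directions move with the feature subset, so spurious
    partitions do not repeat across consensus runs, while planted structure
    spread over many informative features survives subsetting. The affinity is
    sparsified to the union of each node's ``n_neighbors`` strongest edges;
    the number of clusters is chosen by the largest eigengap of the normalised
    Laplacian spectrum within [``k_min``, ``k_max``]; the embedding rows are
    normalised and clustered with k-means.
    """

    n_neighbors: int = 15
    scale_k: int = 7
    k_min: int = 2
    k_max: int = 15
    kmeans_n_init: int = 3
    feature_fraction: float = 0.5

    def cluster(self, X: np.ndarray, seed: int) -> np.ndarray:
        m = X.shape[0]
        if m < self.k_min + 1:
            raise ValueError(f"need at least {self.k_min + 1} samples, got {m}")
        if 0 < self.feature_fraction < 1:
            p = X.shape[1]
            q = max(int(self.feature_fraction * p), 1)
            frng = np.random.default_rng(int(seed) % _SEED_MOD)
            X = X[:, frng.choice(p, size=q, replace=False)]
        D = squareform(pdist(X))
        kth = min(self.scale_k, m - 1)
        sigma = float(np.median(np.sort(D, axis=1)[:, kth]))
        if sigma <= 0:
            sigma = 1.0
        A = np.exp(-(D**2) / (sigma * sigma))
        np.fill_diagonal(A, 0.0)
        k = min(self.n_neighbors, m - 1)
        nn = np.argpartition(-A, k - 1, axis=1)[:, :k]
        keep = np.zeros_like(A, dtype=bool)
        keep[np.arange(m)[:, None], nn] = True
        keep |= keep.T
        A = np.where(keep, A, 0.0)
        deg = A.sum(axis=1)
        deg[deg <= 0] = 1.0
        dinv = 1.0 / np.sqrt(deg)
        M = A * np.outer(dinv, dinv)
        evals, evecs = np.linalg.eigh(M)  # ascending
        lam = 1.0 - evals[::-1]  # Laplacian eigenvalues, ascending
        kmax = min(self.k_max, m - 1)
        gaps = lam[self.k_min : kmax + 1] - lam[self.k_min - 1 : kmax]
        n_clusters = self.k_min + int(np.argmax(gaps))
        emb = evecs[:, -n_clusters:]
        norms = np.linalg.norm(emb, axis=1, keepdims=True)
        emb = emb / np.where(norms > 0, norms, 1.0)
        km = KMeans(
            n_clusters=n_clusters,
            n_init=self.kmeans_n_init,
            random_state=int(seed) % _SEED_MOD,
        )
        return km.fit_predict(emb)


@dataclass
class WeightingConfig:
    """Settings for turning one omic matrix into a signed sample graph.

    ``C`` balances module omic coverage: higher C favours modules covering a
    single strong omic, lower C favours multi-omic modules. ``R`` resampling
    runs at ``subsample_fraction`` drive the consensus scheme. ``global_shift``
    is added to every measured-pair weight and can be used to bias the
    expected number of modules.
    """

    scheme: str = "consensus"  # "consensus" | "gmm"
    C: float = 0.2
    R: int = 100
    subsample_fraction: float = 0.8
    global_shift: float = 0.0
    rng_seed: int = 0
    base_clusterer: SingleOmicClusterer | None = None
    # gmm scheme
    n_pcs: int = 10
    gmm_components: tuple[int, int] = (2, 10)
    gmm_covariance: str = "diag"

    def __post_init__(self) -> None:
        if self.scheme not in ("consensus", "gmm"):
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if self.C < 0:
            raise ValueError("C must be >= 0")
        if self.R < 1:
            raise ValueError("R must be >= 1")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.base_clusterer is None:
            self.base_clusterer = SpectralEigengapClusterer()

    def with_seed(self, seed: int) -> "WeightingConfig":
        cfg = WeightingConfig(**{**self.__dict__})
        cfg.rng_seed = int(seed)
        return cfg


@dataclass
class OmicGraph:
    """Full signed sample graph for one omic over the global sample index.

    ``weights`` is symmetric with zero diagonal; rows/columns of samples not
    measured in the omic are identically zero.
    """

    omic_id: str
    weights: np.ndarray
    measured: np.ndarray

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if not np.allclose(np.diag(w), 0.0):
            raise ValueError("diagonal must be zero")
        absent = ~self.measured
        if absent.any() and (np.abs(w[absent, :]).max() > 0):
            raise ValueError("unmeasured samples must have zero weights")
        if bool(self.measured.all()):
            off = w[np.triu_indices_from(w, k=1)]
            if not ((off > 0).any() and (off < 0).any()):
                warnings.warn(
                    f"omic {self.omic_id!r}: weights are not signed (need both "
                    "positive and negative edges for self-limiting modules)",
                    stacklevel=2,
                )

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def _embed(n: int, idx: np.ndarray, W_local: np.ndarray) -> np.ndarray:
    W = np.zeros((n, n))
    W[np.ix_(idx, idx)] = W_local
    return W


def consensus_edge_weights(
    matrix: OmicMatrix, registry: SampleRegistry, cfg: WeightingConfig
) -> OmicGraph:
    """Consensus-clustering edge weights for one omic.

    For run r (seeded ``rng_seed + r``) a without-replacement subsample of
    ``floor(subsample_fraction * n_measured)`` samples is clustered; the run's
    co-clustering indicator matrix cl_r is centred by its off-diagonal mean
    avg(cl_r) over the run's sampled pairs. The weight of a measured pair is
    ``mean over shared runs of (cl_r - avg(cl_r)) - C + global_shift``; pairs
    never jointly sampled get weight 0, and unmeasured samples get all-zero
    rows.
    """
    idx = registry.global_indices(matrix)
    m = len(idx)
    if m < 20:
        raise ValueError(f"omic {matrix.omic_id!r}: need >= 20 measured samples, got {m}")
    X = matrix.samples_by_features()
    size = int(np.floor(cfg.subsample_fraction * m))
    vote_sum = np.zeros((m, m))
    vote_cnt = np.zeros((m, m))
    for r in range(cfg.R):
        seed = int(cfg.rng_seed) + r
        rng = np.random.default_rng(seed % _SEED_MOD)
        sub = np.sort(rng.choice(m, size=size, replace=False))
        labels = cfg.base_clusterer.cluster(X[sub], seed=seed)
        co = (labels[:, None] == labels[None, :]).astype(float)
        avg = (co.sum() - size) / (size * (size - 1))
        block = np.ix_(sub, sub)
        vote_sum[block] += co - avg
        vote_cnt[block] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(vote_cnt > 0, vote_sum / np.maximum(vote_cnt, 1) - cfg.C + cfg.global_shift, 0.0)
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    return OmicGraph(matrix.omic_id, _embed(registry.n, idx, W), registry.measured(matrix.omic_id))


@dataclass
class GmmOmicModel:
    """Frozen projection + mixture for one omic (supports scoring new samples)."""

    omic_id: str
    feature_ids: list[str]
    pca: PCA
    gmm: GaussianMixture
    gamma_train: np.ndarray  # posteriors of training samples, aligned to train_idx
    train_idx: np.ndarray  # global indices of training samples
    C: float
    global_shift: float

    @property
    def pi_sq(self) -> float:
        return float(np.sum(self.gmm.weights_ ** 2))

    def posteriors(self, X_new: np.ndarray) -> np.ndarray:
        """Posterior component memberships for new samples (rows = samples)."""
        return self.gmm.predict_proba(self.pca.transform(X_new))

    def weights_to_train(self, X_new: np.ndarray) -> np.ndarray:
        """Edge weights from each new sample to every training sample.

        Returns an array of shape (n_new, n_train) aligned with ``train_idx``.
        """
        gamma_new = self.posteriors(X_new)
        return gamma_new @ self.gamma_train.T - self.pi_sq - self.C + self.global_shift


def gmm_edge_weights(
    matrix: OmicMatrix, registry: SampleRegistry, cfg: WeightingConfig
) -> tuple[OmicGraph, GmmOmicModel]:
    """Gaussian-mixture posterior-similarity edge weights for one omic.

    Measured samples are projected to ``cfg.n_pcs`` principal components and a
    Gaussian mixture is fitted, with the component count selected by BIC over
    ``cfg.gmm_components``. With gamma_u the posterior component vector of
    sample u and pi the mixing weights, the similarity sum_k gamma_uk gamma_vk
    is centred by its expectation under independent draws, sum_k pi_k^2, then
    shifted by -C:  w(u, v) = gamma_u . gamma_v - sum(pi^2) - C + global_shift.
    """
    idx = registry.global_indices(matrix)
    m = len(idx)
    if m < 20:
        raise ValueError(f"omic {matrix.omic_id!r}: need >= 20 measured samples, got {m}")
    X = matrix.samples_by_features()
    d = min(cfg.n_pcs, m - 1, matrix.n_features)
    pca = PCA(n_components=d, random_state=int(cfg.rng_seed) % _SEED_MOD)
    Z = pca.fit_transform(X)
    lo, hi = cfg.gmm_components
    hi = min(hi, m - 1)
    best = None
    for K in range(lo, hi + 1):
        gm = GaussianMixture(
            n_components=K,
            covariance_type=cfg.gmm_covariance,
            reg_covar=1e-4,
            n_init=1,
            random_state=(int(cfg.rng_seed) + K) % _SEED_MOD,
        )
        try:
            gm.fit(Z)
        except (np.linalg.LinAlgError, ValueError):
            logger.warning(
                "omic %s: singular covariance at K=%d, falling back to diagonal",
                matrix.omic_id, K,
            )
            gm = GaussianMixture(
                n_components=K,
                covariance_type="diag",
                reg_covar=1e-4,
                random_state=(int(cfg.rng_seed) + K) % _SEED_MOD,
            )
            gm.fit(Z)
        bic = gm.bic(Z)
        if best is None or bic < best[0]:
            best = (bic, gm)
    gmm = best[1]
    gamma = gmm.predict_proba(Z)
    pi_sq = float(np.sum(gmm.weights_ ** 2))
    W = gamma @ gamma.T - pi_sq - cfg.C + cfg.global_shift
    np.fill_diagonal(W, 0.0)
    W = (W + W.T) / 2.0
    graph = OmicGraph(matrix.omic_id, _embed(registry.n, idx, W), registry.measured(matrix.omic_id))
    model = GmmOmicModel(
        omic_id=matrix.omic_id,
        feature_ids=list(matrix.feature_ids),
        pca=pca,
        gmm=gmm,
        gamma_train=gamma,
        train_idx=idx,
        C=cfg.C,
        global_shift=cfg.global_shift,
    )
    return graph, model


def build_graphs(
    omics: list[OmicMatrix], registry: SampleRegistry, cfg: WeightingConfig
) -> tuple[list[OmicGraph], list[GmmOmicModel] | None]:
    """One graph per omic via the configured scheme; deterministic given the seed.

    Omic ``i`` uses a derived seed ``rng_seed + 1_000_003 * i`` so different
    omics do not share identical subsample draws. Returns ``(graphs, models)``
    where ``models`` is ``None`` under the consensus scheme.
    """
    graphs: list[OmicGraph] = []
    models: list[GmmOmicModel] = []
    for i, matrix in enumerate(omics):
        sub = cfg.with_seed(int(cfg.rng_seed) + 1_000_003 * i)
        if cfg.scheme == "consensus":
            graphs.append(consensus_edge_weights(matrix, registry, sub))
        else:
            g, mod = gmm_edge_weights(matrix, registry, sub)
            graphs.append(g)
            models.append(mod)
    return graphs, (models if cfg.scheme == "gmm" else None)
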