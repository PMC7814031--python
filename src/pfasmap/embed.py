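"""PCA reduction and 3D t-SNE embedding of the descriptor space.

The reference (training) set defines the map: descriptors are
standardized, reduced by PCA to the smallest number of components whose
cumulative explained variance reaches a target ratio (default 0.70), and
embedded in three dimensions by t-SNE.  The three output axes are the
map's coordinate system ("TSNE-PCA-1/2/3").

User-supplied compounds are never used to refit anything: their
descriptors are transformed by the stored PCA model and placed on the
existing t-SNE layout by inverse-distance-weighted interpolation over
their nearest reference points in PCA space.  Out-of-sample placement is
an explicit modelling choice, recorded in each point's provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .descriptors import DescriptorMatrix

__all__ = [
    "PCAModel",
    "TSNEConfig",
    "EmbeddingCoordinates",
    "fit_pca",
    "transform_pca",
    "fit_tsne",
    "place_user_points",
]


@dataclass
class PCAModel:
    """Standardization constants + PCA loadings for the reference set.

    ``loadings`` has shape (features, k) with orthonormal columns;
    ``explained_variance_ratio`` covers the k retained components and
    cumulates to at least ``variance_target`` with k minimal.
    """

    feature_names: list[str]
    center: np.ndarray            # per-feature mean of the training matrix
    scale: np.ndarray             # per-feature std (1.0 for constant columns)
    usable: np.ndarray            # bool mask of non-constant columns
    loadings: np.ndarray          # (n_usable_features, k)
    explained_variance_ratio: np.ndarray
    k: int
    variance_target: float

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("\n".join(self.feature_names).encode()).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "pfasmap-pca/1",
            "schema_hash": self.schema_hash,
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "usable": self.usable.astype(int).tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "k": self.k,
            "variance_target": self.variance_target,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "pfasmap-pca/1":
            raise ValueError(f"{path}: not a pfasmap PCA model file")
        return cls(
            feature_names=payload["feature_names"],
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
            usable=np.asarray(payload["usable"], dtype=bool),
            loadings=np.asarray(payload["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(
                payload["explained_variance_ratio"], dtype=float
            ),
            k=int(payload["k"]),
            variance_target=float(payload["variance_target"]),
        )


@dataclass(frozen=True)
class TSNEConfig:
    """t-SNE hyperparameters; steps is the optimizer iteration count."""

    perplexity: float = 50.0
    steps: int = 1000
    random_seed: int = 0
    output_dims: int = 3

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")
        if self.steps < 250:
            raise ValueError("steps must be at least 250")


@dataclass
class EmbeddingCoordinates:
    """Per-structure TSNE-PCA triples with provenance."""

    ids: list[str]
    coords: np.ndarray                      # (n, 3)
    provenance: list[str] = field(default_factory=list)   # reference | user_placed

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.provenance:
            self.provenance = ["reference"] * len(self.ids)
        if self.coords.shape != (len(self.ids), 3):
            raise ValueError("coords must be (n, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")


def _standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    center = matrix.mean(axis=0)
    std = matrix.std(axis=0, ddof=0)
    usable = std > 0
    scale = np.where(usable, std, 1.0)
    z = (matrix - center) / scale
    return z[:, usable], center, scale, usable


def fit_pca(matrix: DescriptorMatrix | np.ndarray, variance_target: float = 0.70,
            feature_names: Sequence[str] | None = None) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA; returns (model, training scores of the k retained components).

    Features are standardized (zero mean, unit variance; constant columns
    dropped) before the decomposition.  k is the smallest component count
    whose cumulative explained-variance ratio reaches ``variance_target``.
    """
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must lie in (0, 1]")
    if isinstance(matrix, DescriptorMatrix):
        names = list(matrix.frame.columns)
        X = matrix.frame.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = list(feature_names) if feature_names is not None else [
            f"f{i}" for i in range(X.shape[1])
        ]
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two rows")
    Z, center, scale, usable = _standardize(X)
    if Z.shape[1] == 0:
        raise ValueError("degenerate_matrix: zero total variance")
    pca = PCA(n_components=min(Z.shape), svd_solver="full")
    scores_full = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(cum))
    model = PCAModel(
        feature_names=names,
        center=center,
        scale=scale,
        usable=usable,
        loadings=pca.components_[:k].T.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:k].copy(),
        k=k,
        variance_target=variance_target,
    )
    return model, scores_full[:, :k]


def transform_pca(model: PCAModel, matrix: DescriptorMatrix | np.ndarray,
                  feature_names: Sequence[str] | None = None) -> np.ndarray:
    """Project vectors into the model's PCA space (never refits)."""
    if isinstance(matrix, DescriptorMatrix):
        names = list(matrix.frame.columns)
        X = matrix.frame.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        names = list(feature_names) if feature_names is not None else model.feature_names
    if names != model.feature_names:
        raise ValueError("schema_mismatch: feature columns differ from the trained model")
    Z = ((X - model.center) / model.scale)[:, model.usable]
    return Z @ model.loadings


def fit_tsne(scores: np.ndarray, config: TSNEConfig = TSNEConfig(),
             ids: Sequence[str] | None = None) -> EmbeddingCoordinates:
    """Embed PCA scores in 3D; identical seed + input gives identical output."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if n <= config.perplexity:
        raise ValueError(
            f"too_few_points: {n} points require perplexity < {n}, got {config.perplexity}"
        )
    tsne = TSNE(
        n_components=config.output_dims,
        perplexity=config.perplexity,
        max_iter=config.steps,
        random_state=config.random_seed,
        init="pca",
    )
    coords = tsne.fit_transform(scores)
    labels = list(ids) if ids is not None else [str(i) for i in range(n)]
    return EmbeddingCoordinates(ids=labels, coords=coords)


def place_user_points(
    reference: EmbeddingCoordinates,
    reference_scores: np.ndarray,
    user_scores: np.ndarray,
    k_neighbors: int = 10,
    user_ids: Sequence[str] | None = None,
) -> EmbeddingCoordinates:
    """Interpolate t-SNE coordinates for out-of-sample compounds.

    Each user point lands at the inverse-distance-weighted mean of the
    map coordinates of its k nearest reference points, with distances
    measured in PCA score space.  A user point coinciding with a
    reference point inherits that point's coordinates exactly.
    """
    reference_scores = np.asarray(reference_scores, dtype=float)
    user_scores = np.atleast_2d(np.asarray(user_scores, dtype=float))
    if reference_scores.shape[0] == 0:
        raise ValueError("empty_reference")
    k = min(k_neighbors, reference_scores.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(reference_scores)
    dist, idx = nn.kneighbors(user_scores)
    placed = np.empty((user_scores.shape[0], 3), dtype=float)
    for i in range(user_scores.shape[0]):
        d = dist[i]
        if d[0] == 0.0:
            placed[i] = reference.coords[idx[i][0]]
            continue
        w = 1.0 / d
        w /= w.sum()
        placed[i] = w @ reference.coords[idx[i]]
    labels = (
        list(user_ids)
        if user_ids is not None
        else [f"user-{i}" for i in range(user_scores.shape[0])]
    )
    return EmbeddingCoordinates(
        ids=labels, coords=placed, provenance=["user_placed"] * len(labels)
    )
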