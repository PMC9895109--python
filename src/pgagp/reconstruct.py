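"""Network improvement from embedding features.

Pairwise cosine similarity of the refined features gives a dense
similarity layer per node set (W_D for diseases, W_G for genes).  Each
is sparsified to a symmetric k-nearest-neighbor graph and either
replaces the original layer (the reconstructed variant, HNrc) or is
max-merged with it (the improved variant, HNim) so that no original
edge is ever lost.  The untouched original layers serve as the
random-walk baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agp import EmbeddingResult
from .errors import ConfigError, ValidationError
from .net_io import HeterogeneousNetwork

__all__ = [
    "VARIANTS",
    "SimilarityLayer",
    "ImprovedLayers",
    "feature_similarity",
    "sparsify_topk",
    "merge_max",
    "build_variant",
]

VARIANTS = ("HNim", "HNrc", "original")


@dataclass
class SimilarityLayer:
    """Dense cosine-similarity matrix of one node set and its sparsified form."""

    dense: np.ndarray
    sparse: np.ndarray
    k_neighbors: int


@dataclass
class ImprovedLayers:
    """Within-layer matrices fed to propagation: merged disease and gene layers."""

    M_D: np.ndarray
    M_G: np.ndarray
    variant: str

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; use one of {VARIANTS}")


def feature_similarity(Z_block: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity of feature rows.

    The diagonal degree normalization of the feature Gram reduces
    exactly to cosine similarity.  Rows with zero norm (isolated nodes
    can have all-zero features) get all-zero similarity rows; the
    diagonal is 1 for nonzero rows.
    """
    Z = np.asarray(Z_block, dtype=float)
    if Z.ndim != 2 or Z.shape[1] < 1:
        raise ConfigError(f"feature block must be 2-D with >=1 column, got {Z.shape}")
    norms = np.linalg.norm(Z, axis=1)
    inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
    W = (Z * inv[:, None]) @ (Z * inv[:, None]).T
    np.clip(W, -1.0, 1.0, out=W)
    np.fill_diagonal(W, np.where(norms > 0, 1.0, 0.0))
    return W


def sparsify_topk(W: np.ndarray, k: int) -> np.ndarray:
    """Symmetric k-nearest-neighbor sparsification of a similarity matrix.

    Per row, the k largest strictly positive off-diagonal entries are
    retained (ties broken toward the lower column index); the result is
    symmetrized by elementwise maximum.  Negative similarities are
    discarded — they would be meaningless as random-walk weights.
    """
    W = np.asarray(W, dtype=float)
    if W.shape[0] != W.shape[1]:
        raise ValidationError(f"similarity matrix must be square, got {W.shape}")
    if k < 1:
        raise ConfigError(f"k must be >= 1, got {k}")
    n = W.shape[0]
    out = np.zeros_like(W)
    for i in range(n):
        row = W[i].copy()
        row[i] = -np.inf  # drop diagonal
        # stable sort on negated values -> ties keep the lower index
        order = np.argsort(-row, kind="stable")[:k]
        keep = order[row[order] > 0]
        out[i, keep] = row[keep]
    return np.maximum(out, out.T)


def merge_max(W_sparse: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Elementwise maximum of the sparsified similarity and the original layer."""
    W_sparse = np.asarray(W_sparse, dtype=float)
    A = np.asarray(A, dtype=float)
    if W_sparse.shape != A.shape:
        raise ValidationError(
            f"shape mismatch: similarity {W_sparse.shape} vs adjacency {A.shape}"
        )
    return np.maximum(W_sparse, A)


def build_variant(
    h: HeterogeneousNetwork,
    emb: EmbeddingResult | None,
    variant: str = "HNim",
    k: int = 10,
) -> ImprovedLayers:
    """Assemble the within-layer matrices of one heterogeneous-network variant.

    HNim: original layers max-merged with the sparsified similarity
    layers; HNrc: sparsified similarity layers alone; original: the
    input adjacencies untouched (the baseline — no embedding needed).
    The association matrix R is carried through unchanged in every
    variant.
    """
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; use one of {VARIANTS}")
    A_D = h.disease_layer.adjacency
    A_G = h.gene_layer.adjacency
    if variant == "original":
        return ImprovedLayers(M_D=A_D.copy(), M_G=A_G.copy(), variant=variant)
    if emb is None:
        raise ConfigError(f"variant {variant!r} requires an embedding")
    Z_D, Z_G = emb.split(h.n_diseases)
    W_D = sparsify_topk(feature_similarity(Z_D), k)
    W_G = sparsify_topk(feature_similarity(Z_G), k)
    if variant == "HNrc":
        return ImprovedLayers(M_D=W_D, M_G=W_G, variant=variant)
    return ImprovedLayers(M_D=merge_max(W_D, A_D), M_G=merge_max(W_G, A_G), variant=variant)
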