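"""Adaptive Gaussian random projection (AGP) embedding.

The embedding sketches a weighted polynomial of the symmetrically
normalized adjacency,

    B = sum_{r=0..q} alpha_r * A_norm^r,

into a random Gaussian subspace S (entries N(0, 1/d')), giving raw
features X = B S without ever forming a matrix power: X preserves the
high-order proximity Gram B B^T in expectation because E[S S^T] = I.
The raw features are then refined adaptively: eigendecompose the Gram
of the column-centered features, keep the smallest number of leading
eigendirections whose relative accumulative contribution of eigenvalues
reaches a threshold, and project X onto them.  All the linear algebra
is on d' x d' matrices, never n x n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateSpectrumError
from .net_io import HeterogeneousNetwork, combined_adjacency

__all__ = [
    "EmbeddingConfig",
    "EmbeddingResult",
    "normalize_symmetric",
    "gaussian_subspace",
    "project_features",
    "accumulative_contribution",
    "refine_features",
    "embed",
]

#: eigenvalues below this fraction of the leading one count as zero
_EIG_CLAMP_REL = 1e-12


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the AGP embedding.

    Parameters
    ----------
    p : float
        Proportion of the node count used as the initial sketch
        dimension, d' = max(1, round(p * n)).  0 < p <= 1.
    q : int
        Order of the adjacency polynomial.
    alpha : tuple of float
        Weights alpha_0..alpha_q of the polynomial terms; length q + 1,
        at least one nonzero.
    threshold : float
        Accumulative eigenvalue-contribution threshold used to select
        the final dimension d.  0 < threshold <= 1.
    seed : int
        Seed of the Gaussian subspace.
    """

    p: float = 0.1
    q: int = 3
    alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    threshold: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ConfigError(f"p must be in (0, 1], got {self.p}")
        if self.q < 0:
            raise ConfigError(f"q must be non-negative, got {self.q}")
        object.__setattr__(self, "alpha", tuple(float(a) for a in self.alpha))
        if len(self.alpha) != self.q + 1:
            raise ConfigError(
                f"alpha must have q+1={self.q + 1} entries, got {len(self.alpha)}"
            )
        if not any(a != 0 for a in self.alpha):
            raise ConfigError("at least one alpha weight must be nonzero")
        if not all(np.isfinite(self.alpha)):
            raise ConfigError("alpha weights must be finite")
        if not 0 < self.threshold <= 1:
            raise ConfigError(f"threshold must be in (0, 1], got {self.threshold}")

    def initial_dim(self, n: int) -> int:
        """Initial sketch dimension d' for an n-node network.

        Fractional dimensions round up, so a small p on a small network
        still retains at least the requested fraction (and the
        contribution threshold keeps something to select over).
        """
        return max(1, int(np.ceil(self.p * n - 1e-9)))


@dataclass
class EmbeddingResult:
    """Raw and refined node features together with the selection diagnostics."""

    raw_features: np.ndarray  # X, n x d'
    final_features: np.ndarray  # Z = X V_d, n x d
    eigenvalues: np.ndarray  # spectrum of Y^T Y, descending, clamped at 0
    contributions: np.ndarray  # accumulative contributions c_k
    selected_dim: int  # d
    projection_basis: np.ndarray  # V_d, d' x d

    @property
    def initial_dim(self) -> int:
        return self.raw_features.shape[1]

    def split(self, n_diseases: int) -> tuple[np.ndarray, np.ndarray]:
        """Split the refined features into the disease block Z_D and gene block Z_G."""
        return self.final_features[:n_diseases], self.final_features[n_diseases:]


def normalize_symmetric(A: np.ndarray) -> np.ndarray:
    """Symmetric degree normalization D^{-1/2} A D^{-1/2}.

    Rows and columns of isolated nodes (zero degree) stay all-zero.
    The spectral radius of the result is at most 1.
    """
    A = np.asarray(A, dtype=float)
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    return A * np.outer(inv_sqrt, inv_sqrt)


def gaussian_subspace(n: int, d_prime: int, seed: int) -> np.ndarray:
    """Random subspace S (n x d') with i.i.d. N(0, 1/d') entries.

    E[S S^T] = I, so sketching with S preserves Gram matrices in
    expectation; the same seed reproduces the same matrix bitwise.
    """
    if d_prime <= 0:
        raise ConfigError(f"initial dimension must be positive, got {d_prime}")
    if n <= 0:
        raise ConfigError(f"node count must be positive, got {n}")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0 / np.sqrt(d_prime), size=(n, d_prime))


def project_features(
    A_norm: np.ndarray, S: np.ndarray, alpha: Sequence[float]
) -> np.ndarray:
    """Sketch the adjacency polynomial: X = sum_r alpha_r A_norm^r S.

    Computed by repeated propagation S_r = A_norm S_{r-1}; only q
    matrix-times-sketch products, never an n x n matrix power.
    """
    A_norm = np.asarray(A_norm, dtype=float)
    S = np.asarray(S, dtype=float)
    if A_norm.shape[1] != S.shape[0]:
        raise ConfigError(
            f"shape mismatch: adjacency {A_norm.shape} vs subspace {S.shape}"
        )
    S_r = S
    X = alpha[0] * S
    for a_r in alpha[1:]:
        S_r = A_norm @ S_r
        X = X + a_r * S_r
    return X


def accumulative_contribution(eigenvalues: np.ndarray) -> np.ndarray:
    """Relative accumulative contribution c_k = sum_{i<=k} lam_i / sum_i lam_i."""
    lam = np.asarray(eigenvalues, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise DegenerateSpectrumError("spectrum has no positive eigenvalue")
    return np.cumsum(lam) / total


def refine_features(X: np.ndarray, threshold: float) -> EmbeddingResult:
    """Adaptive refinement of raw features by eigen-contribution thresholding.

    Column-center X into Y, eigendecompose the d' x d' Gram Y^T Y
    (eigenvalues descending, tiny/negative values clamped to zero),
    select d = min{k : c_k >= threshold}, and project the *raw*
    features onto the retained eigenvectors: Z = X V_d.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ConfigError(f"feature matrix must be 2-D with >=1 column, got {X.shape}")
    if not 0 < threshold <= 1:
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")

    Y = X - X.mean(axis=0, keepdims=True)
    gram = Y.T @ Y
    lam, V = np.linalg.eigh(gram)
    order = np.argsort(lam)[::-1]  # descending
    lam = lam[order]
    V = V[:, order]
    if lam.size and lam[0] > 0:
        lam = np.where(lam < _EIG_CLAMP_REL * lam[0], 0.0, lam)
    else:
        lam = np.zeros_like(lam)
    contributions = accumulative_contribution(lam)  # raises if all zero
    # tiny slack so cumsum round-off cannot push the selection past the
    # rank of the spectrum when threshold == 1
    reached = contributions >= threshold - 1e-12
    d = int(np.argmax(reached)) + 1 if reached.any() else lam.size
    V_d = V[:, :d]
    return EmbeddingResult(
        raw_features=X,
        final_features=X @ V_d,
        eigenvalues=lam,
        contributions=contributions,
        selected_dim=d,
        projection_basis=V_d,
    )


def embed(h: HeterogeneousNetwork, config: EmbeddingConfig) -> EmbeddingResult:
    """Run the full AGP pipeline on a heterogeneous network.

    Rows of the result follow the combined node order: diseases first
    (rows 0..n_D-1), then genes.
    """
    A = combined_adjacency(h)
    A_norm = normalize_symmetric(A)
    n = A.shape[0]
    d_prime = config.initial_dim(n)
    S = gaussian_subspace(n, d_prime, config.seed)
    X = project_features(A_norm, S, config.alpha)
    return refine_features(X, config.threshold)
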