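"""Random walk with restart (RWR) on the two-layer heterogeneous network.

The walker moves inside the disease layer or the gene layer and jumps
between layers through the association matrix with probability lambda;
at every step it restarts at the query distribution with probability r.
Scores are the stationary probabilities P_inf of the iteration

    P_{t+1} = (1 - r) T_H P_t + r P_0.

All-zero columns (nodes with no outgoing transitions) are left as
zeros: mass leaking through them shrinks the total uniformly within a
query and therefore never changes a ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .net_io import HeterogeneousNetwork
from .reconstruct import ImprovedLayers

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "TransitionMatrix",
    "PropagationResult",
    "column_normalize",
    "build_transition",
    "transition_from_layers",
    "restart_vector",
    "rwr",
    "score_all_diseases",
]


@dataclass(frozen=True)
class PropagationConfig:
    """Parameters of the heterogeneous random walk with restart.

    jump_lambda is the inter-layer jump probability, restart_r the
    restart probability, and seed_gene_weight (eta) the fraction of
    restart mass placed on the query disease's known genes (the rest
    stays on the disease node itself).
    """

    jump_lambda: float = 0.5
    restart_r: float = 0.7
    tol: float = 1e-6
    max_iter: int = 1000
    seed_gene_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.jump_lambda <= 1:
            raise ConfigError(f"jump_lambda must be in [0, 1], got {self.jump_lambda}")
        if not 0 < self.restart_r <= 1:
            raise ConfigError(f"restart_r must be in (0, 1], got {self.restart_r}")
        if self.tol <= 0:
            raise ConfigError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1:
            raise ConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        if not 0 <= self.seed_gene_weight <= 1:
            raise ConfigError(
                f"seed_gene_weight must be in [0, 1], got {self.seed_gene_weight}"
            )


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix with the diseases-first layout."""

    matrix: np.ndarray
    n_diseases: int

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValidationError(f"transition matrix must be square, got {M.shape}")
        self.matrix = M

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class PropagationResult:
    """Stationary scores of one query plus convergence diagnostics."""

    scores: np.ndarray
    iterations: int
    residual: float
    converged: bool


def column_normalize(M: np.ndarray) -> np.ndarray:
    """Divide each nonzero column by its sum; all-zero columns stay zero."""
    M = np.asarray(M, dtype=float)
    if (M < 0).any():
        raise ValidationError("matrix must be non-negative for column normalization")
    sums = M.sum(axis=0)
    inv = np.where(sums > 0, 1.0 / np.where(sums > 0, sums, 1.0), 0.0)
    return M * inv[None, :]


def build_transition(
    T_D: np.ndarray,
    T_G: np.ndarray,
    R_prime: np.ndarray,
    Q: np.ndarray,
    jump_lambda: float,
) -> TransitionMatrix:
    """Assemble the block transition matrix of the heterogeneous walk.

    T_H = [[(1-lambda) T_D, lambda R'], [lambda Q, (1-lambda) T_G]],
    followed by one more column normalization of the assembled matrix
    so that nodes missing from a layer (zero block columns) still have
    stochastic columns.
    """
    if not 0 <= jump_lambda <= 1:
        raise ConfigError(f"jump_lambda must be in [0, 1], got {jump_lambda}")
    n_d = T_D.shape[0]
    n_g = T_G.shape[0]
    if T_D.shape != (n_d, n_d) or T_G.shape != (n_g, n_g):
        raise ValidationError("diagonal blocks must be square")
    if R_prime.shape != (n_d, n_g) or Q.shape != (n_g, n_d):
        raise ValidationError(
            f"off-diagonal blocks have wrong shapes: {R_prime.shape}, {Q.shape}"
        )
    lam = jump_lambda
    T = np.block(
        [
            [(1 - lam) * T_D, lam * R_prime],
            [lam * Q, (1 - lam) * T_G],
        ]
    )
    return TransitionMatrix(matrix=column_normalize(T), n_diseases=n_d)


def transition_from_layers(
    h: HeterogeneousNetwork, layers: ImprovedLayers, jump_lambda: float
) -> TransitionMatrix:
    """Column-normalize M_D, M_G, R, R^T and assemble the full transition."""
    R = h.associations.matrix
    return build_transition(
        T_D=column_normalize(layers.M_D),
        T_G=column_normalize(layers.M_G),
        R_prime=column_normalize(R),
        Q=column_normalize(R.T),
        jump_lambda=jump_lambda,
    )


def restart_vector(
    h: HeterogeneousNetwork, query_disease: str, eta: float
) -> np.ndarray:
    """Restart distribution of one query over all n_D + n_G nodes.

    Mass 1 - eta sits on the query disease node and mass eta is split
    uniformly over its known (training) genes; a disease without known
    genes gets all mass on its own node.
    """
    if query_disease not in h.disease_layer.index:
        raise ValidationError(f"unknown disease {query_disease!r}")
    if not 0 <= eta <= 1:
        raise ConfigError(f"eta must be in [0, 1], got {eta}")
    d_idx = h.disease_layer.index[query_disease]
    genes = np.nonzero(h.associations.matrix[d_idx])[0]
    P0 = np.zeros(h.n_nodes)
    if genes.size == 0 or eta == 0:
        P0[d_idx] = 1.0
    else:
        P0[d_idx] = 1.0 - eta
        P0[h.n_diseases + genes] = eta / genes.size
    return P0


def rwr(
    T: TransitionMatrix,
    P0: np.ndarray,
    restart_r: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationResult:
    """Iterate the restart recursion to its stationary distribution.

    Convergence is declared when the L1 change between successive
    probability vectors drops below tol; hitting max_iter first returns
    the last iterate flagged as non-converged.
    """
    P0 = np.asarray(P0, dtype=float)
    if P0.shape != (T.n_nodes,):
        raise ValidationError(f"P0 has shape {P0.shape}, expected ({T.n_nodes},)")
    if not np.isclose(P0.sum(), 1.0):
        raise ValidationError(f"P0 must sum to 1, got {P0.sum()}")
    if not 0 < restart_r <= 1:
        raise ConfigError(f"restart_r must be in (0, 1], got {restart_r}")
    M = T.matrix
    P = P0
    residual = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        P_next = (1 - restart_r) * (M @ P) + restart_r * P0
        residual = float(np.abs(P_next - P).sum())
        P = P_next
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        logger.warning(
            "RWR did not converge after %d iterations (residual %.3g)",
            iterations,
            residual,
        )
    return PropagationResult(
        scores=P, iterations=iterations, residual=residual, converged=converged
    )


def score_all_diseases(
    h: HeterogeneousNetwork,
    layers: ImprovedLayers,
    config: PropagationConfig,
    queries: list[str],
) -> pd.DataFrame:
    """Gene-relevance scores for each query disease (diseases x genes frame).

    The transition matrix is built once and shared; each query runs its
    own restart vector through the walk, and the gene block of the
    stationary vector becomes that disease's score row.
    """
    if not queries:
        raise ValidationError("query list is empty")
    T = transition_from_layers(h, layers, config.jump_lambda)
    rows = np.empty((len(queries), h.n_genes))
    for i, disease in enumerate(queries):
        P0 = restart_vector(h, disease, config.seed_gene_weight)
        result = rwr(T, P0, config.restart_r, config.tol, config.max_iter)
        rows[i] = result.scores[h.n_diseases :]
    return pd.DataFrame(rows, index=queries, columns=h.gene_layer.index.labels)
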