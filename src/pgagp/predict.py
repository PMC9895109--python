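"""Ranked candidate-gene prediction: the three PGAGP strategies.

HNim and HNrc embed the heterogeneous network, rebuild the within-layer
networks from the embedding (max-merged with, or replacing, the
originals) and rank genes by random walk with restart; CSim skips the
walk and ranks genes directly by the cosine similarity between disease
and gene feature vectors; "original" runs the walk on the untouched
network (the RWRH baseline).  Known training genes of the query disease
are excluded from its candidate list, and ties are broken by gene index
so identical runs produce identical rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agp import EmbeddingConfig, embed
from .errors import ConfigError, ValidationError
from .net_io import HeterogeneousNetwork
from .propagate import PropagationConfig, score_all_diseases
from .reconstruct import build_variant

__all__ = ["STRATEGIES", "RankedPrediction", "csim_scores", "rank_genes", "predict"]

STRATEGIES = ("HNim", "HNrc", "CSim", "original")


@dataclass
class RankedPrediction:
    """Descending-score candidate-gene list for one disease."""

    disease: str
    genes: list[tuple[str, float]]

    @property
    def labels(self) -> list[str]:
        return [g for g, _ in self.genes]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.genes])

    def top(self, k: int) -> list[str]:
        return self.labels[:k]


def csim_scores(Z_D: np.ndarray, Z_G: np.ndarray) -> np.ndarray:
    """Cosine similarity between every disease and every gene feature row.

    Zero-norm rows score 0 against everything.
    """
    Z_D = np.asarray(Z_D, dtype=float)
    Z_G = np.asarray(Z_G, dtype=float)
    if Z_D.shape[1] != Z_G.shape[1]:
        raise ValidationError(
            f"feature blocks disagree on dimension: {Z_D.shape[1]} vs {Z_G.shape[1]}"
        )

    def _unit(Z: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(Z, axis=1)
        inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
        return Z * inv[:, None]

    S = _unit(Z_D) @ _unit(Z_G).T
    return np.clip(S, -1.0, 1.0)


def rank_genes(
    h: HeterogeneousNetwork, disease: str, gene_scores: np.ndarray
) -> RankedPrediction:
    """Sort candidate genes of one disease by descending score.

    The disease's known (training) genes are removed from the candidate
    list; score ties are broken by gene index (stable sort).
    """
    if gene_scores.shape != (h.n_genes,):
        raise ValidationError(
            f"score vector has shape {gene_scores.shape}, expected ({h.n_genes},)"
        )
    d_idx = h.disease_layer.index[disease]
    known = set(np.nonzero(h.associations.matrix[d_idx])[0])
    order = np.argsort(-gene_scores, kind="stable")
    labels = h.gene_layer.index.labels
    genes = [
        (labels[j], float(gene_scores[j])) for j in order if j not in known
    ]
    return RankedPrediction(disease=disease, genes=genes)


def predict(
    h: HeterogeneousNetwork,
    strategy: str = "HNim",
    emb_config: EmbeddingConfig | None = None,
    prop_config: PropagationConfig | None = None,
    queries: list[str] | None = None,
    knn: int = 10,
) -> list[RankedPrediction]:
    """Run one PGAGP strategy end to end and rank candidates per query.

    ``queries=None`` predicts for every disease in the network.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
    emb_config = emb_config or EmbeddingConfig()
    prop_config = prop_config or PropagationConfig()
    if queries is None:
        queries = list(h.disease_layer.index.labels)
    if not queries:
        raise ValidationError("query list is empty")

    if strategy == "CSim":
        emb = embed(h, emb_config)
        Z_D, Z_G = emb.split(h.n_diseases)
        S = csim_scores(Z_D, Z_G)
        return [
            rank_genes(h, q, S[h.disease_layer.index[q]]) for q in queries
        ]

    emb = None if strategy == "original" else embed(h, emb_config)
    layers = build_variant(h, emb, variant=strategy, k=knn)
    scores = score_all_diseases(h, layers, prop_config, queries)
    return [rank_genes(h, q, scores.loc[q].to_numpy()) for q in queries]
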