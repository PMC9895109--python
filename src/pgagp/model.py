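"""Model/Results interface tying the pipeline together.

:class:`PGAGP` is constructed from a heterogeneous network plus the
embedding and propagation settings; :meth:`PGAGP.fit` runs the
embedding and network-improvement stages once and returns a
:class:`PGAGPResults` that carries the fitted artifacts (spectrum,
selected dimension, improved layers) and exposes prediction,
evaluation and a text summary — the fit is reused across queries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agp import EmbeddingConfig, EmbeddingResult, embed
from .errors import ConfigError
from .evaluate import EvaluationReport, cross_validate, evaluate_predictions
from .net_io import (
    HeterogeneousNetwork,
    read_associations,
    read_edge_list,
)
from .predict import (
    STRATEGIES,
    RankedPrediction,
    csim_scores,
    rank_genes,
)
from .propagate import PropagationConfig, score_all_diseases
from .reconstruct import ImprovedLayers, build_variant

__all__ = ["PGAGP", "PGAGPResults"]


class PGAGP:
    """Disease-gene prioritization model on a heterogeneous network.

    Parameters
    ----------
    network : HeterogeneousNetwork
        Disease layer, gene (PPI) layer and known associations.
    strategy : {"HNim", "HNrc", "CSim", "original"}
        HNim max-merges embedding-similarity edges into the original
        layers before the walk (the recommended strategy); HNrc walks
        on the similarity layers alone; CSim ranks by disease-gene
        feature cosine; "original" is the plain heterogeneous-walk
        baseline.
    embedding, propagation
        Stage configurations; defaults follow the recommended settings
        (p=0.1, threshold=0.5, lambda=0.5, r=0.7).
    knn : int
        Neighbors kept per node when sparsifying similarity layers.
    """

    def __init__(
        self,
        network: HeterogeneousNetwork,
        strategy: str = "HNim",
        embedding: EmbeddingConfig | None = None,
        propagation: PropagationConfig | None = None,
        knn: int = 10,
    ):
        if strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {strategy!r}; use one of {STRATEGIES}")
        self.network = network
        self.strategy = strategy
        self.embedding = embedding or EmbeddingConfig()
        self.propagation = propagation or PropagationConfig()
        self.knn = knn

    @classmethod
    def from_edge_lists(
        cls,
        ppi_path,
        ddn_path,
        dgn_path,
        weighted_ddn: bool = True,
        header: bool = False,
        **kwargs,
    ) -> "PGAGP":
        """Build the model straight from the three TSV edge lists."""
        gene_layer = read_edge_list(ppi_path, weighted=False, header=header)
        disease_layer = read_edge_list(ddn_path, weighted=weighted_ddn, header=header)
        associations = read_associations(
            dgn_path, disease_layer.index, gene_layer.index, header=header
        )
        network = HeterogeneousNetwork(disease_layer, gene_layer, associations)
        return cls(network, **kwargs)

    def fit(self) -> "PGAGPResults":
        """Run embedding and network improvement; propagation is deferred
        to per-query prediction on the results object."""
        emb = None if self.strategy == "original" else embed(self.network, self.embedding)
        layers = (
            None
            if self.strategy == "CSim"
            else build_variant(self.network, emb, variant=self.strategy, k=self.knn)
        )
        return PGAGPResults(model=self, embedding_result=emb, layers=layers)

    def cross_validate(self, k_folds: int = 5, seed: int = 0) -> EvaluationReport:
        """k-fold cross-validation of this model's strategy and settings."""
        return cross_validate(
            self.network,
            strategy=self.strategy,
            emb_config=self.embedding,
            prop_config=self.propagation,
            k_folds=k_folds,
            seed=seed,
            knn=self.knn,
        )


@dataclass
class PGAGPResults:
    """Fitted artifacts of one PGAGP run plus prediction/evaluation methods."""

    model: PGAGP
    embedding_result: EmbeddingResult | None
    layers: ImprovedLayers | None

    @property
    def network(self) -> HeterogeneousNetwork:
        return self.model.network

    @property
    def selected_dim(self) -> int | None:
        return None if self.embedding_result is None else self.embedding_result.selected_dim

    def score_frame(self, queries: list[str] | None = None) -> pd.DataFrame:
        """Raw disease x gene score table (before candidate filtering)."""
        h = self.network
        if queries is None:
            queries = list(h.disease_layer.index.labels)
        if self.model.strategy == "CSim":
            Z_D, Z_G = self.embedding_result.split(h.n_diseases)
            S = csim_scores(Z_D, Z_G)
            rows = [S[h.disease_layer.index[q]] for q in queries]
            return pd.DataFrame(rows, index=queries, columns=h.gene_layer.index.labels)
        return score_all_diseases(h, self.layers, self.model.propagation, queries)

    def predict(self, queries: list[str] | None = None) -> list[RankedPrediction]:
        """Ranked candidate genes per query disease (training genes excluded)."""
        h = self.network
        if queries is None:
            queries = list(h.disease_layer.index.labels)
        frame = self.score_frame(queries)
        return [rank_genes(h, q, frame.loc[q].to_numpy()) for q in queries]

    def evaluate(
        self, positives: dict[str, set[str]], queries: list[str] | None = None
    ) -> EvaluationReport:
        """Score this fit's rankings against a held-out truth map."""
        if queries is None:
            queries = sorted(positives)
        return evaluate_predictions(self.predict(queries), positives)

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        h = self.network
        m = self.model
        lines = [
            "PGAGP disease-gene prioritization",
            "=" * 40,
            f"strategy            {m.strategy}",
            f"diseases            {h.n_diseases} ({h.disease_layer.n_edges} edges)",
            f"genes               {h.n_genes} ({h.gene_layer.n_edges} edges)",
            f"known associations  {h.associations.n_associations}",
        ]
        if self.embedding_result is not None:
            er = self.embedding_result
            lines += [
                f"initial dim d'      {er.initial_dim} (p={m.embedding.p})",
                f"selected dim d      {er.selected_dim} "
                f"(threshold={m.embedding.threshold})",
                f"top contributions   "
                + ", ".join(f"{c:.3f}" for c in er.contributions[:5]),
            ]
        if self.layers is not None:
            nnz_d = int(np.count_nonzero(np.triu(self.layers.M_D, 1)))
            nnz_g = int(np.count_nonzero(np.triu(self.layers.M_G, 1)))
            lines += [
                f"variant layers      {self.layers.variant}: "
                f"{nnz_d} disease edges, {nnz_g} gene edges",
                f"walk parameters     lambda={m.propagation.jump_lambda}, "
                f"r={m.propagation.restart_r}, eta={m.propagation.seed_gene_weight}",
            ]
        return "\n".join(lines)
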