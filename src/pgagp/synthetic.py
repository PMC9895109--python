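"""Seeded planted-structure generator for disease-gene heterogeneous networks.

The generator emulates the statistical premise of network-based gene
prioritization — genes of the same or similar diseases cluster together —
with the minimal generative model that has that property: a planted
partition.  Diseases and genes are split into matched modules; each
layer is a stochastic block model (within-module edge probability p_in,
between-module p_out), and disease-gene associations appear with
probability assoc_in between matched modules and assoc_out otherwise.
A fraction of the matched-module (signal) associations is withheld as
recoverable ground truth and removed from the training network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ValidationError
from .net_io import (
    AssociationTable,
    HeterogeneousNetwork,
    LayerGraph,
    NodeIndex,
    assemble_heterogeneous,
)

__all__ = ["SyntheticSpec", "SyntheticNetwork", "generate", "default_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-partition heterogeneous network."""

    n_modules: int = 4
    diseases_per_module: int = 5
    genes_per_module: int = 30
    p_in: float = 0.3
    p_out: float = 0.02
    assoc_in: float = 0.2
    assoc_out: float = 0.005
    holdout_fraction: float = 0.3
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ConfigError(f"n_modules must be >= 1, got {self.n_modules}")
        if self.diseases_per_module < 1 or self.genes_per_module < 1:
            raise ConfigError("module sizes must be >= 1")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ConfigError(
                f"need 0 <= p_out < p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}"
            )
        if not 0 <= self.assoc_out < self.assoc_in <= 1:
            raise ConfigError(
                "need 0 <= assoc_out < assoc_in <= 1, got "
                f"assoc_in={self.assoc_in}, assoc_out={self.assoc_out}"
            )
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError(
                f"holdout_fraction must be in (0, 1), got {self.holdout_fraction}"
            )

    @property
    def n_diseases(self) -> int:
        return self.n_modules * self.diseases_per_module

    @property
    def n_genes(self) -> int:
        return self.n_modules * self.genes_per_module


@dataclass
class SyntheticNetwork:
    """A generated network (truth removed from R) plus the held-out truth."""

    network: HeterogeneousNetwork
    truth: AssociationTable
    module_labels: dict[str, int]

    def truth_map(self) -> dict[str, set[str]]:
        """Held-out positives as disease -> gene-label sets."""
        out: dict[str, set[str]] = {}
        for d, g in self.truth.pairs():
            out.setdefault(d, set()).add(g)
        return out


def _planted_layer(
    rng: np.random.Generator, modules: np.ndarray, p_in: float, p_out: float
) -> np.ndarray:
    n = modules.size
    same = modules[:, None] == modules[None, :]
    probs = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    A = upper.astype(float)
    return A + A.T


def generate(spec: SyntheticSpec) -> SyntheticNetwork:
    """Draw one seeded planted-partition heterogeneous network.

    Fully reproducible: the same spec (including seed) yields the same
    network and truth.
    """
    rng = np.random.default_rng(spec.seed)
    d_modules = np.repeat(np.arange(spec.n_modules), spec.diseases_per_module)
    g_modules = np.repeat(np.arange(spec.n_modules), spec.genes_per_module)

    disease_index = NodeIndex([f"D{i}" for i in range(spec.n_diseases)])
    gene_index = NodeIndex([f"G{j}" for j in range(spec.n_genes)])

    A_D = _planted_layer(rng, d_modules, spec.p_in, spec.p_out)
    A_G = _planted_layer(rng, g_modules, spec.p_in, spec.p_out)

    matched = d_modules[:, None] == g_modules[None, :]
    assoc_probs = np.where(matched, spec.assoc_in, spec.assoc_out)
    R_full = (rng.random(assoc_probs.shape) < assoc_probs).astype(float)

    # withhold a fraction of the matched-module (signal) associations as truth
    signal_i, signal_j = np.nonzero(R_full * matched)
    n_holdout = int(round(spec.holdout_fraction * signal_i.size))
    if n_holdout == 0:
        raise ValidationError(
            "spec yields an empty truth set; increase sizes, assoc_in or holdout_fraction"
        )
    chosen = rng.choice(signal_i.size, size=n_holdout, replace=False)
    truth_m = np.zeros_like(R_full)
    truth_m[signal_i[chosen], signal_j[chosen]] = 1.0
    train_m = R_full - truth_m

    network = assemble_heterogeneous(
        LayerGraph(A_D, disease_index),
        LayerGraph(A_G, gene_index),
        AssociationTable(train_m, disease_index, gene_index),
    )
    truth = AssociationTable(truth_m, disease_index, gene_index)
    module_labels = {
        **{f"D{i}": int(m) for i, m in enumerate(d_modules)},
        **{f"G{j}": int(m) for j, m in enumerate(g_modules)},
    }
    return SyntheticNetwork(network=network, truth=truth, module_labels=module_labels)


def default_fixture() -> SyntheticNetwork:
    """The fixed small instance used throughout the test suite.

    4 matched modules of 5 diseases + 30 genes each (140 nodes total),
    dense enough within modules for the planted signal to be
    recoverable, seeded so every run sees the same network.
    """
    return generate(SyntheticSpec())
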