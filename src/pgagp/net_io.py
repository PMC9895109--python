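"""Edge-list I/O and assembly of the disease-gene heterogeneous network.

The heterogeneous network has two within-layer graphs — a disease-disease
similarity network (possibly weighted) and a gene-gene interaction (PPI)
network (0/1) — joined by a binary bipartite disease-gene association
matrix.  Nodes are addressed by string labels externally and by contiguous
0-based integer indices internally; :class:`NodeIndex` is the only place
the two meet.  In every combined representation diseases come first, then
genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "NodeIndex",
    "LayerGraph",
    "AssociationTable",
    "HeterogeneousNetwork",
    "read_edge_list",
    "write_edge_list",
    "read_associations",
    "write_associations",
    "write_node_index",
    "assemble_heterogeneous",
    "combined_adjacency",
]


class NodeIndex:
    """Immutable bidirectional mapping between node labels and 0-based indices."""

    __slots__ = ("labels", "position")

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(x) for x in labels)
        position = {lab: i for i, lab in enumerate(labels)}
        if len(position) != len(labels):
            seen: set[str] = set()
            dups = sorted({x for x in labels if x in seen or seen.add(x)})
            raise ValidationError(f"duplicate node labels: {dups[:10]}")
        self.labels = labels
        self.position = position

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        return label in self.position

    def __getitem__(self, label: str) -> int:
        return self.position[label]

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, NodeIndex) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"NodeIndex({len(self)} nodes)"


@dataclass
class LayerGraph:
    """One within-layer network: symmetric non-negative adjacency plus its index."""

    adjacency: np.ndarray
    index: NodeIndex

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError(f"adjacency must be square, got shape {A.shape}")
        if A.shape[0] != len(self.index):
            raise ValidationError(
                f"adjacency size {A.shape[0]} != index size {len(self.index)}"
            )
        if not np.allclose(A, A.T):
            raise ValidationError("adjacency must be symmetric")
        if (A < 0).any():
            raise ValidationError("adjacency must be non-negative")
        if np.diagonal(A).any():
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        self.adjacency = A

    @property
    def n_nodes(self) -> int:
        return len(self.index)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges (nonzero entries above the diagonal)."""
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))


@dataclass
class AssociationTable:
    """Binary disease-gene association matrix R (n_D x n_G) with both indices."""

    matrix: np.ndarray
    disease_index: NodeIndex
    gene_index: NodeIndex

    def __post_init__(self) -> None:
        R = np.asarray(self.matrix, dtype=float)
        if R.shape != (len(self.disease_index), len(self.gene_index)):
            raise ValidationError(
                f"association matrix shape {R.shape} does not match indices "
                f"({len(self.disease_index)}, {len(self.gene_index)})"
            )
        if not np.isin(R, (0.0, 1.0)).all():
            raise ValidationError("association matrix must be binary")
        self.matrix = R

    @property
    def n_associations(self) -> int:
        return int(self.matrix.sum())

    def pairs(self) -> list[tuple[str, str]]:
        """Known associations as (disease label, gene label) pairs."""
        di, gi = np.nonzero(self.matrix)
        return [
            (self.disease_index.labels[i], self.gene_index.labels[j])
            for i, j in zip(di, gi)
        ]


@dataclass
class HeterogeneousNetwork:
    """The two layers A_D, A_G and the bipartite associations R tying them."""

    disease_layer: LayerGraph
    gene_layer: LayerGraph
    associations: AssociationTable

    def __post_init__(self) -> None:
        if self.disease_layer.index != self.associations.disease_index:
            raise ValidationError("disease layer and association disease index differ")
        if self.gene_layer.index != self.associations.gene_index:
            raise ValidationError("gene layer and association gene index differ")

    @property
    def n_diseases(self) -> int:
        return self.disease_layer.n_nodes

    @property
    def n_genes(self) -> int:
        return self.gene_layer.n_nodes

    @property
    def n_nodes(self) -> int:
        return self.n_diseases + self.n_genes

    @property
    def combined_labels(self) -> tuple[str, ...]:
        return self.disease_layer.index.labels + self.gene_layer.index.labels

    def with_associations(self, matrix: np.ndarray) -> "HeterogeneousNetwork":
        """Same layers, different association matrix (used by cross-validation)."""
        table = AssociationTable(
            matrix=matrix,
            disease_index=self.associations.disease_index,
            gene_index=self.associations.gene_index,
        )
        return HeterogeneousNetwork(self.disease_layer, self.gene_layer, table)


def _parse_lines(path: str | Path, header: bool) -> Iterator[tuple[int, list[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split()


def read_edge_list(
    path: str | Path, weighted: bool = False, header: bool = False
) -> LayerGraph:
    """Read a 2- or 3-column TSV edge list into a :class:`LayerGraph`.

    Duplicate edges collapse keeping the maximum weight; self-loops are
    dropped with a warning (the node itself is kept); node order is
    first-appearance order in the file.
    """
    labels: list[str] = []
    position: dict[str, int] = {}
    edges: dict[tuple[int, int], float] = {}
    n_self_loops = 0

    def _idx(label: str) -> int:
        if label not in position:
            position[label] = len(labels)
            labels.append(label)
        return position[label]

    for lineno, parts in _parse_lines(path, header):
        if len(parts) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
            )
        a, b = parts[0], parts[1]
        if weighted and len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
            if not np.isfinite(w):
                raise ParseError(f"{path}:{lineno}: non-finite weight {parts[2]!r}")
            if w < 0:
                raise ValidationError(f"{path}:{lineno}: negative weight {w}")
        else:
            w = 1.0
        i, j = _idx(a), _idx(b)
        if i == j:
            n_self_loops += 1
            continue
        key = (min(i, j), max(i, j))
        edges[key] = max(edges.get(key, 0.0), w)

    if n_self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_self_loops)

    index = NodeIndex(labels)
    A = np.zeros((len(index), len(index)))
    for (i, j), w in edges.items():
        A[i, j] = A[j, i] = w
    return LayerGraph(adjacency=A, index=index)


def write_edge_list(layer: LayerGraph, path: str | Path) -> None:
    """Write the upper-triangle nonzero entries as a TSV edge list."""
    A = layer.adjacency
    labels = layer.index.labels
    unweighted = np.isin(A, (0.0, 1.0)).all()
    with open(path, "w", encoding="utf-8") as fh:
        ii, jj = np.nonzero(np.triu(A, k=1))
        for i, j in zip(ii, jj):
            if unweighted:
                fh.write(f"{labels[i]}\t{labels[j]}\n")
            else:
                fh.write(f"{labels[i]}\t{labels[j]}\t{A[i, j]:.10g}\n")


def read_associations(
    path: str | Path,
    disease_index: NodeIndex,
    gene_index: NodeIndex,
    policy: str = "drop-unknown",
    header: bool = False,
) -> AssociationTable:
    """Read disease-gene pairs, mapping them onto the given indices.

    ``policy="drop-unknown"`` silently drops (and counts) pairs whose
    disease or gene is absent from the indices, mirroring the filtering
    of association data against the interactome; ``policy="keep"``
    raises instead.
    """
    if policy not in ("drop-unknown", "keep"):
        raise ValidationError(f"unknown policy {policy!r}")
    R = np.zeros((len(disease_index), len(gene_index)))
    n_dropped = 0
    for lineno, parts in _parse_lines(path, header):
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        d, g = parts[0], parts[1]
        if d not in disease_index or g not in gene_index:
            if policy == "keep":
                raise ValidationError(
                    f"{path}:{lineno}: unknown node in pair ({d!r}, {g!r})"
                )
            n_dropped += 1
            continue
        R[disease_index[d], gene_index[g]] = 1.0
    if n_dropped:
        logger.info("%s: dropped %d pair(s) with unknown nodes", path, n_dropped)
    if not R.any():
        raise ValidationError(f"{path}: no associations left after filtering")
    return AssociationTable(R, disease_index, gene_index)


def write_associations(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d, g in table.pairs():
            fh.write(f"{d}\t{g}\n")


def write_node_index(index: NodeIndex, path: str | Path) -> None:
    """Export a label -> integer-index map as two-column TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, lab in enumerate(index.labels):
            fh.write(f"{lab}\t{i}\n")


def assemble_heterogeneous(
    disease_layer: LayerGraph,
    gene_layer: LayerGraph,
    associations: AssociationTable,
) -> HeterogeneousNetwork:
    """Validate index compatibility and assemble the heterogeneous network."""
    problems: list[str] = []
    if disease_layer.index != associations.disease_index:
        extra = set(associations.disease_index.labels) - set(disease_layer.index.labels)
        problems.append(f"disease index mismatch (e.g. {sorted(extra)[:5]})")
    if gene_layer.index != associations.gene_index:
        extra = set(associations.gene_index.labels) - set(gene_layer.index.labels)
        problems.append(f"gene index mismatch (e.g. {sorted(extra)[:5]})")
    if problems:
        raise ValidationError("; ".join(problems))
    h = HeterogeneousNetwork(disease_layer, gene_layer, associations)
    if h.associations.n_associations == 0:
        logger.warning("heterogeneous network has an empty association matrix")
    logger.info(
        "assembled network: %d diseases (%d edges), %d genes (%d edges), %d associations",
        h.n_diseases,
        disease_layer.n_edges,
        h.n_genes,
        gene_layer.n_edges,
        h.associations.n_associations,
    )
    return h


def combined_adjacency(h: HeterogeneousNetwork) -> np.ndarray:
    """The (n_D+n_G) square block matrix [[A_D, R], [R^T, A_G]].

    Disease indices occupy rows/columns 0..n_D-1, gene indices follow.
    """
    R = h.associations.matrix
    return np.block(
        [
            [h.disease_layer.adjacency, R],
            [R.T, h.gene_layer.adjacency],
        ]
    )
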