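"""Weighted protein–protein interaction networks and the transition operator.

A :class:`WeightedNetwork` is an undirected graph over gene identifiers
(Ensembl peptide IDs in real data, synthetic labels in tests) whose edges
carry integer confidence scores in [1, 999], the STRING convention.  Node
order is fixed lexicographically so that every vector or matrix aligned to
the network is byte-reproducible across runs.

The random walk uses a column-stochastic transition operator: entry (i, j)
is the edge confidence Q(i, j) divided by the weighted degree of j, so a
probability vector keeps unit mass under repeated application.  Nodes left
isolated (possible after confidence filtering) get a self-transition of 1;
they can only hold mass if seeded.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

MIN_CONFIDENCE = 1
MAX_CONFIDENCE = 999

STRING_HEADER = "protein1 protein2 combined_score"


def validate_gene_id(gene: str) -> str:
    """Check that a gene identifier is a non-empty string without whitespace."""
    if not isinstance(gene, str) or not gene:
        raise ValidationError(f"gene identifier must be a non-empty string, got {gene!r}")
    if any(c.isspace() for c in gene):
        raise ValidationError(f"gene identifier contains whitespace: {gene!r}")
    return gene


class WeightedNetwork:
    """Undirected weighted graph over gene identifiers.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, confidence)`` triples.  Duplicate pairs (in
        either orientation) are collapsed to one undirected edge; on
        conflicting confidences the maximum is kept and the conflict logged.
        Self-loops are rejected.
    extra_nodes
        Optional additional (isolated) node identifiers.
    """

    __slots__ = ("nodes", "_index", "_adj")

    def __init__(self, edges: Iterable[tuple[str, str, int]], extra_nodes: Iterable[str] = ()):
        adj: dict[str, dict[str, int]] = {}
        for u, v, c in edges:
            validate_gene_id(u)
            validate_gene_id(v)
            if u == v:
                raise ValidationError(f"self-loop on {u!r} is not allowed")
            c = int(c)
            if not (MIN_CONFIDENCE <= c <= MAX_CONFIDENCE):
                raise ValidationError(
                    f"confidence {c} for edge {u}-{v} outside [{MIN_CONFIDENCE}, {MAX_CONFIDENCE}]"
                )
            prev = adj.get(u, {}).get(v)
            if prev is not None and prev != c:
                log.warning("conflicting confidences for %s-%s (%d vs %d); keeping max", u, v, prev, c)
                c = max(prev, c)
            adj.setdefault(u, {})[v] = c
            adj.setdefault(v, {})[u] = c
        for g in extra_nodes:
            validate_gene_id(g)
            adj.setdefault(g, {})
        if not adj:
            raise ValidationError("network is empty")
        self.nodes: tuple[str, ...] = tuple(sorted(adj))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        self._adj = adj

    # -- basic queries -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def node_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise ValidationError(f"gene {gene!r} not in network") from None

    def neighbors(self, gene: str) -> tuple[str, ...]:
        self.node_index(gene)
        return tuple(sorted(self._adj[gene]))

    def confidence(self, u: str, v: str) -> int:
        """Edge confidence Q(u, v); 0 when the pair is not adjacent."""
        self.node_index(u)
        self.node_index(v)
        return self._adj[u].get(v, 0)

    def edges(self) -> Iterator[tuple[str, str, int]]:
        """Each undirected edge once, as (u, v, confidence) with u < v, sorted."""
        for u in self.nodes:
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def degree(self, gene: str) -> int:
        self.node_index(gene)
        return len(self._adj[gene])

    # -- linear-algebra views ------------------------------------------

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric confidence-weighted adjacency matrix in node order."""
        rows, cols, vals = [], [], []
        for u, v, c in self.edges():
            i, j = self._index[u], self._index[v]
            rows += [i, j]
            cols += [j, i]
            vals += [c, c]
        return sparse.csr_matrix(
            (np.asarray(vals, dtype=float), (rows, cols)),
            shape=(self.n_nodes, self.n_nodes),
        )

    def weighted_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=0)).ravel()


@dataclass(frozen=True)
class SeedSet:
    """Non-empty set of disease seed genes resolvable against a network."""

    genes: frozenset[str]
    unmapped: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.genes:
            raise ValidationError("seed set is empty")
        for g in self.genes:
            validate_gene_id(g)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass(frozen=True)
class TransitionOperator:
    """Column-stochastic walk operator aligned to a network's node order."""

    matrix: sparse.csr_matrix = field(repr=False)
    nodes: tuple[str, ...]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def apply(self, vector: np.ndarray) -> np.ndarray:
        return self.matrix @ vector


def build_transition_operator(network: WeightedNetwork) -> TransitionOperator:
    """Column-normalize the confidence-weighted adjacency matrix.

    Entry (i, j) = Q(i, j) / weighted-degree(j).  Isolated nodes receive a
    unit self-transition so every column sums to one.
    """
    adjacency = network.adjacency().tocsc()
    wdeg = np.asarray(adjacency.sum(axis=0)).ravel()
    isolated = wdeg == 0
    inv = np.zeros_like(wdeg)
    inv[~isolated] = 1.0 / wdeg[~isolated]
    matrix = (adjacency @ sparse.diags(inv)).tocsr()
    if isolated.any():
        log.info("%d isolated node(s); assigning self-transition columns", int(isolated.sum()))
        matrix = (matrix + sparse.diags(isolated.astype(float))).tocsr()
    return TransitionOperator(matrix=matrix, nodes=network.nodes)


# -- file formats -------------------------------------------------------


def _open_text(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def load_string_links(path: str | Path, min_confidence: int = 1) -> WeightedNetwork:
    """Load a STRING-links-style edge list (plain text or gzip).

    Lines hold ``protein1 protein2 combined_score`` separated by whitespace,
    with one optional header line.  Directed duplicates collapse to one
    undirected edge (max confidence on conflict); self-loops are dropped
    with a warning; edges below ``min_confidence`` are dropped, and the
    node set is the endpoints of the surviving edges.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"edge file not found: {path}")
    edges: dict[tuple[str, str], int] = {}
    n_self = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
            u, v, score_text = fields
            try:
                score = int(score_text)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(f"{path}:{lineno}: confidence {score_text!r} is not an integer") from None
            if not (MIN_CONFIDENCE <= score <= MAX_CONFIDENCE):
                raise ValidationError(
                    f"{path}:{lineno}: confidence {score} outside [{MIN_CONFIDENCE}, {MAX_CONFIDENCE}]"
                )
            if u == v:
                n_self += 1
                continue
            if score < min_confidence:
                continue
            key = (u, v) if u < v else (v, u)
            prev = edges.get(key)
            if prev is None:
                edges[key] = score
            elif prev != score:
                log.warning("%s:%d: conflicting confidence for %s-%s (%d vs %d); keeping max",
                            path, lineno, key[0], key[1], prev, score)
                edges[key] = max(prev, score)
    if n_self:
        log.warning("%s: dropped %d self-loop line(s)", path, n_self)
    if not edges:
        raise ValidationError(f"{path}: no edges remain after filtering at min_confidence={min_confidence}")
    return WeightedNetwork((u, v, c) for (u, v), c in edges.items())


def write_string_links(network: WeightedNetwork, path: str | Path, header: bool = True) -> None:
    """Write the network in the STRING-links dialect (gzip if path ends .gz)."""
    path = Path(path)
    with _open_text(path, "wt") as fh:
        if header:
            fh.write(STRING_HEADER + "\n")
        for u, v, c in network.edges():
            fh.write(f"{u} {v} {c}\n")


def load_gene_list(path: str | Path, network: WeightedNetwork) -> SeedSet:
    """Load a one-ID-per-line gene list and intersect it with the network.

    Blank lines and ``#`` comments are skipped; identifiers absent from the
    network are recorded on the returned :class:`SeedSet` and logged.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"gene list not found: {path}")
    seen: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seen.append(validate_gene_id(line))
    mapped = frozenset(g for g in seen if g in network)
    unmapped = tuple(sorted({g for g in seen if g not in network}))
    if unmapped:
        log.warning("%s: %d gene(s) not in network: %s", path, len(unmapped),
                    ", ".join(unmapped[:10]) + ("…" if len(unmapped) > 10 else ""))
    if not mapped:
        raise ValidationError(f"{path}: no seed genes found in network")
    return SeedSet(genes=mapped, unmapped=unmapped)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")
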