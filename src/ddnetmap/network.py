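"""Weighted undirected gene interaction networks.

The container mirrors functional gene networks such as HumanNet-XC: an
edge list of ``(gene_a, gene_b, weight)`` with positive weights, no
self-loops and no duplicate undirected edges.  The normalized transition
matrix ``W`` used by random-walk-with-restart propagation is column
stochastic: each column of the weighted adjacency matrix is divided by
its column sum, so a walker at gene *j* moves to neighbour *i* with
probability proportional to the edge weight.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .errors import FormatError, ParameterError

__all__ = ["GeneNetwork", "normalize_adjacency", "read_edge_list"]


@dataclass
class LoadReport:
    """Bookkeeping for every record dropped while building a network."""

    n_genes: int = 0
    n_edges: int = 0
    self_loops_dropped: int = 0
    duplicate_edges_merged: int = 0
    isolated_genes_dropped: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class GeneNetwork:
    """Weighted undirected network over uniquely named genes.

    Parameters
    ----------
    edges
        Iterable of ``(gene_a, gene_b, weight)``.  Self-loops are dropped,
        duplicate undirected edges are merged keeping the maximum weight,
        and both events are counted in :attr:`report`.  Gene identifiers
        are opaque case-sensitive strings.
    """

    def __init__(self, edges):
        report = LoadReport()
        merged: dict[tuple[str, str], float] = {}
        for a, b, w in edges:
            a, b = str(a), str(b)
            w = float(w)
            if w <= 0:
                raise FormatError(f"non-positive edge weight {w} on {a}--{b}")
            if a == b:
                report.self_loops_dropped += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in merged:
                report.duplicate_edges_merged += 1
                merged[key] = max(merged[key], w)  # keep-max-weight policy
            else:
                merged[key] = w
        if not merged:
            raise ParameterError("network has no usable edges")
        self.edges: list[tuple[str, str, float]] = [
            (a, b, w) for (a, b), w in sorted(merged.items())
        ]
        self.genes: list[str] = sorted({g for a, b, _ in self.edges for g in (a, b)})
        self._index = {g: i for i, g in enumerate(self.genes)}
        report.n_genes = len(self.genes)
        report.n_edges = len(self.edges)
        self.report = report
        self._W: sp.csc_matrix | None = None
        self._graph: nx.Graph | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise ParameterError(f"gene {gene!r} not in network") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.genes)
            g.add_weighted_edges_from(self.edges)
            self._graph = g
        return self._graph

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix in gene order."""
        n = self.n_genes
        rows, cols, vals = [], [], []
        for a, b, w in self.edges:
            i, j = self._index[a], self._index[b]
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    @property
    def W(self) -> sp.csc_matrix:
        """Column-stochastic transition matrix (lazily built and cached)."""
        if self._W is None:
            self._W = normalize_adjacency(self.adjacency())
        return self._W

    def degrees(self, weighted: bool = False) -> np.ndarray:
        """Per-gene degree in gene order."""
        adj = self.adjacency()
        if weighted:
            return np.asarray(adj.sum(axis=0)).ravel()
        return np.asarray((adj != 0).sum(axis=0)).ravel()

    def subnetwork(self, genes) -> "GeneNetwork":
        """Induced subgraph on ``genes``; genes absent from the network or
        left isolated by the restriction are dropped (counted in the
        report of the returned network)."""
        keep = set(genes)
        sub_edges = [(a, b, w) for a, b, w in self.edges if a in keep and b in keep]
        if not sub_edges:
            raise ParameterError("induced subnetwork has no edges")
        sub = GeneNetwork(sub_edges)
        sub.report.isolated_genes_dropped = len(keep & set(self.genes)) - sub.n_genes
        return sub

    # -- I/O -------------------------------------------------------------
    def write_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("geneA\tgeneB\tweight\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w:.10g}\n")

    def __repr__(self) -> str:
        return f"GeneNetwork(n_genes={self.n_genes}, n_edges={self.n_edges})"


def normalize_adjacency(adjacency: sp.spmatrix) -> sp.csc_matrix:
    """Divide each column of a weighted adjacency matrix by its column sum.

    The result is column stochastic, which makes random-walk-with-restart
    propagation conserve total heat exactly.  Columns with zero sum
    (isolated nodes) are rejected: isolated genes must be excluded before
    normalization.
    """
    adjacency = sp.csc_matrix(adjacency)
    colsums = np.asarray(adjacency.sum(axis=0)).ravel()
    if np.any(colsums <= 0):
        raise ParameterError("adjacency has empty columns; drop isolated genes first")
    inv = sp.diags(1.0 / colsums)
    return sp.csc_matrix(adjacency @ inv)


def read_edge_list(path, weight_column=2) -> GeneNetwork:
    """Read a tab-separated edge list (HumanNet-XC-style dialect).

    Lines starting with ``#`` are comments.  A header line is detected when
    the third field is not numeric.  Extra columns are ignored; the weight
    column may be selected by 0-based index or by header name.
    """
    path = Path(path)
    text = path.read_text()
    return _parse_edge_list(text, weight_column, str(path))


def _parse_edge_list(text: str, weight_column, source: str) -> GeneNetwork:
    edges = []
    header: list[str] | None = None
    wcol = weight_column
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{source}:{lineno}: expected at least 2 fields")
        if header is None:
            # header detection: non-numeric weight field on the first row
            pcol = wcol if isinstance(wcol, int) and wcol < len(fields) else 2
            probe = fields[pcol] if len(fields) > 2 else None
            if probe is not None and not _is_number(probe):
                header = fields
                if isinstance(wcol, str):
                    if wcol not in header:
                        raise FormatError(f"{source}: weight column {wcol!r} not in header")
                    wcol = header.index(wcol)
                continue
            header = []
            if isinstance(wcol, str):
                raise FormatError(f"{source}: named weight column needs a header line")
        a, b = fields[0], fields[1]
        if len(fields) > 2:
            if wcol >= len(fields):
                raise FormatError(f"{source}:{lineno}: missing weight column {wcol}")
            wtext = fields[wcol]
            if not _is_number(wtext):
                raise FormatError(f"{source}:{lineno}: bad weight {wtext!r}")
            w = float(wtext)
            if w < 0:
                raise FormatError(f"{source}:{lineno}: negative weight {w}")
            if w == 0:
                raise FormatError(f"{source}:{lineno}: zero weight")
        else:
            w = 1.0
        edges.append((a, b, w))
    if not edges:
        raise FormatError(f"{source}: empty network file")
    return GeneNetwork(edges)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False
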