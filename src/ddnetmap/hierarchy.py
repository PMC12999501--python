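"""Multiscale persistent community hierarchy.

Communities are detected on the seed-proximal subnetwork with a
resolution-parameterized modularity partitioner across a sweep of
resolutions (small resolution -> large communities).  Blocks that
reappear across consecutive resolutions (matched by Jaccard similarity
above a threshold) form persistent communities; persistence is the
length of the matched chain.  Persistent communities are organized into
a DAG: an edge from parent w to child v is added when the containment
index CI(v, w) = |v ∩ w| / |v| exceeds a threshold and v is strictly
smaller than w, then redundant (transitively implied) edges are removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ParameterError
from .network import GeneNetwork

__all__ = [
    "Community",
    "HierarchyConfig",
    "CommunityHierarchy",
    "partition_at_resolution",
    "sweep_resolutions",
    "jaccard",
    "containment_index",
    "persistent_communities",
    "build_hierarchy",
]


@dataclass
class Community:
    community_id: str
    genes: frozenset
    resolution_first: float
    resolution_last: float
    persistence: int
    annotation: str | None = None

    def __post_init__(self):
        if not self.genes:
            raise ParameterError(f"community {self.community_id} is empty")
        if self.resolution_first > self.resolution_last:
            raise ParameterError("resolution_first must be <= resolution_last")


@dataclass
class HierarchyConfig:
    """Sweep and hierarchy-assembly settings.

    The default grid sweeps resolutions 0.5 .. 5.0 in 10 steps (maximum
    resolution 5); jaccard_threshold matches blocks across consecutive
    resolutions; persistence_min is the minimal chain length a community
    must persist for; ci_threshold gates parent-child containment edges.
    """

    resolution_grid: tuple = tuple(np.round(np.linspace(0.5, 5.0, 10), 10))
    jaccard_threshold: float = 0.75
    persistence_min: int = 5
    ci_threshold: float = 0.75
    min_size: int = 2
    partition_seed: int = 0

    def __post_init__(self):
        grid = tuple(float(r) for r in self.resolution_grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ParameterError("resolution_grid must be nonempty and increasing")
        object.__setattr__(self, "resolution_grid", grid)
        if not 0 < self.jaccard_threshold <= 1:
            raise ParameterError("jaccard_threshold must be in (0,1]")
        if not 0 < self.ci_threshold <= 1:
            raise ParameterError("ci_threshold must be in (0,1]")
        if self.persistence_min < 1:
            raise ParameterError("persistence_min must be >= 1")
        if self.min_size < 1:
            raise ParameterError("min_size must be >= 1")


def partition_at_resolution(network: GeneNetwork, resolution: float,
                            partition_seed: int = 0) -> list[frozenset]:
    """Seeded resolution-parameterized modularity partition (Leiden).

    Uses the Reichardt-Bornholdt configuration-null quality function with
    a linear resolution parameter; iterated until stable, so the result
    is deterministic for a fixed seed.  Communities are connected, hence
    disconnected components never share a block.
    """
    import igraph as ig
    import leidenalg as la

    if network.n_genes == 0:
        raise ParameterError("empty subnetwork")
    idx = {g: i for i, g in enumerate(network.genes)}
    g = ig.Graph(
        n=network.n_genes,
        edges=[(idx[a], idx[b]) for a, b, _ in network.edges],
    )
    weights = [w for _, _, w in network.edges]
    part = la.find_partition(
        g, la.RBConfigurationVertexPartition, weights=weights,
        resolution_parameter=float(resolution), seed=int(partition_seed),
        n_iterations=-1)
    blocks = [frozenset(network.genes[i] for i in block) for block in part]
    return sorted(blocks, key=lambda b: (-len(b), sorted(b)))


def sweep_resolutions(network: GeneNetwork, config: HierarchyConfig):
    """One partition per grid resolution, ascending."""
    return [(r, partition_at_resolution(network, r, config.partition_seed))
            for r in config.resolution_grid]


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ParameterError("Jaccard undefined for two empty sets")
    return len(a & b) / len(union)


def containment_index(v, w) -> float:
    """Fraction of community v contained in community w: |v ∩ w| / |v|."""
    v, w = set(v), set(w)
    if not v:
        raise ParameterError("containment index undefined for empty v")
    return len(v & w) / len(v)


def _match_consecutive(blocks_lo, blocks_hi, tau: float) -> dict[int, int]:
    """Greedy one-to-one Jaccard matching between two partitions.

    Pairs with Jaccard >= tau are taken best-first; ties broken by larger
    overlap, then by lexicographic block identity for determinism.
    """
    cands = []
    for i, bl in enumerate(blocks_lo):
        for j, bh in enumerate(blocks_hi):
            inter = len(bl & bh)
            if inter == 0:
                continue
            jac = inter / len(bl | bh)
            if jac >= tau:
                cands.append((-jac, -inter, sorted(bl), sorted(bh), i, j))
    cands.sort()
    used_lo, used_hi, match = set(), set(), {}
    for _, _, _, _, i, j in cands:
        if i in used_lo or j in used_hi:
            continue
        match[i] = j
        used_lo.add(i)
        used_hi.add(j)
    return match


def persistent_communities(sweep, tau: float = 0.75,
                           persistence_min: int = 5,
                           min_size: int = 2) -> list[Community]:
    """Chain blocks across consecutive resolutions and keep long chains.

    A chain is a maximal run of blocks matched one-to-one (Jaccard >= tau)
    at consecutive resolutions; each block belongs to at most one chain.
    Chains of length >= persistence_min become communities whose gene set
    is the block at the chain's first resolution.  Blocks smaller than
    ``min_size`` (default 2: singletons are not communities of a systems
    map) are not chained.
    """
    if not sweep:
        raise ParameterError("empty resolution sweep")
    resolutions = [r for r, _ in sweep]
    partitions = [[b for b in p if len(b) >= min_size] for _, p in sweep]
    matches = [
        _match_consecutive(partitions[i], partitions[i + 1], tau)
        for i in range(len(partitions) - 1)
    ]
    # a block (level, index) is a chain start if nothing matched into it
    matched_into = [set() for _ in partitions]
    for lvl, m in enumerate(matches):
        for j in m.values():
            matched_into[lvl + 1].add(j)
    communities = []
    for lvl, blocks in enumerate(partitions):
        for i, block in enumerate(blocks):
            if i in matched_into[lvl]:
                continue
            # walk the chain forward
            length = 1
            cur_lvl, cur_i = lvl, i
            while cur_lvl < len(matches) and cur_i in matches[cur_lvl]:
                cur_i = matches[cur_lvl][cur_i]
                cur_lvl += 1
                length += 1
            if length >= persistence_min:
                communities.append(Community(
                    community_id="",  # assigned below, in deterministic order
                    genes=block,
                    resolution_first=resolutions[lvl],
                    resolution_last=resolutions[lvl + length - 1],
                    persistence=length,
                ))
    communities.sort(key=lambda c: (-len(c.genes), c.resolution_first, sorted(c.genes)))
    for n, c in enumerate(communities):
        c.community_id = f"C{n}"
    return communities


@dataclass
class CommunityHierarchy:
    """DAG of persistent communities with containment-index edges."""

    nodes: list[Community]
    edges: list[tuple[str, str, float]]  # (parent_id, child_id, CI(child, parent))
    root: str

    def community(self, community_id: str) -> Community:
        for c in self.nodes:
            if c.community_id == community_id:
                return c
        raise ParameterError(f"no community {community_id!r}")

    def digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(c.community_id for c in self.nodes)
        g.add_weighted_edges_from(self.edges, weight="ci")
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.digraph())

    def write_tsv(self, nodes_path, edges_path) -> None:
        with open(nodes_path, "w") as fh:
            fh.write("community_id\tsize\tresolution_first\tresolution_last"
                     "\tpersistence\tannotation\tgenes\n")
            for c in self.nodes:
                fh.write(f"{c.community_id}\t{len(c.genes)}\t{c.resolution_first:g}"
                         f"\t{c.resolution_last:g}\t{c.persistence}"
                         f"\t{c.annotation or ''}\t{','.join(sorted(c.genes))}\n")
        with open(edges_path, "w") as fh:
            fh.write("parent\tchild\tci\n")
            for p, ch, ci in self.edges:
                fh.write(f"{p}\t{ch}\t{ci:.10g}\n")

    def to_json(self) -> str:
        return json.dumps({
            "root": self.root,
            "nodes": [
                {"community_id": c.community_id, "genes": sorted(c.genes),
                 "resolution_first": c.resolution_first,
                 "resolution_last": c.resolution_last,
                 "persistence": c.persistence, "annotation": c.annotation}
                for c in self.nodes
            ],
            "edges": [{"parent": p, "child": c, "ci": ci} for p, c, ci in self.edges],
        }, indent=2)


ROOT_ID = "root"


def build_hierarchy(communities, ci_threshold: float = 0.75,
                    all_genes=None) -> CommunityHierarchy:
    """Assemble the containment DAG over persistent communities.

    Candidate edge parent w -> child v whenever CI(v, w) > ci_threshold
    and |v| < |w| (the strict size condition rules out cycles).
    Equal-size communities with mutual containment above threshold are
    merged.  Transitive reduction removes redundant edges, and a
    synthetic all-genes root is added when more than one community would
    otherwise be parentless.
    """
    if not communities:
        raise ParameterError("no communities to organize")
    nodes = [Community(c.community_id, c.genes, c.resolution_first,
                       c.resolution_last, c.persistence, c.annotation)
             for c in communities]
    # merge equal-size mutually contained communities (identical or
    # near-identical sets); keep the earlier-resolution identity
    merged = True
    while merged:
        merged = False
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                a, b = nodes[i], nodes[j]
                if len(a.genes) == len(b.genes) \
                        and containment_index(a.genes, b.genes) > ci_threshold \
                        and containment_index(b.genes, a.genes) > ci_threshold:
                    keep, drop = (a, b) if a.resolution_first <= b.resolution_first else (b, a)
                    keep.genes = frozenset(keep.genes | drop.genes)
                    keep.resolution_first = min(a.resolution_first, b.resolution_first)
                    keep.resolution_last = max(a.resolution_last, b.resolution_last)
                    keep.persistence = max(a.persistence, b.persistence)
                    nodes.remove(drop)
                    merged = True
                    break
            if merged:
                break
    genes_of = {c.community_id: c.genes for c in nodes}
    g = nx.DiGraph()
    g.add_nodes_from(genes_of)
    for v in nodes:
        for w in nodes:
            if v is w or len(v.genes) >= len(w.genes):
                continue
            ci = containment_index(v.genes, w.genes)
            if ci > ci_threshold:
                g.add_edge(w.community_id, v.community_id)
    reduced = nx.transitive_reduction(g)
    roots = [n for n in reduced.nodes if reduced.in_degree(n) == 0]
    root_id = roots[0] if len(roots) == 1 else ROOT_ID
    if len(roots) > 1:
        universe = frozenset(all_genes) if all_genes is not None else \
            frozenset().union(*(c.genes for c in nodes))
        res = [c.resolution_first for c in nodes]
        nodes.insert(0, Community(ROOT_ID, universe, min(res), max(res), 1,
                                  annotation="synthetic root"))
        genes_of[ROOT_ID] = universe
        for r in roots:
            reduced.add_edge(ROOT_ID, r)
    edges = sorted(
        (p, c, containment_index(genes_of[c], genes_of[p]))
        for p, c in reduced.edges
    )
    return CommunityHierarchy(nodes=nodes, edges=edges, root=root_id)
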