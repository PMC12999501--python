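import itertools

import networkx as nx
import numpy as np
import pytest

from ddnetmap import (
    Community,
    GeneNetwork,
    HierarchyConfig,
    ParameterError,
    build_hierarchy,
    containment_index,
    gen_network,
    jaccard,
    partition_at_resolution,
    persistent_communities,
    sweep_resolutions,
)
from ddnetmap.synthetic import PlantedNetworkSpec


# ----------------------------------------------------------------------
# exhaustive oracle: enumerate every partition of a tiny graph and pick
# the one(s) maximizing the same resolution-parameterized quality
# ----------------------------------------------------------------------

def set_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in set_partitions(rest):
        for i in range(len(sub)):
            yield sub[:i] + [[first] + sub[i]] + sub[i + 1:]
        yield [[first]] + sub


def rb_quality(net: GeneNetwork, blocks, resolution: float) -> float:
    """Reichardt-Bornholdt configuration-null modularity (unnormalized),
    computed from first principles on the weighted adjacency."""
    A = net.adjacency().toarray()
    k = A.sum(axis=0)
    two_m = A.sum()
    q = 0.0
    for block in blocks:
        idx = [net.index(g) for g in block]
        for i in idx:
            for j in idx:
                q += A[i, j] - resolution * k[i] * k[j] / two_m
    return q


def exhaustive_best_partitions(net: GeneNetwork, resolution: float):
    best_q, best = -np.inf, []
    for parts in set_partitions(net.genes):
        q = rb_quality(net, parts, resolution)
        if q > best_q + 1e-9:
            best_q, best = q, [frozenset(map(frozenset, parts))]
        elif abs(q - best_q) <= 1e-9:
            best.append(frozenset(map(frozenset, parts)))
    return best_q, best


class TestPartitioner:
    def test_two_triangles_match_exhaustive_maximum(self, two_triangles):
        for res in (0.5, 1.0, 2.0, 4.0, 5.0):
            found = frozenset(partition_at_resolution(two_triangles, res, 0))
            best_q, best = exhaustive_best_partitions(two_triangles, res)
            assert rb_quality(two_triangles, found, res) == pytest.approx(best_q, abs=1e-9)
            assert found in best

    def test_two_triangles_low_resolution_recovers_triangles(self, two_triangles):
        blocks = partition_at_resolution(two_triangles, 1.0, 0)
        assert set(blocks) == {frozenset("abc"), frozenset("xyz")}

    def test_clique_is_one_block_at_low_resolution(self):
        genes = list("abcdef")
        edges = [(a, b, 1.0) for a, b in itertools.combinations(genes, 2)]
        net = GeneNetwork(edges)
        blocks = partition_at_resolution(net, 0.5, 0)
        assert blocks == [frozenset(genes)]
        best_q, best = exhaustive_best_partitions(net, 0.5)
        assert frozenset(blocks) in best

    def test_deterministic_under_seed(self, planted_sbm):
        sub = planted_sbm.network
        a = partition_at_resolution(sub, 1.0, 123)
        b = partition_at_resolution(sub, 1.0, 123)
        assert a == b

    def test_disconnected_components_never_share_block(self, two_triangles):
        for res in (0.5, 1.0, 3.0, 5.0):
            for block in partition_at_resolution(two_triangles, res, 0):
                assert block <= frozenset("abc") or block <= frozenset("xyz")

    def test_empty_subnetwork_rejected(self):
        with pytest.raises(ParameterError):
            GeneNetwork([])


class TestSweep:
    def test_one_partition_per_grid_point(self, two_triangles):
        cfg = HierarchyConfig()
        sweep = sweep_resolutions(two_triangles, cfg)
        assert len(sweep) == 10
        assert [r for r, _ in sweep] == list(cfg.resolution_grid)


class TestSetSimilarity:
    def test_jaccard_examples(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard(set("abc"), set("bcd")) == 0.5
        with pytest.raises(ParameterError):
            jaccard(set(), set())

    def test_containment_examples(self):
        assert containment_index({"a", "b"}, {"a", "b", "c"}) == 1.0
        assert containment_index({"a"}, {"b"}) == 0.0
        assert containment_index(set("abcd"), set("ab")) == 0.5
        assert containment_index(set("ab"), set("ab")) == 1.0
        with pytest.raises(ParameterError):
            containment_index(set(), {"a"})

    def test_bounds(self):
        rng = np.random.default_rng(0)
        universe = list(range(30))
        for _ in range(50):
            a = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            b = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            assert 0 <= containment_index(a, b) <= 1
            assert 0 <= jaccard(a, b) <= 1


class TestPersistence:
    def _sweep_from(self, partitions, start=0.5, step=0.5):
        return [(start + i * step, p) for i, p in enumerate(partitions)]

    def test_block_present_everywhere_has_full_persistence(self):
        block = frozenset("abc")
        other = frozenset("xyz")
        sweep = self._sweep_from([[block, other]] * 10)
        comms = persistent_communities(sweep, 0.75, persistence_min=5)
        assert len(comms) == 2
        assert all(c.persistence == 10 for c in comms)

    def test_single_resolution_block_dropped(self):
        stable = frozenset("abcdef")
        sweep = self._sweep_from(
            [[stable]] * 4 + [[frozenset("abc"), frozenset("def")]]
            + [[stable]] * 5)
        comms = persistent_communities(sweep, 0.75, persistence_min=5)
        # the interrupted chain restarts: only the 5-long tail survives,
        # the transient split blocks do not
        genesets = {c.genes for c in comms}
        assert frozenset("abc") not in genesets
        assert frozenset("def") not in genesets

    def test_two_triangles_full_pipeline_yields_two_communities(self, two_triangles):
        cfg = HierarchyConfig()
        sweep = sweep_resolutions(two_triangles, cfg)
        comms = persistent_communities(sweep, cfg.jaccard_threshold,
                                       cfg.persistence_min)
        assert {c.genes for c in comms} == {frozenset("abc"), frozenset("xyz")}

    def test_chain_gene_set_taken_at_first_resolution(self):
        drift = [frozenset("abcde"), frozenset("abcdf")]  # jaccard 4/6 < 0.75
        grown = [frozenset("abcde"), frozenset("abcdef")]  # jaccard 5/6 >= 0.75
        sweep = self._sweep_from([[grown[0]]] * 3 + [[grown[1]]] * 3)
        comms = persistent_communities(sweep, 0.75, persistence_min=5)
        assert len(comms) == 1
        assert comms[0].genes == grown[0]
        assert comms[0].persistence == 6
        # below threshold: two separate chains, both too short
        sweep2 = self._sweep_from([[drift[0]]] * 3 + [[drift[1]]] * 3)
        assert persistent_communities(sweep2, 0.75, persistence_min=5) == []


def _mk(cid, genes, rf=0.5, rl=5.0, pers=10):
    return Community(cid, frozenset(genes), rf, rl, pers)


class TestHierarchyAssembly:
    def test_chain_is_transitively_reduced(self):
        comms = [_mk("big", "abcd"), _mk("mid", "ab"), _mk("leaf", "a")]
        h = build_hierarchy(comms, 0.75)
        assert sorted((p, c) for p, c, _ in h.edges) == [("big", "mid"), ("mid", "leaf")]
        assert h.root == "big"
        assert h.is_acyclic()

    def test_disjoint_communities_get_synthetic_root(self):
        comms = [_mk("u", "abc"), _mk("v", "xyz")]
        h = build_hierarchy(comms, 0.75)
        assert h.root == "root"
        assert {(p, c) for p, c, _ in h.edges} == {("root", "u"), ("root", "v")}
        root = h.community("root")
        assert root.genes == frozenset("abcxyz")

    def test_every_edge_satisfies_ci_and_size(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(40)]
        comms = []
        for i in range(12):
            size = int(rng.integers(2, 30))
            comms.append(_mk(f"c{i}", rng.choice(universe, size, replace=False)))
        h = build_hierarchy(comms, 0.75)
        assert h.is_acyclic()
        genes = {c.community_id: c.genes for c in h.nodes}
        for p, c, ci in h.edges:
            assert ci == pytest.approx(containment_index(genes[c], genes[p]))
            if p != "root":
                assert ci > 0.75
                assert len(genes[c]) < len(genes[p])

    def test_transitive_reduction_idempotent_and_preserves_reachability(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(50)]
        comms = [_mk("all", universe)]
        for i in range(20):
            size = int(rng.integers(1, 40))
            comms.append(_mk(f"c{i}", rng.choice(universe, size, replace=False)))
        h = build_hierarchy(comms, 0.6)
        g = h.digraph()
        # pre-reduction candidate graph
        pre = nx.DiGraph()
        gsets = {c.community_id: c.genes for c in h.nodes}
        pre.add_nodes_from(gsets)
        for v in gsets:
            for w in gsets:
                if v != w and len(gsets[v]) < len(gsets[w]) \
                        and containment_index(gsets[v], gsets[w]) > 0.6:
                    pre.add_edge(w, v)
        for n in pre.nodes:
            if n == h.root:
                continue
            assert nx.descendants(pre, n) == nx.descendants(g, n)
        again = nx.transitive_reduction(g)
        assert set(again.edges) == set(g.edges)

    def test_identical_communities_merged(self):
        comms = [_mk("a1", "abc", rf=0.5), _mk("a2", "abc", rf=1.0), _mk("b", "ab")]
        h = build_hierarchy(comms, 0.75)
        ids = {c.community_id for c in h.nodes}
        assert "a2" not in ids and "a1" in ids

    def test_nested_planted_structure_recovered(self):
        # two superblocks, each split into two tight subblocks
        planted = gen_network(PlantedNetworkSpec(
            n_genes=80, n_communities=4, p_within=0.9, p_between=0.0,
            rng_seed=5))
        # stitch pairs of subblocks into superblocks with moderate density
        rng = np.random.default_rng(6)
        extra = []
        for pair in ((0, 1), (2, 3)):
            a = planted.community_members(pair[0], in_network_only=False)
            b = planted.community_members(pair[1], in_network_only=False)
            for g1 in a:
                for g2 in b:
                    if rng.random() < 0.25:
                        extra.append((g1, g2, 1.0))
        net = GeneNetwork(planted.network.edges + extra)
        cfg = HierarchyConfig(
            resolution_grid=tuple(np.round(np.linspace(0.1, 5.0, 25), 10)),
            persistence_min=3)
        sweep = sweep_resolutions(net, cfg)
        comms = persistent_communities(sweep, cfg.jaccard_threshold,
                                       cfg.persistence_min)
        h = build_hierarchy(comms, cfg.ci_threshold, all_genes=net.genes)
        supers = {frozenset(planted.community_members(0)) | frozenset(planted.community_members(1)),
                  frozenset(planted.community_members(2)) | frozenset(planted.community_members(3))}
        subs = {frozenset(planted.community_members(i)) for i in range(4)}
        found = {c.genes for c in h.nodes}
        assert supers <= found
        assert subs <= found
        # each subblock's parent is its superblock
        gsets = {c.community_id: c.genes for c in h.nodes}
        for p, c, ci in h.edges:
            if gsets[c] in subs and gsets[p] in supers:
                assert gsets[c] <= gsets[p]
                assert ci == 1.0

    def test_byte_identical_outputs(self, tmp_path, two_triangles):
        cfg = HierarchyConfig()
        outputs = []
        for run in range(2):
            sweep = sweep_resolutions(two_triangles, cfg)
            comms = persistent_communities(sweep, cfg.jaccard_threshold,
                                           cfg.persistence_min)
            h = build_hierarchy(comms, cfg.ci_threshold,
                                all_genes=two_triangles.genes)
            np_, ep = tmp_path / f"n{run}.tsv", tmp_path / f"e{run}.tsv"
            h.write_tsv(np_, ep)
            outputs.append(np_.read_bytes() + ep.read_bytes())
        assert outputs[0] == outputs[1]
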