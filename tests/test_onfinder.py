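"""Network construction, best-hit repair, Markov clustering, export."""

import itertools

import networkx as nx
import numpy as np
import pytest

from clonnet.clfinder import CLParams
from clonnet.mcl import mcl_partition
from clonnet.onfinder import (
    EdgeWeightScheme,
    OrthNet,
    build_orthnets,
    component_weight_matrix,
    flag_truncated_orfs,
    node_key,
    read_sif,
    repair_best_hit_pairs,
    write_sif,
)
from clonnet.simulate import SimConfig, evolve_genomes

from conftest import identity_pair, make_genome, make_hits


def hexagon_inputs(n_genomes=6, n_loci=25):
    """n identical genomes with mutual identity best-hits."""
    ids = [f"G{k}" for k in range(n_genomes)]
    genomes = {
        g: make_genome(g, {"s1": [f"{g.lower()}_{i:03d}" for i in range(n_loci)]})
        for g in ids
    }
    besthits = {}
    for q, t in itertools.permutations(ids, 2):
        mapping = {
            f"{q.lower()}_{i:03d}": f"{t.lower()}_{i:03d}" for i in range(n_loci)
        }
        besthits[(q, t)] = make_hits(q, t, mapping)
    return genomes, besthits


class TestRawNetworkAndPipeline:
    def test_single_copy_everywhere_gives_perfect_hexagons(self):
        genomes, besthits = hexagon_inputs()
        orthnets, _, _ = build_orthnets(genomes, besthits)
        assert len(orthnets) == 25
        for net in orthnets:
            assert len(net) == 6
            rc_cl = [
                (u, v) for u, v, d in net.graph.edges(data=True)
                if d["property"] == "cl" and d["reciprocity"] == "rc"
            ]
            assert len(rc_cl) == 30  # 15 reciprocal pairs, stored directed

    def test_node_conservation_across_orthnets(self):
        cfg = SimConfig(n_loci=150, seed=5)
        genomes, besthits, clusters, _ = evolve_genomes(cfg, "((A,B),(C,D));")
        orthnets, _, _ = build_orthnets(genomes, besthits, clusters)
        all_nodes = [n for net in orthnets for n in net.graph.nodes]
        assert len(all_nodes) == len(set(all_nodes))
        assert len(all_nodes) == sum(g.n_loci for g in genomes.values())


class TestRepair:
    def _context(self, genomes, besthits):
        _, _, ctx = build_orthnets(genomes, besthits)
        return ctx

    def test_candidate_list_yields_reciprocal_pair(self):
        # A's best hit is B; B's best hit is C (same genome as A) but A is
        # B's candidate #2 and C does not point back at B.
        n = 25
        ga = make_genome("GA", {"s1": [f"a{i:02d}" for i in range(n)]})
        gb = make_genome("GB", {"s1": [f"b{i:02d}" for i in range(n)]})
        fwd = {f"a{i:02d}": f"b{i:02d}" for i in range(n)}
        rev = {f"b{i:02d}": f"a{i:02d}" for i in range(n)}
        rev["b10"] = ["a11", "a10"]  # wrong top hit; a10 is candidate 2
        besthits = {
            ("GA", "GB"): make_hits("GA", "GB", fwd),
            ("GB", "GA"): make_hits("GB", "GA", rev),
        }
        orthnets, _, ctx = build_orthnets(
            {"GA": ga, "GB": gb}, besthits
        )
        net = next(n_ for n_ in orthnets if node_key("GB", "b10") in n_.graph)
        edge = net.graph["GB|b10"]["GA|a10"]
        assert edge["candidate_rank"] == 2
        assert edge["reciprocity"] == "rc"

    def test_absent_candidate_stays_unidirectional(self):
        n = 25
        ga = make_genome("GA", {"s1": [f"a{i:02d}" for i in range(n)]})
        gb = make_genome("GB", {"s1": [f"b{i:02d}" for i in range(n)]})
        fwd = {f"a{i:02d}": f"b{i:02d}" for i in range(n)}
        rev = {f"b{i:02d}": f"a{i:02d}" for i in range(n)}
        rev["b10"] = ["a11"]  # a10 nowhere in b10's list
        besthits = {
            ("GA", "GB"): make_hits("GA", "GB", fwd),
            ("GB", "GA"): make_hits("GB", "GA", rev),
        }
        orthnets, _, _ = build_orthnets({"GA": ga, "GB": gb}, besthits)
        graph = next(
            n_.graph for n_ in orthnets if node_key("GA", "a10") in n_.graph
        )
        assert graph["GA|a10"]["GB|b10"]["reciprocity"] == "uni"

    def test_repair_is_idempotent(self):
        n = 25
        ga = make_genome("GA", {"s1": [f"a{i:02d}" for i in range(n)]})
        gb = make_genome("GB", {"s1": [f"b{i:02d}" for i in range(n)]})
        fwd = {f"a{i:02d}": f"b{i:02d}" for i in range(n)}
        rev = {f"b{i:02d}": f"a{i:02d}" for i in range(n)}
        rev["b10"] = ["a11", "a10"]
        besthits = {
            ("GA", "GB"): make_hits("GA", "GB", fwd),
            ("GB", "GA"): make_hits("GB", "GA", rev),
        }
        from clonnet.onfinder import build_raw_network
        from clonnet.clfinder import classify_projection, effective_projection
        from clonnet.onfinder import OnfinderContext

        genomes = {"GA": ga, "GB": gb}
        projections = {
            (q, t): effective_projection(genomes[q], genomes[t], besthits[(q, t)])
            for q, t in besthits
        }
        relations = {
            (q, t): classify_projection(projections[(q, t)], genomes[q], CLParams())
            for q, t in besthits
        }
        ctx = OnfinderContext(
            genomes=genomes, besthits=besthits, projections=projections,
            td_groups={g: [] for g in genomes},
        )
        graph = build_raw_network(relations, genomes)
        repair_best_hit_pairs(graph, ctx)
        snapshot = {(u, v): dict(d) for u, v, d in graph.edges(data=True)}
        repair_best_hit_pairs(graph, ctx)
        after = {(u, v): dict(d) for u, v, d in graph.edges(data=True)}
        assert snapshot == after


def reference_mcl(W, inflation=1.2, max_iter=500):
    """Independent dense MCL used as an oracle (no pruning, fresh code)."""
    W = np.array(W, dtype=float)
    n = len(W)
    M = W.copy()
    for i in range(n):
        M[i, i] = 0.0
    for i in range(n):
        mx = M[:, i].max()
        M[i, i] = mx if mx > 0 else 1.0
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = M.copy()
        M = np.linalg.matrix_power(M, 2)
        M = M ** inflation
        M = M / M.sum(axis=0, keepdims=True)
        if np.max(np.abs(M - prev)) < 1e-8:
            break
    M[M < 1e-9] = 0.0
    clusters = []
    for i in range(n):
        if M[i, i] > 0:
            members = set(np.nonzero(M[i])[0]) | {i}
            clusters.append(members)
    merged = []
    for c in clusters:
        hit = None
        for m in merged:
            if m & c:
                hit = m
                break
        if hit is None:
            merged.append(set(c))
        else:
            hit |= c
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(merged), 2):
            if a & b:
                a |= b
                merged.remove(b)
                changed = True
                break
    assigned = set().union(*merged) if merged else set()
    for i in range(n):
        if i not in assigned:
            order = np.argsort(-W[i])
            placed = False
            for j in order:
                if W[i, j] > 0 and j in assigned:
                    for m in merged:
                        if j in m:
                            m.add(i)
                            placed = True
                            break
                if placed:
                    break
            if not placed:
                merged.append({i})
            assigned.add(i)
    return {frozenset(m) for m in merged}


def random_weighted_graph(rng, max_nodes=12):
    n = int(rng.integers(2, max_nodes + 1))
    W = np.zeros((n, n))
    weights = [1.5, 1.2, 0.6, 0.5, 0.25]
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.45:
                W[i, j] = W[j, i] = weights[int(rng.integers(0, 5))]
    return W


class TestMCL:
    def test_hexagon_stays_together(self):
        W = np.full((6, 6), 1.2)
        np.fill_diagonal(W, 0.0)
        assert mcl_partition(W) == [set(range(6))]

    def test_weak_bridge_splits_two_hexagons(self):
        W = np.zeros((12, 12))
        for block in (range(6), range(6, 12)):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 1.2
        W[0, 6] = W[6, 0] = 0.25  # one unidirectional tr edge
        parts = {frozenset(c) for c in mcl_partition(W)}
        assert parts == {frozenset(range(6)), frozenset(range(6, 12))}

    @pytest.mark.parametrize("seed", range(4))
    def test_agreement_with_reference_mcl(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            W = random_weighted_graph(rng)
            ours = {frozenset(c) for c in mcl_partition(W)}
            ref = reference_mcl(W)
            assert ours == ref, f"disagreement on\n{W}"

    def test_out_paralogue_aggregate_splits(self):
        # two co-linear hexagons bridged only by weak tr edges
        genomes, besthits = hexagon_inputs(n_genomes=4, n_loci=30)
        graph = nx.DiGraph()
        for block, prefix in ((0, "p"), (1, "q")):
            for k in range(4):
                graph.add_node(f"G{k}|{prefix}{k}", genome=f"G{k}", gene=f"{prefix}{k}",
                               orf_length=900, scaffold="s1", rank=k, truncation="none")
        for prefix in ("p", "q"):
            for a in range(4):
                for b in range(4):
                    if a != b:
                        graph.add_edge(f"G{a}|{prefix}{a}", f"G{b}|{prefix}{b}",
                                       property="cl", reciprocity="rc", candidate_rank=1)
        graph.add_edge("G0|p0", "G1|q1", property="tr", reciprocity="uni", candidate_rank=1)
        nodes = sorted(graph.nodes)
        W = component_weight_matrix(graph, nodes, EdgeWeightScheme())
        parts = {
            frozenset(nodes[i] for i in c) for c in mcl_partition(W)
        }
        assert parts == {
            frozenset(n for n in nodes if "|p" in n),
            frozenset(n for n in nodes if "|q" in n),
        }


class TestTruncationFlags:
    def _net(self, orfs):
        graph = nx.DiGraph()
        names = list(orfs)
        for i, (name, orf) in enumerate(orfs.items()):
            graph.add_node(f"G{i}|{name}", genome=f"G{i}", gene=name,
                           orf_length=orf, scaffold="s", rank=0, truncation="none")
        hub = f"G0|{names[0]}"
        for i, name in enumerate(names[1:], start=1):
            graph.add_edge(hub, f"G{i}|{name}", property="cl",
                           reciprocity="rc", candidate_rank=1)
            graph.add_edge(f"G{i}|{name}", hub, property="cl",
                           reciprocity="rc", candidate_rank=1)
        return OrthNet(orthnet_id="ON_x", graph=graph)

    def test_equal_orfs_unflagged(self):
        net = self._net({"a": 900, "b": 900, "c": 900})
        flag_truncated_orfs(net)
        assert all(d["truncation"] == "none" for _, d in net.graph.nodes(data=True))

    def test_lt40_and_lt80(self):
        net = self._net({"short": 300, "b": 1000, "c": 1000, "d": 900})
        flag_truncated_orfs(net)
        assert net.graph.nodes["G0|short"]["truncation"] == "lt40"
        net2 = self._net({"mid": 700, "b": 1000, "c": 1000, "d": 1000})
        flag_truncated_orfs(net2)
        assert net2.graph.nodes["G0|mid"]["truncation"] == "lt80"


class TestSifExport:
    def test_hexagon_has_15_reciprocal_lines(self, tmp_path):
        genomes, besthits = hexagon_inputs(n_loci=21)
        orthnets, _, _ = build_orthnets(genomes, besthits)
        path = tmp_path / "net.sif"
        write_sif(orthnets[0], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 15
        assert all("cl_rc" in line for line in lines)

    def test_round_trip_preserves_topology(self, tmp_path):
        genomes, besthits = hexagon_inputs(n_genomes=3, n_loci=21)
        orthnets, _, _ = build_orthnets(genomes, besthits)
        net = orthnets[0]
        path = tmp_path / "net.sif"
        write_sif(net, path)
        back = read_sif(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        want = {
            (u, v, d["property"], d["reciprocity"])
            for u, v, d in net.graph.edges(data=True)
        }
        got = {
            (u, v, d["property"], d["reciprocity"])
            for u, v, d in back.graph.edges(data=True)
        }
        assert want == got

    def test_td_pair_written_once(self, tmp_path):
        graph = nx.DiGraph()
        for name in ("a", "b"):
            graph.add_node(f"GX|{name}", genome="GX", gene=name, orf_length=900,
                           scaffold="s", rank=0, truncation="none")
        graph.add_edge("GX|a", "GX|b", property="td", reciprocity="und",
                       candidate_rank=0)
        net = OrthNet(orthnet_id="ON_td", graph=graph)
        path = tmp_path / "td.sif"
        write_sif(net, path)
        assert path.read_text().strip() == "GX|a\ttd\tGX|b"
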