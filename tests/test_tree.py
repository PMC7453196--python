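"""Clone-tree rules, exhaustive enumeration vs brute force, subtrees, drivers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonephy.cluster import ClusterSet, annotate_clonality
from clonephy.tree import (
    BRANCHING_REQUIRED,
    ORDER_PERMITTED,
    SYMMETRIC,
    CloneTree,
    assign_drivers,
    build_trees,
    check_crossing_rule,
    check_dominance,
    check_sum_rule,
    count_bifurcations,
    enumerate_valid_trees,
    sample_subtree,
    write_newick,
)

from conftest import match_called_to_truth


def _cluster_set(locs, sizes=None, samples=None):
    """locs: {cluster_id: tuple of per-sample CCFs}."""
    samples = samples or [f"S{i+1}" for i in range(len(next(iter(locs.values()))))]
    rows = {}
    for cid, v in locs.items():
        rows[cid] = {"n_snvs": (sizes or {}).get(cid, 100),
                     **{f"ccf_{s}": v[j] for j, s in enumerate(samples)}}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cluster_id"
    cs = ClusterSet(clusters=df, assignments=pd.Series(dtype=object),
                    samples=samples)
    return annotate_clonality(cs)


class TestRules:
    def test_dominance(self):
        assert check_dominance((1, 1), (0.5, 0.5))
        assert not check_dominance((0.5, 0.5), (0.5, 0.5))  # no strict sample
        assert not check_dominance((0.6, 0.2), (0.2, 0.5))
        with pytest.raises(ValueError):
            check_dominance((1, 1), (1, 1, 1))

    def test_sum_rule(self):
        assert check_sum_rule((1, 1), [(0.6, 0.2), (0.3, 0.5)])
        assert not check_sum_rule((1, 1), [(0.7, 0.4), (0.5, 0.3)])
        assert check_sum_rule((1, 1), [(0.5, 0.5)])
        with pytest.raises(ValueError):
            check_sum_rule((1, 1), [])

    def test_crossing_rule(self):
        assert check_crossing_rule((0.6, 0.2), (0.2, 0.5)) == BRANCHING_REQUIRED
        assert check_crossing_rule((0.6, 0.5), (0.2, 0.1)) == ORDER_PERMITTED
        assert check_crossing_rule((0.4, 0.4), (0.4, 0.4)) == SYMMETRIC

    def test_crossing_rule_symmetric_under_swap(self):
        rng = np.random.default_rng(7)
        swap_ok = {BRANCHING_REQUIRED: BRANCHING_REQUIRED, SYMMETRIC: SYMMETRIC,
                   ORDER_PERMITTED: ORDER_PERMITTED}
        for _ in range(200):
            b, c = rng.random(3), rng.random(3)
            r1 = check_crossing_rule(b, c)
            r2 = check_crossing_rule(c, b)
            assert swap_ok[r1] == r2


def brute_force_trees(ccfs, root, eps):
    """Independent oracle: enumerate every parent assignment over all
    clusters, keep acyclic trees satisfying the three rules post-hoc."""
    ids = list(ccfs)
    non_root = [c for c in ids if c != root]
    valid = []
    for combo in itertools.product(*[[p for p in ids if p != c]
                                     for c in non_root]):
        parent = dict(zip(non_root, combo))
        parent[root] = None
        # acyclic / rooted
        ok = True
        for c in non_root:
            seen, p = {c}, parent[c]
            while p is not None:
                if p in seen:
                    ok = False
                    break
                seen.add(p)
                p = parent[p]
            if not ok:
                break
        if not ok:
            continue
        # dominance on every edge
        if any(not check_dominance(ccfs[parent[c]], ccfs[c], eps)
               for c in non_root):
            continue
        # sum rule at every node
        kids = {}
        for c in non_root:
            kids.setdefault(parent[c], []).append(c)
        if any(not check_sum_rule(ccfs[n], [ccfs[k] for k in ks], eps)
               for n, ks in kids.items()):
            continue
        # crossing rule: branching pairs must not be ancestrally related
        bad = False
        for a, b in itertools.combinations(ids, 2):
            if check_crossing_rule(ccfs[a], ccfs[b], eps) != BRANCHING_REQUIRED:
                continue
            for x, y in ((a, b), (b, a)):
                p = parent[x]
                while p is not None:
                    if p == y:
                        bad = True
                        break
                    p = parent[p]
        if bad:
            continue
        valid.append(frozenset((c, parent[c]) for c in non_root))
    return set(valid)


class TestEnumeration:
    def test_matches_brute_force_on_random_instances(self):
        """Exhaustive agreement with the brute-force oracle on 200 random
        CCF configurations of up to 6 clusters."""
        rng = np.random.default_rng(20240)
        for trial in range(200):
            k = int(rng.integers(2, 7))
            n_samples = int(rng.integers(1, 4))
            ccfs = {"T": np.ones(n_samples)}
            for i in range(k - 1):
                ccfs[f"N{i}"] = np.round(rng.random(n_samples), 2)
            eps = float(rng.choice([0.0, 0.05, 0.1]))
            got = {
                frozenset((c, p) for c, p in parent.items() if p is not None)
                for parent in enumerate_valid_trees(ccfs, "T", eps)
            }
            expected = brute_force_trees(ccfs, "T", eps)
            assert got == expected, f"trial {trial}: {got} != {expected}"

    def test_enumeration_bound(self):
        ccfs = {"T": np.ones(2)}
        for i in range(12):
            ccfs[f"N{i}"] = np.array([0.01 * (i + 1), 0.01 * (i + 1)])
        with pytest.raises(ValueError, match="prune"):
            enumerate_valid_trees(ccfs, "T")


class TestBuildTrees:
    def test_mutually_exclusive_clonal_children_unique_tree(self):
        cs = _cluster_set({"T": (1, 1, 1, 1), "B": (1, 1, 0, 0),
                           "D": (0, 0, 1, 1)})
        sols = build_trees(cs)
        assert len(sols.trees) == 1
        tree = sols.best
        assert sorted(tree.children("T")) == ["B", "D"]

    def test_single_truncal_cluster_single_node_tree(self):
        cs = _cluster_set({"T": (1, 1)})
        sols = build_trees(cs)
        assert sols.best.nodes == ["T"]
        assert count_bifurcations(sols.best) == 0

    def test_requires_truncal_cluster(self):
        cs = _cluster_set({"A": (0.5, 0.5), "B": (0.3, 0.2)})
        with pytest.raises(ValueError, match="truncal"):
            build_trees(cs)

    def test_generating_topology_of_branching_design(self):
        cs = _cluster_set({
            "T": (1, 1, 1, 1), "B": (1, 1, 0, 0), "D": (0, 0, 1, 1),
            "C1": (0.7, 0, 0, 0), "C2": (0, 0.3, 0, 0),
            "C3": (0, 0, 0.7, 0), "C4": (0, 0, 0, 0.3)})
        sols = build_trees(cs)
        tree = sols.best
        assert tree.parent == {"T": None, "B": "T", "D": "T", "C1": "B",
                               "C2": "B", "C3": "D", "C4": "D"}
        assert count_bifurcations(tree) == 3
        assert tree.audit()

    def test_artefact_cluster_removed_and_reported(self):
        cs = _cluster_set({
            "T": (1, 1), "B": (0.9, 0.1), "C": (0.1, 0.9),
            # X crosses both B and C but no parent can host the sums
            "X": (0.6, 0.6)}, sizes={"T": 1000, "B": 300, "C": 300, "X": 5})
        sols = build_trees(cs)
        assert sols.trees
        assert "X" in sols.removed or all("X" not in t.nodes for t in sols.trees)

    def test_returned_trees_pass_audit(self, design_run):
        run = design_run(3, 5000, 3)
        cs = run["results"].called_cluster_set
        sols = build_trees(cs)
        for t in sols.trees:
            assert t.audit()

    def test_recovered_clusters_rebuild_generating_topology(self, design_run):
        run = design_run(3, 5000, 3)
        cs = run["results"].called_cluster_set
        sols = build_trees(cs)
        tree = sols.best
        assert count_bifurcations(tree) == 3
        match = match_called_to_truth(cs, run["truth"], cs.samples)
        name = {t: c for t, (c, _) in match.items()}
        assert tree.parent[name["B"]] == name["T"]
        assert tree.parent[name["C1"]] == name["B"]
        assert tree.parent[name["C4"]] == name["D"]


class TestSampleSubtree:
    TREE = CloneTree(
        root="T",
        parent={"T": None, "B": "T", "D": "T", "C1": "B"},
        ccf={"T": np.array([1.0, 1.0]), "B": np.array([1.0, 0.0]),
             "D": np.array([0.0, 1.0]), "C1": np.array([0.6, 0.0])},
        n_snvs={"T": 1000, "B": 100, "D": 100, "C1": 50},
        samples=["S1", "S2"])

    def test_absent_nodes_excluded(self):
        sub = sample_subtree(self.TREE, "S1")
        assert set(sub.nodes) == {"T", "B", "C1"}

    def test_root_always_present(self):
        for s in ("S1", "S2"):
            assert self.TREE.root in sample_subtree(self.TREE, s).nodes

    def test_unknown_sample_raises(self):
        with pytest.raises(ValueError):
            sample_subtree(self.TREE, "S9")

    def test_bridging_over_excluded_intermediate(self):
        tree = CloneTree(
            root="T", parent={"T": None, "A": "T", "B": "A"},
            ccf={"T": np.array([1.0]), "A": np.array([0.0]),
                 "B": np.array([0.0])},
            n_snvs={"T": 10, "A": 5, "B": 2}, samples=["S1"])
        tree.ccf["B"] = np.array([0.4])  # B present, its parent A absent
        sub = sample_subtree(tree, "S1")
        assert sub.parent["B"] == "T"

    def test_lineage_separation_on_recovered_tree(self, design_run):
        """A sample carrying one clonal lineage shows no clusters of the
        opposing lineage in its subtree."""
        run = design_run(3, 5000, 3)
        cs = run["results"].called_cluster_set
        tree = build_trees(cs).best
        match = match_called_to_truth(cs, run["truth"], cs.samples)
        name = {t: c for t, (c, _) in match.items()}
        sub = sample_subtree(tree, "S1")
        assert name["B"] in sub.nodes
        for other in ("D", "C3", "C4"):
            assert name[other] not in sub.nodes


class TestDrivers:
    def _setup(self):
        cs = _cluster_set({"T": (1, 1), "B": (0.6, 0.2)})
        cs.assignments = pd.Series({"snv_braf": "T", "snv_tp53": "B"})
        tree = build_trees(cs).best
        return cs, tree

    def test_truncal_driver_on_trunk(self):
        cs, tree = self._setup()
        out = assign_drivers(tree, cs, {"snv_braf": "BRAF"})
        assert out.drivers["T"] == ["BRAF"]

    def test_branch_driver_on_branch(self):
        cs, tree = self._setup()
        out = assign_drivers(tree, cs, {"snv_tp53": "TP53"})
        assert out.drivers["B"] == ["TP53"]

    def test_unassigned_driver_reported_not_fatal(self):
        cs, tree = self._setup()
        out = assign_drivers(tree, cs, {"snv_unknown": "KRAS"})
        assert out.drivers["<unplaced>"] == ["KRAS"]

    def test_empty_driver_list_unchanged(self):
        cs, tree = self._setup()
        out = assign_drivers(tree, cs, [])
        assert out.drivers == {}
        assert out.parent == tree.parent


class TestNewick:
    def test_shapes(self):
        tree = CloneTree(root="T", parent={"T": None, "B": "T", "D": "T"},
                         ccf={k: np.array([1.0]) for k in "TBD"},
                         n_snvs={"T": 10, "B": 3, "D": 4}, samples=["S1"])
        assert write_newick(tree) == "(B:3,D:4)T:10;"
        single = CloneTree(root="T", parent={"T": None},
                           ccf={"T": np.array([1.0])}, n_snvs={"T": 7},
                           samples=["S1"])
        assert write_newick(single) == "T:7;"

    def test_round_trip_through_standard_parser(self):
        dendropy = pytest.importorskip("dendropy")
        tree = CloneTree(
            root="T",
            parent={"T": None, "B": "T", "D": "T", "C1": "B", "C2": "B"},
            ccf={k: np.array([1.0]) for k in ("T", "B", "D", "C1", "C2")},
            n_snvs={"T": 100, "B": 10, "D": 20, "C1": 5, "C2": 6},
            samples=["S1"])
        parsed = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        labels = {}
        for node in parsed.preorder_node_iter():
            name = node.taxon.label if node.taxon else node.label
            parent = node.parent_node
            pname = None
            if parent is not None:
                pname = parent.taxon.label if parent.taxon else parent.label
            labels[name] = pname
            if name in tree.n_snvs:
                assert node.edge.length == tree.n_snvs[name]
        assert labels == tree.parent
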