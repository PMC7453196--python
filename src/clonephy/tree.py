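"""Clone-tree reconstruction from cluster CCFs.

Under the infinite sites assumption (each mutation arises once and never
reverts), the per-sample CCFs of mutation clusters constrain their ancestry:

* dominance — an ancestor's CCF must be >= the descendant's in every sample,
  and strictly greater in at least one;
* sum rule — sibling clusters' CCFs may not sum above their parent's CCF in
  any sample (pigeonhole);
* crossing rule — two clusters whose CCF ordering flips between samples
  cannot be ancestrally related and must branch.

Trees rooted at the truncal cluster (the MRCA) are enumerated exhaustively
over parent assignments that satisfy all three rules; clusters that cannot be
placed under any topology are treated as artefacts and removed. Valid trees
are ranked by total rule slack (the amount of tolerance each constraint
consumed), most parsimonious first. Sample-level trees are induced subtrees
on the clusters present in a sample.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterSet

__all__ = [
    "CloneTree",
    "TreeSolutionSet",
    "check_dominance",
    "check_sum_rule",
    "check_crossing_rule",
    "enumerate_valid_trees",
    "build_trees",
    "sample_subtree",
    "assign_drivers",
    "count_bifurcations",
    "write_newick",
]

DEFAULT_EPS = 0.1
MAX_CLUSTERS = 12
_MAX_VISITS = 5_000_000

BRANCHING_REQUIRED = "branching-required"
ORDER_PERMITTED = "order-permitted"
SYMMETRIC = "symmetric"


@dataclass
class CloneTree:
    """Rooted clone tree: nodes are cluster ids, root is the truncal cluster.

    ``n_snvs`` (branch length) and per-sample ``ccf`` (whose mean across
    samples is the branch width) annotate every node. ``drivers`` maps nodes
    to driver mutation labels.
    """

    root: str
    parent: dict
    ccf: dict
    n_snvs: dict
    samples: list
    drivers: dict = field(default_factory=dict)
    slack: float = 0.0

    def children(self, node) -> list:
        return [c for c, p in self.parent.items() if p == node]

    @property
    def nodes(self) -> list:
        return [self.root] + [c for c in self.parent if self.parent[c] is not None]

    def ancestors(self, node) -> list:
        out = []
        while self.parent.get(node) is not None:
            node = self.parent[node]
            out.append(node)
        return out

    def mean_ccf(self, node) -> float:
        """Branch width: mean CCF of the cluster across all samples."""
        return float(np.mean(self.ccf[node]))

    def audit(self, eps: float = DEFAULT_EPS) -> bool:
        """Post-hoc check of dominance and the sum rule at every edge/node."""
        for c, p in self.parent.items():
            if p is None:
                continue
            if not check_dominance(self.ccf[p], self.ccf[c], eps):
                return False
        for node in self.nodes:
            kids = self.children(node)
            if kids and not check_sum_rule(self.ccf[node],
                                           [self.ccf[k] for k in kids], eps):
                return False
        return True

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "samples": list(self.samples),
            "nodes": {
                n: {
                    "parent": self.parent.get(n),
                    "n_snvs": int(self.n_snvs.get(n, 0)),
                    "ccf_per_sample": [float(x) for x in self.ccf[n]],
                    "mean_ccf": self.mean_ccf(n),
                    "drivers": list(self.drivers.get(n, [])),
                }
                for n in self.nodes
            },
        }


@dataclass
class TreeSolutionSet:
    """All rule-satisfying trees (ranked by slack) plus removed clusters."""

    trees: list
    removed: dict  # cluster_id -> violation reason

    @property
    def best(self) -> CloneTree:
        if not self.trees:
            raise ValueError("no valid tree solutions")
        return self.trees[0]


def _as_vec(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def check_dominance(ancestor_ccf, descendant_ccf, eps: float = DEFAULT_EPS) -> bool:
    """True iff ``ancestor`` may be an ancestor of ``descendant``: CCF >=
    descendant - eps in all samples and strictly greater (by > eps) in at
    least one."""
    a, d = _as_vec(ancestor_ccf), _as_vec(descendant_ccf)
    if a.shape != d.shape:
        raise ValueError("CCF vectors must have equal sample dimension")
    return bool(np.all(a >= d - eps) and np.any(a > d + eps))


def check_sum_rule(parent_ccf, children_ccfs, eps: float = DEFAULT_EPS) -> bool:
    """True iff in every sample the children's CCFs sum to at most the
    parent's CCF (+ eps)."""
    p = _as_vec(parent_ccf)
    kids = [_as_vec(c) for c in children_ccfs]
    if not kids:
        raise ValueError("need at least one child")
    if any(c.shape != p.shape for c in kids):
        raise ValueError("CCF vectors must have equal sample dimension")
    return bool(np.all(np.sum(kids, axis=0) <= p + eps))


def check_crossing_rule(ccf_b, ccf_c, eps: float = DEFAULT_EPS) -> str:
    """Classify the relation of two clusters from their CCF ordering.

    ``branching-required`` when each exceeds the other (by > eps) in some
    sample; ``symmetric`` when equal within eps everywhere; otherwise
    ``order-permitted`` (one weakly dominates, so an ancestral relation is
    allowed)."""
    b, c = _as_vec(ccf_b), _as_vec(ccf_c)
    if b.shape != c.shape:
        raise ValueError("CCF vectors must have equal sample dimension")
    b_gt = np.any(b > c + eps)
    c_gt = np.any(c > b + eps)
    if b_gt and c_gt:
        return BRANCHING_REQUIRED
    if not b_gt and not c_gt:
        return SYMMETRIC
    return ORDER_PERMITTED


def _tree_slack(root, parent, ccf) -> float:
    """Tolerance consumed by dominance and sum-rule constraints (0 = rules
    hold exactly; larger = the tree leans harder on eps)."""
    slack = 0.0
    children = {}
    for c, p in parent.items():
        if p is not None:
            children.setdefault(p, []).append(c)
            slack += float(np.sum(np.maximum(ccf[c] - ccf[p], 0.0)))
    for node, kids in children.items():
        tot = np.sum([ccf[k] for k in kids], axis=0)
        slack += float(np.sum(np.maximum(tot - ccf[node], 0.0)))
    return slack


def enumerate_valid_trees(cluster_ccfs: dict, root: str,
                          eps: float = DEFAULT_EPS) -> list:
    """Enumerate every rooted tree over the clusters satisfying dominance,
    sum and crossing rules in all samples.

    ``cluster_ccfs`` maps cluster_id -> per-sample CCF vector; ``root`` must
    be one of them. Returns parent dicts (root maps to None). Raises on more
    than 12 clusters.
    """
    ids = list(cluster_ccfs)
    if root not in cluster_ccfs:
        raise ValueError(f"root cluster {root!r} not among clusters")
    if len(ids) > MAX_CLUSTERS:
        raise ValueError(
            f"{len(ids)} clusters exceed the enumeration bound of "
            f"{MAX_CLUSTERS}; prune clusters first")
    ccf = {k: _as_vec(v) for k, v in cluster_ccfs.items()}
    non_root = [k for k in ids if k != root]

    candidates = {
        c: [p for p in ids if p != c and check_dominance(ccf[p], ccf[c], eps)]
        for c in non_root
    }
    must_branch = {
        frozenset((a, b))
        for a, b in itertools.combinations(ids, 2)
        if check_crossing_rule(ccf[a], ccf[b], eps) == BRANCHING_REQUIRED
    }
    if any(not v for v in candidates.values()):
        return []

    # place hardest-to-place clusters first
    order = sorted(non_root, key=lambda c: len(candidates[c]))
    solutions = []
    visits = 0

    def ancestors_of(node, parent):
        while parent.get(node) is not None:
            node = parent[node]
            yield node

    def ok_so_far(node, parent):
        # acyclicity within assigned-so-far + crossing constraint
        seen = {node}
        for anc in ancestors_of(node, parent):
            if anc in seen:
                return False
            seen.add(anc)
            if frozenset((node, anc)) in must_branch:
                return False
        # sum rule at the new parent over currently assigned children
        p = parent[node]
        kids = [c for c, q in parent.items() if q == p]
        if not check_sum_rule(ccf[p], [ccf[k] for k in kids], eps):
            return False
        # crossing constraint against descendants already attached below node
        stack = [c for c, q in parent.items() if q == node]
        while stack:
            d = stack.pop()
            if frozenset((node, d)) in must_branch:
                return False
            stack.extend(c for c, q in parent.items() if q == d)
        return True

    def rec(i, parent):
        nonlocal visits
        if i == len(order):
            solutions.append({root: None, **parent})
            return
        node = order[i]
        for p in candidates[node]:
            visits += 1
            if visits > _MAX_VISITS:
                raise RuntimeError("tree enumeration budget exceeded; prune clusters")
            parent[node] = p
            if ok_so_far(node, parent):
                rec(i + 1, parent)
            del parent[node]

    rec(0, {})
    return solutions


def build_trees(cluster_set: ClusterSet, eps: float = DEFAULT_EPS) -> TreeSolutionSet:
    """Reconstruct the patient-level clone tree(s) from called clusters.

    Enumerates all rooted trees (root = truncal cluster) satisfying the
    rules; if none exists, greedily removes the cluster involved in most
    unresolvable pairwise conflicts (ties: fewer SNVs) and retries.
    Solutions are ranked by total rule slack, most parsimonious first.
    """
    truncal = cluster_set.truncal_id
    if truncal is None:
        raise ValueError("no truncal cluster: cannot root the clone tree")
    ccfs = {cid: cluster_set.location_of(cid) for cid in cluster_set.cluster_ids}
    n_snvs = cluster_set.clusters["n_snvs"].to_dict()
    removed: dict = {}

    def conflict_scores(current):
        """Per-cluster count of unresolvable conflicts."""
        scores = {c: 0 for c in current if c != truncal}
        for c in scores:
            parents = [p for p in current
                       if p != c and check_dominance(ccfs[p], ccfs[c], eps)]
            if not parents:
                scores[c] += len(current)  # unplaceable: dominates any pair count
        for a, b in itertools.combinations([c for c in current if c != truncal], 2):
            if check_crossing_rule(ccfs[a], ccfs[b], eps) != BRANCHING_REQUIRED:
                continue
            # branching pair that no common ancestor can host as siblings
            hosts = [p for p in current if p not in (a, b)
                     and check_dominance(ccfs[p], ccfs[a], eps)
                     and check_dominance(ccfs[p], ccfs[b], eps)
                     and check_sum_rule(ccfs[p], [ccfs[a], ccfs[b]], eps)]
            if not hosts:
                scores[a] += 1
                scores[b] += 1
        return scores

    current = list(ccfs)
    while True:
        parents_list = enumerate_valid_trees(
            {c: ccfs[c] for c in current}, truncal, eps)
        if parents_list:
            break
        scores = conflict_scores(current)
        if not scores:
            parents_list = [{truncal: None}]
            break
        worst = max(scores, key=lambda c: (scores[c], -n_snvs.get(c, 0)))
        if scores[worst] == 0:
            # conflicts are higher-order; fall back to removing smallest cluster
            worst = min((c for c in current if c != truncal),
                        key=lambda c: n_snvs.get(c, 0))
        reason = ("no-dominating-parent"
                  if not any(p != worst and check_dominance(ccfs[p], ccfs[worst], eps)
                             for p in current)
                  else "rule-violations")
        removed[worst] = reason
        current.remove(worst)
        if current == [truncal]:
            parents_list = [{truncal: None}]
            break

    trees = []
    for parent in parents_list:
        tree = CloneTree(
            root=truncal, parent=parent,
            ccf={c: ccfs[c] for c in parent},
            n_snvs={c: int(n_snvs.get(c, 0)) for c in parent},
            samples=list(cluster_set.samples),
            slack=_tree_slack(truncal, parent, ccfs))
        trees.append(tree)
    trees.sort(key=lambda t: (t.slack, tuple(sorted(t.parent.items(),
                                                    key=lambda kv: str(kv)))))
    return TreeSolutionSet(trees=trees, removed=removed)


def sample_subtree(tree: CloneTree, sample_id: str,
                   presence_tol: float = 0.05) -> CloneTree:
    """Induced subtree of the clusters present in one sample (CCF above
    ``presence_tol``); the truncal root is always retained and excluded
    intermediate nodes are bridged over."""
    if sample_id not in tree.samples:
        raise ValueError(f"unknown sample {sample_id!r}")
    j = tree.samples.index(sample_id)
    keep = {n for n in tree.nodes if tree.ccf[n][j] > presence_tol}
    keep.add(tree.root)
    parent = {}
    for n in keep:
        if n == tree.root:
            parent[n] = None
            continue
        p = tree.parent[n]
        while p is not None and p not in keep:
            p = tree.parent[p]
        parent[n] = p if p is not None else tree.root
    return CloneTree(
        root=tree.root, parent=parent,
        ccf={n: tree.ccf[n] for n in keep},
        n_snvs={n: tree.n_snvs.get(n, 0) for n in keep},
        samples=list(tree.samples),
        drivers={n: tree.drivers.get(n, []) for n in keep if n in tree.drivers})


def assign_drivers(tree: CloneTree, cluster_set: ClusterSet,
                   driver_snvs) -> CloneTree:
    """Annotate the tree with driver mutations via their cluster assignment.

    ``driver_snvs`` maps snv_id -> driver label (or is a list of snv_ids).
    Drivers in the truncal cluster land on the trunk; drivers whose SNV is
    unassigned or whose cluster is not in the tree are reported in
    ``tree.drivers['<unplaced>']``. Input order is preserved.
    """
    if not isinstance(driver_snvs, dict):
        driver_snvs = {s: s for s in driver_snvs}
    drivers = {n: list(tree.drivers.get(n, [])) for n in tree.drivers}
    for snv_id, label in driver_snvs.items():
        cl = cluster_set.assignments.get(snv_id)
        if cl is None or (isinstance(cl, float) and np.isnan(cl)) \
                or cl not in tree.nodes:
            drivers.setdefault("<unplaced>", []).append(label)
        else:
            drivers.setdefault(cl, []).append(label)
    return CloneTree(root=tree.root, parent=dict(tree.parent),
                     ccf=dict(tree.ccf), n_snvs=dict(tree.n_snvs),
                     samples=list(tree.samples), drivers=drivers,
                     slack=tree.slack)


def count_bifurcations(tree: CloneTree) -> int:
    """Number of nodes with at least two children."""
    return sum(1 for n in tree.nodes if len(tree.children(n)) >= 2)


def write_newick(tree: CloneTree) -> str:
    """Newick serialisation: labels are cluster ids, branch lengths are SNV
    counts (cluster burdens)."""

    def render(node):
        kids = sorted(tree.children(node))
        label = f"{node}:{tree.n_snvs.get(node, 0)}"
        if not kids:
            return label
        return "(" + ",".join(render(k) for k in kids) + ")" + label

    return render(tree.root) + ";"
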