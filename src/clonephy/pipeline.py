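"""End-to-end pipeline: reads -> CCFs -> filters -> clusters -> clone tree.

The stages mirror the standard multi-sample clonality workflow: estimate a
CCF per SNV per sample, remove pseudo-heterogeneity explainable by copy
number, cluster SNVs across samples with the Dirichlet-process mixture, drop
clusters under the minimum size fraction, annotate clonality, reconstruct
the clone tree under the sum and crossing rules, derive per-sample subtrees
and place driver mutations.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ccf import compute_ccf_matrix
from .cluster import ClusterConfig, DirichletProcessMixture
from .filters import apply_heterogeneity_filters, write_filter_report
from .io import read_purities, read_segments, read_snv_table
from .tree import assign_drivers, build_trees, sample_subtree, write_newick

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("clonephy")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    reads: str
    segments: str
    purities: str
    out_dir: str
    reads_format: str = "tsv"
    drivers: str | None = None
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    tree_eps: float = 0.1
    presence_tol: float = 0.05
    seed: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "cluster" in d and isinstance(d["cluster"], dict):
            d["cluster"] = ClusterConfig(**d["cluster"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the artefact bundle to ``cfg.out_dir``.

    Outputs: ``assignments.tsv`` (SNV -> cluster with per-sample CCF
    locations), ``clusters.tsv``, ``tree.nwk`` + ``tree.json`` (with
    per-sample subtrees and drivers), ``filter_report.tsv`` and
    ``run_log.json`` recording the seed and all resolved settings.
    Returns the bundle as a dict of in-memory objects.
    """
    logging.basicConfig(level=cfg.log_level, stream=sys.stderr)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.seed is not None:
        cfg.cluster = dataclasses.replace(cfg.cluster, seed=cfg.seed)

    def stage(name, fn, *args, **kw):
        log.info("stage %s", name)
        try:
            return fn(*args, **kw)
        except Exception as e:  # noqa: BLE001 - reported with stage name
            raise StageError(name, e) from e

    reads = stage("load-reads", read_snv_table, cfg.reads, cfg.reads_format)
    if reads.n_snvs == 0:
        raise StageError("ccf", "empty SNV table")
    segments = stage("load-segments", read_segments, cfg.segments)
    purities = stage("load-purities", read_purities, cfg.purities)

    ccf = stage("ccf", compute_ccf_matrix, reads, segments, purities)
    ccf, filter_report = stage("het-filter", apply_heterogeneity_filters,
                               ccf, reads)

    def _cluster():
        model = DirichletProcessMixture(reads.subset(ccf.snv_ids), ccf,
                                        cfg.cluster)
        return model.fit()

    results = stage("cluster", _cluster)
    cluster_set = results.cluster_set

    solutions = stage("tree", build_trees, cluster_set, cfg.tree_eps)
    tree = solutions.best
    if cfg.drivers:
        driver_list = [l.strip() for l in open(cfg.drivers)
                       if l.strip() and not l.startswith("#")]
        tree = stage("drivers", assign_drivers, tree, cluster_set, driver_list)
    subtrees = {s: sample_subtree(tree, s, cfg.presence_tol)
                for s in cluster_set.samples}

    # -- outputs ----------------------------------------------------------
    assignments = cluster_set.assignments.rename("cluster_id").to_frame()
    loc = cluster_set.locations()
    for s in cluster_set.samples:
        assignments[f"ccf_{s}"] = assignments["cluster_id"].map(loc[f"ccf_{s}"])
    with open(out / "assignments.tsv", "w") as fh:
        fh.write("# SNV cluster assignments; positions 1-based in source table\n")
        assignments.to_csv(fh, sep="\t", index_label="snv_id")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("# called clusters with per-sample CCF locations\n")
        cluster_set.clusters.to_csv(fh, sep="\t", index_label="cluster_id")
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")
    tree_doc = tree.to_dict()
    tree_doc["sample_subtrees"] = {s: t.to_dict() for s, t in subtrees.items()}
    tree_doc["alternative_trees"] = len(solutions.trees)
    tree_doc["removed_clusters"] = solutions.removed
    (out / "tree.json").write_text(json.dumps(tree_doc, indent=2))
    write_filter_report(filter_report, out / "filter_report.tsv")
    run_log = {"version": __version__, "seed": cfg.cluster.seed,
               "config": cfg.to_dict()}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))

    return {"reads": reads, "ccf": ccf, "filter_report": filter_report,
            "results": results, "cluster_set": cluster_set,
            "solutions": solutions, "tree": tree, "subtrees": subtrees}
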