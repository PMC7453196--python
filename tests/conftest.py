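"""Shared fixtures: simulated datasets and fitted cluster models.

Heavy Gibbs runs are cached per (design, trunk size, seed) so the recovery
tests and the end-to-end tests share a single sampler run per condition.
"""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from clonephy.ccf import compute_ccf_matrix
from clonephy.cluster import ClusterConfig, DirichletProcessMixture
from clonephy.simulate import (
    simulate_reads,
    simulated_purities,
    simulated_segments,
    standard_design,
)

RECOVERY_TRUNK = 5000


@lru_cache(maxsize=16)
def _design_run(design: int, trunk: int, seed: int):
    spec = standard_design(design, trunk_snvs=trunk, seed=1000 + seed)
    reads, truth = simulate_reads(spec)
    ccf = compute_ccf_matrix(reads, simulated_segments(spec),
                             simulated_purities(spec))
    model = DirichletProcessMixture(reads, ccf, ClusterConfig(seed=seed))
    res = model.fit()
    return {"spec": spec, "reads": reads, "truth": truth, "ccf": ccf,
            "results": res}


@pytest.fixture(scope="session")
def design_run():
    """Factory: cached simulate + CCF + Gibbs run for one design."""
    return _design_run


@pytest.fixture(scope="session")
def small_two_cluster_run():
    """Two samples, 50 clonal shared SNVs + 50 SNVs at CCF 0.7 unique to
    one sample: the hardest separation claimed for the method."""
    from clonephy.simulate import ClusterSpec, SimulationSpec

    spec = SimulationSpec(
        n_samples=2, coverage_lambda=34.0,
        purity_per_sample=(0.85, 0.8),
        clusters=[
            ClusterSpec("T", 50, (1.0, 1.0)),
            ClusterSpec("S", 50, (0.7, 0.0), parent_id="T"),
        ],
        seed=42)
    reads, truth = simulate_reads(spec)
    ccf = compute_ccf_matrix(reads, simulated_segments(spec),
                             simulated_purities(spec))
    res = DirichletProcessMixture(reads, ccf, ClusterConfig(seed=5)).fit()
    return {"spec": spec, "reads": reads, "truth": truth, "ccf": ccf,
            "results": res}


def truth_ccf_matrix(truth: pd.DataFrame, samples) -> dict:
    """cluster_id -> true per-sample CCF vector."""
    out = {}
    for cl, sub in truth.groupby("cluster_id"):
        out[cl] = np.array([sub[f"ccf_{s}"].iloc[0] for s in samples])
    return out


def match_called_to_truth(cluster_set, truth, samples, tol=0.1):
    """Map each truth cluster to the closest called cluster; return
    {truth_id: (called_id or None, max_abs_error)}."""
    truth_loc = truth_ccf_matrix(truth, samples)
    out = {}
    for tid, tv in truth_loc.items():
        best, best_err = None, np.inf
        for cid in cluster_set.cluster_ids:
            err = np.max(np.abs(cluster_set.location_of(cid) - tv))
            if err < best_err:
                best, best_err = cid, err
        out[tid] = (best if best_err <= tol else None, best_err)
    return out
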