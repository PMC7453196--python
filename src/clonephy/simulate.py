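"""Read-count simulator for multi-sample tumour sequencing from a known clone tree.

Emulates whole-genome sequencing of several tumour samples that share a clonal
phylogeny: every mutation cluster has a true cancer cell fraction (CCF) per
sample, sequencing depth at each locus is Poisson, and the number of mutant
reads is binomial with a success rate derived from the true CCF, the sample
purity and the local copy number. The six standard designs used to validate
cluster and tree recovery (a truncal-only genome, and a three-bifurcation tree
at five per-branch mutation burdens) are available as presets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClusterSpec",
    "SimulationSpec",
    "expected_vaf",
    "simulate_reads",
    "standard_design",
    "simulated_segments",
    "simulated_purities",
]

#: Poisson mean of the WGS coverage model used by the standard designs.
DEFAULT_COVERAGE_LAMBDA = 34.0

#: Per-sample purity range of the standard designs.
DEFAULT_PURITY_RANGE = (0.70, 0.95)

#: Trunk burden of the standard designs (SNVs carried by every tumour cell).
DEFAULT_TRUNK_SNVS = 100_000

#: Per-branch burdens of designs 2..6.
BRANCH_BURDENS = (50, 100, 150, 200, 500)


@dataclass
class ClusterSpec:
    """One mutation cluster of the generating clone tree.

    ``ccf_per_sample`` gives the true fraction of tumour cells carrying the
    cluster's mutations in each sample. The truncal cluster (``parent_id``
    None) must have CCF 1 everywhere; every child must be dominated by its
    parent in every sample (infinite sites).
    """

    cluster_id: str
    n_snvs: int
    ccf_per_sample: tuple
    parent_id: str | None = None

    def __post_init__(self):
        self.ccf_per_sample = tuple(float(c) for c in self.ccf_per_sample)
        if self.n_snvs < 0:
            raise ValueError(f"cluster {self.cluster_id}: n_snvs must be >= 0")
        if any(c < 0 or c > 1 for c in self.ccf_per_sample):
            raise ValueError(f"cluster {self.cluster_id}: CCFs must lie in [0, 1]")


@dataclass
class SimulationSpec:
    """Full description of a simulated multi-sample experiment."""

    n_samples: int
    coverage_lambda: float
    purity_per_sample: tuple
    clusters: list
    ploidy_normal: int = 2
    ploidy_tumour_locus: int = 2
    multiplicity: int = 1
    seed: int = 0

    def __post_init__(self):
        self.purity_per_sample = tuple(float(p) for p in self.purity_per_sample)
        self.validate()

    def validate(self) -> None:
        if self.coverage_lambda <= 0:
            raise ValueError("coverage_lambda must be > 0")
        if len(self.purity_per_sample) != self.n_samples:
            raise ValueError("one purity per sample required")
        if any(not (0 < p <= 1) for p in self.purity_per_sample):
            raise ValueError("purities must lie in (0, 1]")
        truncal = [c for c in self.clusters if c.parent_id is None]
        if len(truncal) != 1:
            raise ValueError("exactly one truncal (parent-less) cluster required")
        if any(abs(c - 1.0) > 1e-12 for c in truncal[0].ccf_per_sample):
            raise ValueError("truncal cluster must have CCF 1 in every sample")
        by_id = {c.cluster_id: c for c in self.clusters}
        if len(by_id) != len(self.clusters):
            raise ValueError("cluster ids must be unique")
        for c in self.clusters:
            if len(c.ccf_per_sample) != self.n_samples:
                raise ValueError(f"cluster {c.cluster_id}: need one CCF per sample")
            if c.parent_id is not None:
                parent = by_id.get(c.parent_id)
                if parent is None:
                    raise ValueError(f"cluster {c.cluster_id}: unknown parent {c.parent_id}")
                if any(cc > pc + 1e-12 for cc, pc in
                       zip(c.ccf_per_sample, parent.ccf_per_sample)):
                    raise ValueError(
                        f"cluster {c.cluster_id} exceeds parent CCF (infinite sites)")

    @property
    def sample_ids(self) -> list:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def total_snvs(self) -> int:
        return sum(c.n_snvs for c in self.clusters)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["purity_per_sample"] = list(self.purity_per_sample)
        d["clusters"] = [
            {
                "cluster_id": c.cluster_id,
                "n_snvs": c.n_snvs,
                "ccf_per_sample": list(c.ccf_per_sample),
                "parent_id": c.parent_id,
            }
            for c in self.clusters
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        d["clusters"] = [ClusterSpec(**c) for c in d["clusters"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def expected_vaf(ccf, multiplicity, purity, cn_tumour, cn_normal=2):
    """Expected variant allele frequency of a mutation.

    A mutation carried by a fraction ``ccf`` of tumour cells on
    ``multiplicity`` chromosomal copies, in a sample of purity ``purity``
    where the locus has ``cn_tumour`` tumour copies and ``cn_normal`` normal
    copies, is expected at VAF

        m * CCF * rho / (rho * CNt + (1 - rho) * CNn).

    Accepts scalars or broadcastable arrays.
    """
    ccf = np.asarray(ccf, dtype=float)
    m = np.asarray(multiplicity, dtype=float)
    rho = np.asarray(purity, dtype=float)
    denom = rho * np.asarray(cn_tumour, dtype=float) \
        + (1.0 - rho) * np.asarray(cn_normal, dtype=float)
    if np.any(denom <= 0):
        raise ZeroDivisionError("total locus copy number is zero (purity 0 with CNn 0)")
    out = m * ccf * rho / denom
    return float(out) if out.ndim == 0 else out


def standard_design(index: int, *, trunk_snvs: int | None = None,
                    trunk_scale: float = 1.0, n_samples: int = 4,
                    coverage_lambda: float = DEFAULT_COVERAGE_LAMBDA,
                    purity_per_sample=None, seed: int = 2024) -> SimulationSpec:
    """Build one of the six standard validation designs.

    Design 1 is truncal-only: a trunk of 100,000 SNVs at CCF 1 in all four
    samples and no branches. Designs 2..6 add six non-truncal clusters in
    three bifurcations: two mutually exclusive clonal clusters (CCF 1 in
    samples 1-2 / 3-4 respectively), each carrying two second-step subclonal
    branches at mean CCFs 0.7 and 0.3, one per sample. Every branch carries
    the same burden: 50, 100, 150, 200 or 500 SNVs for designs 2..6, giving
    totals from 100,300 to 103,000.

    ``trunk_scale`` (or an explicit ``trunk_snvs``) shrinks the trunk only,
    so branch/trunk proportions can be varied for desk-scale runs while the
    branch structure is preserved. Purities are drawn uniformly in
    [0.70, 0.95] from ``seed`` unless given explicitly.
    """
    if not 1 <= index <= 6:
        raise ValueError(f"design index must be in 1..6, got {index}")
    if n_samples != 4:
        raise ValueError("the standard designs use exactly 4 samples")
    if trunk_snvs is None:
        trunk_snvs = int(round(DEFAULT_TRUNK_SNVS * trunk_scale))
    if purity_per_sample is None:
        rng = np.random.default_rng(seed)
        lo, hi = DEFAULT_PURITY_RANGE
        purity_per_sample = tuple(rng.uniform(lo, hi, size=n_samples))

    clusters = [ClusterSpec("T", trunk_snvs, (1.0, 1.0, 1.0, 1.0))]
    if index >= 2:
        b = BRANCH_BURDENS[index - 2]
        clusters += [
            ClusterSpec("B", b, (1.0, 1.0, 0.0, 0.0), parent_id="T"),
            ClusterSpec("D", b, (0.0, 0.0, 1.0, 1.0), parent_id="T"),
            ClusterSpec("C1", b, (0.7, 0.0, 0.0, 0.0), parent_id="B"),
            ClusterSpec("C2", b, (0.0, 0.3, 0.0, 0.0), parent_id="B"),
            ClusterSpec("C3", b, (0.0, 0.0, 0.7, 0.0), parent_id="D"),
            ClusterSpec("C4", b, (0.0, 0.0, 0.0, 0.3), parent_id="D"),
        ]
    return SimulationSpec(
        n_samples=n_samples,
        coverage_lambda=coverage_lambda,
        purity_per_sample=purity_per_sample,
        clusters=clusters,
        seed=seed,
    )


def simulate_reads(spec: SimulationSpec):
    """Draw read counts for every SNV in every sample.

    Depth at each SNV x sample cell is Poisson(``coverage_lambda``); the
    mutant read count is Binomial(depth, expected_vaf(true CCF, m, purity,
    CNt, CNn)). Deterministic given ``spec.seed``.

    Returns ``(reads, truth)`` where ``reads`` is a
    :class:`clonephy.io.SnvReadTable` and ``truth`` a DataFrame indexed by
    snv_id with the generating cluster, multiplicity, locus copy number and
    true per-sample CCF.
    """
    from .io import SnvReadTable

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    samples = spec.sample_ids
    n = spec.total_snvs

    cluster_of = np.concatenate([
        np.repeat(c.cluster_id, c.n_snvs) for c in spec.clusters
    ]) if n else np.array([], dtype=object)
    ccf_true = np.concatenate([
        np.tile(c.ccf_per_sample, (c.n_snvs, 1)) for c in spec.clusters
    ]) if n else np.empty((0, spec.n_samples))

    rho = np.asarray(spec.purity_per_sample)
    p = expected_vaf(ccf_true, spec.multiplicity, rho[None, :],
                     spec.ploidy_tumour_locus, spec.ploidy_normal)
    depth = rng.poisson(spec.coverage_lambda, size=(n, spec.n_samples))
    alt = rng.binomial(depth, p)

    snv_ids = np.array([f"snv{i:07d}" for i in range(n)], dtype=object)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            # synthetic coordinates: 1-based, evenly spaced
            "pos": np.arange(1, n + 1, dtype=np.int64) * 100,
            "ref": "A",
            "alt": "T",
        },
        index=pd.Index(snv_ids, name="snv_id"),
    )
    reads = SnvReadTable(
        variants=variants,
        alt=pd.DataFrame(alt, index=variants.index, columns=samples),
        depth=pd.DataFrame(depth, index=variants.index, columns=samples),
    )

    truth = pd.DataFrame(
        {
            "cluster_id": cluster_of,
            "multiplicity": spec.multiplicity,
            "cn_tumour": spec.ploidy_tumour_locus,
        },
        index=variants.index,
    )
    for j, s in enumerate(samples):
        truth[f"ccf_{s}"] = ccf_true[:, j]
    return reads, truth


def simulated_segments(spec: SimulationSpec) -> pd.DataFrame:
    """Copy-number segment table matching a simulation: one diploid
    (major 1, minor 1) segment per sample spanning all simulated loci."""
    end = spec.total_snvs * 100 + 100
    return pd.DataFrame([
        {"sample": s, "chrom": "1", "start": 0, "end": end,
         "major_cn": spec.ploidy_tumour_locus - 1, "minor_cn": 1}
        for s in spec.sample_ids
    ])


def simulated_purities(spec: SimulationSpec) -> pd.DataFrame:
    """Purity table matching a simulation spec."""
    return pd.DataFrame({"sample": spec.sample_ids,
                         "purity": list(spec.purity_per_sample),
                         "ploidy": float(spec.ploidy_tumour_locus)})
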