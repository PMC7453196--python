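"""Multidimensional Dirichlet-process mixture clustering of SNVs.

SNVs are clustered by their cancer cell fraction jointly across all samples
of a patient. The model is a truncated stick-breaking Dirichlet-process
mixture: each component k has a CCF location c_ks per sample s, and the
likelihood of SNV i under component k is the product over samples of

    Binomial(alt_is | depth_is, c_ks * f_is)

where f_is is the VAF expected for a fully clonal mutation given the SNV's
multiplicity, the sample purity and the local copy number. Working on raw
read counts (rather than Gaussian noise on CCF point estimates) weights each
SNV by its sequencing depth; CCF point estimates are used only to initialise
the sampler and to report results.

Inference is Gibbs sampling: component assignments are drawn from their
categorical conditionals, stick weights from their Beta conditionals, the
concentration alpha from its Gamma conditional, and component locations from
their conditional posterior discretised on a fine grid over [0, 1.2] (the
uniform location prior allows mild super-clonal mass; summaries cap at 1).

Usage follows the model/results convention::

    model = DirichletProcessMixture(reads, ccf, ClusterConfig(seed=1))
    res = model.fit()
    clusters = res.cluster_set          # called, merged, annotated clusters
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy, xlog1py

from .ccf import CcfMatrix
from .io import SnvReadTable

__all__ = [
    "ClusterConfig",
    "PosteriorTrace",
    "ClusterSet",
    "DirichletProcessMixture",
    "DPMixtureResults",
    "call_clusters",
    "filter_small_clusters",
    "annotate_clonality",
]

_LOC_GRID = np.round(np.arange(0, 1.2 + 1e-9, 0.005), 10)
_PMIN, _PMAX = 1e-12, 1 - 1e-9


@dataclass
class ClusterConfig:
    """Sampler and cluster-calling settings.

    Defaults: 2,000 sweeps with 1,000 burn-in and thinning 10; truncation at
    30 components; concentration alpha ~ Gamma(1, 1) resampled every sweep;
    components merged when within ``merge_tol`` CCF in every sample;
    clusters below ``min_fraction`` of clustered SNVs dropped; a cluster is
    clonal in a sample when within ``clonal_tol`` of CCF 1 and absent below
    ``absence_tol``.
    """

    n_iterations: int = 2000
    burn_in: int = 1000
    thin: int = 10
    truncation: int = 30
    alpha_shape: float = 1.0
    alpha_rate: float = 1.0
    seed: int = 0
    merge_tol: float = 0.05
    min_fraction: float = 0.01
    clonal_tol: float = 0.1
    absence_tol: float = 0.05
    init_clusters: int = 10

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.truncation < 2:
            raise ValueError("truncation must be >= 2")
        if not 0 <= self.min_fraction < 1:
            raise ValueError("min_fraction must lie in [0, 1)")


@dataclass
class PosteriorTrace:
    """Retained Gibbs samples.

    ``locations``: (n_kept, K, S) CCF locations; ``assignments``:
    (n_kept, n_snv) component indices; ``counts``: (n_kept, K) occupancy;
    ``log_joint``: per-iteration joint log density (up to constants);
    ``assign_prob``: (n_snv, K) posterior component-membership frequencies.
    """

    locations: np.ndarray
    assignments: np.ndarray
    counts: np.ndarray
    alpha: np.ndarray
    log_joint: np.ndarray
    assign_prob: np.ndarray
    snv_ids: pd.Index
    samples: list

    @property
    def n_kept(self) -> int:
        return len(self.log_joint)


@dataclass
class ClusterSet:
    """Called mutation clusters.

    ``clusters``: DataFrame indexed by cluster_id with per-sample location
    columns ``ccf_<sample>``, ``n_snvs``, per-sample clonality columns
    ``clonality_<sample>`` (clonal/subclonal/absent, once annotated) and a
    boolean ``truncal`` column. ``assignments``: Series snv_id -> cluster_id
    (NaN = unassigned).
    """

    clusters: pd.DataFrame
    assignments: pd.Series
    samples: list

    @property
    def cluster_ids(self) -> list:
        return list(self.clusters.index)

    def locations(self) -> pd.DataFrame:
        return self.clusters[[f"ccf_{s}" for s in self.samples]]

    def location_of(self, cluster_id) -> np.ndarray:
        return self.clusters.loc[cluster_id,
                                 [f"ccf_{s}" for s in self.samples]].to_numpy(float)

    @property
    def truncal_id(self):
        t = self.clusters.index[self.clusters["truncal"]]
        return t[0] if len(t) else None


class _Likelihood:
    """Grouped binomial likelihood machinery shared by the sampler and the
    post-hoc location refits.

    Cells are grouped per sample by their clonal-VAF scale factor f so the
    log1p(-c f) terms reduce to a small number of sufficient statistics;
    missing cells enter with alt = depth = 0 and contribute nothing.
    """

    def __init__(self, alt, depth, f):
        self.n, self.S = alt.shape
        self.A = np.ascontiguousarray(alt, dtype=float)
        self.D = np.ascontiguousarray(depth, dtype=float)
        self.Dma = self.D - self.A
        self.f = f
        self.f_uniq, self.gidx = [], []
        for s in range(self.S):
            u, g = np.unique(np.round(f[:, s], 12), return_inverse=True)
            self.f_uniq.append(u)
            self.gidx.append(g)
        # constants of the binomial pmf and the a*log(f) terms (component
        # independent; included so log_joint is comparable across sweeps)
        with np.errstate(divide="ignore", invalid="ignore"):
            logf = np.where(self.f > 0, np.log(np.maximum(self.f, _PMIN)), 0.0)
        self.const = float(
            (gammaln(self.D + 1) - gammaln(self.A + 1) - gammaln(self.Dma + 1)).sum()
            + (self.A * logf).sum())

    def loglik_matrix(self, C):
        """(n, K) log likelihood of every SNV under every component, up to
        per-SNV constants."""
        logC = np.log(np.clip(C, _PMIN, None))
        L = self.A @ logC.T
        for s in range(self.S):
            p = np.clip(np.outer(C[:, s], self.f_uniq[s]), 0.0, _PMAX)
            T = np.log1p(-p)  # (K, U_s)
            L += self.Dma[:, s, None] * T[:, self.gidx[s]].T
        return L

    def location_logpost(self, z, K, grid):
        """(K, S, G) conditional log posterior of each component location on
        ``grid``, given assignments z (uniform prior: likelihood only)."""
        G = len(grid)
        gclip = np.clip(grid, _PMIN, None)
        out = np.empty((K, self.S, G))
        for s in range(self.S):
            U = len(self.f_uniq[s])
            SA = np.bincount(z, weights=self.A[:, s], minlength=K)
            DG = np.bincount(z * U + self.gidx[s], weights=self.Dma[:, s],
                             minlength=K * U).reshape(K, U)
            T2 = np.log1p(-np.clip(self.f_uniq[s][:, None] * grid[None, :],
                                   0.0, _PMAX))  # (U, G)
            out[:, s, :] = SA[:, None] * np.log(gclip)[None, :] + DG @ T2
        return out


class DirichletProcessMixture:
    """Truncated Dirichlet-process mixture over per-sample CCFs.

    Parameters
    ----------
    reads : SnvReadTable
        Raw per-sample read counts (the likelihood's evidence).
    ccf : CcfMatrix
        CCF context: multiplicities, clonal-VAF scale factors and flags.
        SNVs flagged implausible are excluded; missing cells are ignored.
    config : ClusterConfig, optional
    """

    def __init__(self, reads: SnvReadTable, ccf: CcfMatrix,
                 config: ClusterConfig | None = None):
        self.config = config or ClusterConfig()
        self.samples = list(ccf.samples)
        usable = ccf.usable_snvs()
        if len(usable) < 2:
            raise ValueError("need at least 2 usable SNVs to cluster")
        self.snv_ids = usable
        self.all_snv_ids = ccf.snv_ids
        alt = reads.alt.loc[usable, self.samples].to_numpy(float)
        depth = reads.depth.loc[usable, self.samples].to_numpy(float)
        f = ccf.clonal_vaf.loc[usable, self.samples].to_numpy(float)
        missing = ccf.missing.loc[usable, self.samples].to_numpy(bool)
        bad = ~np.isfinite(f) | missing | (depth <= 0)
        alt = np.where(bad, 0.0, alt)
        depth = np.where(bad, 0.0, depth)
        f = np.where(bad, 0.5, f)
        if not (np.isfinite(alt).all() and np.isfinite(depth).all()):
            raise ValueError("non-finite read counts in input")
        self._lik = _Likelihood(alt, depth, f)
        self._ccf_points = np.nan_to_num(
            np.clip(ccf.ccf.loc[usable, self.samples].to_numpy(float), 0, 1.2),
            nan=0.0)

    # -- initial state -----------------------------------------------------

    def _init_assignments(self, rng):
        from sklearn.cluster import KMeans

        n = self._lik.n
        k = int(min(self.config.init_clusters, n))
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        return km.fit_predict(self._ccf_points)

    # -- sampling ----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "DPMixtureResults":
        """Run the Gibbs sampler and return results. Deterministic given the
        seed (``config.seed`` unless overridden here)."""
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        rng = np.random.default_rng(cfg.seed)
        lik, K, S, n = self._lik, cfg.truncation, self._lik.S, self._lik.n
        grid = _LOC_GRID

        z = self._init_assignments(rng)
        alpha = 1.0
        C = np.empty((K, S))
        # ML locations for initial clusters, prior draws for the rest
        lp = lik.location_logpost(z, K, grid)
        counts = np.bincount(z, minlength=K)
        for k in range(K):
            if counts[k] > 0:
                C[k] = grid[np.argmax(lp[k], axis=1)]
            else:
                C[k] = rng.choice(grid, size=S)

        kept = range(cfg.burn_in, cfg.n_iterations, cfg.thin)
        n_kept = len(list(kept))
        trace_loc = np.empty((n_kept, K, S))
        trace_z = np.empty((n_kept, n), dtype=np.int32)
        trace_counts = np.empty((n_kept, K), dtype=np.int64)
        trace_alpha = np.empty(n_kept)
        trace_lj = np.empty(n_kept)
        assign_freq = np.zeros((n, K))
        t = 0

        logpi = np.full(K, -np.log(K))
        for sweep in range(cfg.n_iterations):
            # 1. assignments
            L = lik.loglik_matrix(C)
            G = L + logpi[None, :]
            z = np.argmax(G + rng.gumbel(size=(n, K)), axis=1)
            counts = np.bincount(z, minlength=K)

            # 2. stick-breaking weights and concentration
            tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
            v = rng.beta(1.0 + counts, alpha + tail)
            v[-1] = 1.0
            v = np.clip(v, 1e-12, 1 - 1e-12)
            log1mv = np.log1p(-v)
            logpi = np.log(v) + np.concatenate([[0.0], np.cumsum(log1mv[:-1])])
            alpha = rng.gamma(cfg.alpha_shape + K - 1,
                              1.0 / (cfg.alpha_rate - log1mv[:-1].sum()))

            # 3. component locations (grid Gibbs; empty components draw from
            # the uniform prior automatically since their stats are zero)
            lp = lik.location_logpost(z, K, grid)
            lp -= lp.max(axis=2, keepdims=True)
            w = np.exp(lp)
            cum = np.cumsum(w, axis=2)
            r = rng.random((K, S)) * cum[:, :, -1]
            idx = (cum < r[:, :, None]).sum(axis=2)
            C = grid[np.clip(idx, 0, len(grid) - 1)]

            if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
                trace_loc[t] = C
                trace_z[t] = z
                trace_counts[t] = counts
                trace_alpha[t] = alpha
                trace_lj[t] = L[np.arange(n), z].sum() + (counts * logpi).sum() \
                    + lik.const
                assign_freq[np.arange(n), z] += 1
                t += 1

        assign_prob = assign_freq / max(t, 1)
        trace = PosteriorTrace(
            locations=trace_loc, assignments=trace_z, counts=trace_counts,
            alpha=trace_alpha, log_joint=trace_lj, assign_prob=assign_prob,
            snv_ids=self.snv_ids, samples=self.samples)
        return DPMixtureResults(self, trace, cfg)


class DPMixtureResults:
    """Fitted mixture: posterior trace plus cluster calling and summaries."""

    def __init__(self, model: DirichletProcessMixture, trace: PosteriorTrace,
                 config: ClusterConfig):
        self.model = model
        self.trace = trace
        self.config = config
        self._called = None
        self._cluster_set = None

    @property
    def called_cluster_set(self) -> ClusterSet:
        """All called clusters (clonality-annotated, before the minimum
        cluster-size filter)."""
        if self._called is None:
            cs = call_clusters(self.trace, self.config, self.model)
            self._called = annotate_clonality(
                cs, self.config.clonal_tol, self.config.absence_tol)
        return self._called

    @property
    def cluster_set(self) -> ClusterSet:
        """Called, size-filtered, clonality-annotated clusters (cached)."""
        if self._cluster_set is None:
            cs = filter_small_clusters(self.called_cluster_set,
                                       self.config.min_fraction)
            self._cluster_set = annotate_clonality(
                cs, self.config.clonal_tol, self.config.absence_tol)
        return self._cluster_set

    def summary(self) -> str:
        cs = self.cluster_set
        lines = [
            "Dirichlet-process mixture of per-sample CCFs",
            f"  SNVs clustered: {len(self.trace.snv_ids)}   samples: {len(self.trace.samples)}",
            f"  sweeps: {self.config.n_iterations} (burn-in {self.config.burn_in}, "
            f"thin {self.config.thin}, {self.trace.n_kept} retained)",
            f"  mean concentration alpha: {self.trace.alpha.mean():.3f}",
            f"  clusters called: {len(cs.clusters)}",
            "",
            cs.clusters.to_string(),
        ]
        return "\n".join(lines)


# -- cluster calling -------------------------------------------------------

def _refit_locations(model, z, K):
    """Maximum-likelihood component locations on a fine grid given
    assignments — the peak of each component's posterior mutation density."""
    lp = model._lik.location_logpost(z, K, _LOC_GRID)
    return _LOC_GRID[np.argmax(lp, axis=2)]


def call_clusters(trace: PosteriorTrace, config: ClusterConfig,
                  model: DirichletProcessMixture) -> ClusterSet:
    """Summarise the posterior into discrete clusters.

    The retained iteration with the highest joint posterior fixes the
    component structure; each occupied component's location is then refined
    to the peak of its conditional posterior density given that assignment.
    Components whose locations agree within ``merge_tol`` in every sample
    are merged, every SNV is reassigned to its maximum-posterior cluster,
    and empty clusters are dropped.
    """
    if trace.n_kept < 1:
        raise ValueError("empty posterior trace")
    S = len(trace.samples)
    best = int(np.argmax(trace.log_joint))
    z = trace.assignments[best].astype(np.int64).copy()
    K = trace.locations.shape[1]
    C = _refit_locations(model, z, K)
    occupied = np.flatnonzero(np.bincount(z, minlength=K) > 0)

    # merge components whose locations coincide within tolerance everywhere
    parent = {k: k for k in occupied}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, a in enumerate(occupied):
        for b in occupied[i + 1:]:
            if np.all(np.abs(C[a] - C[b]) <= config.merge_tol):
                parent[find(b)] = find(a)
    for k in occupied:
        z[z == k] = find(k)
    occupied = np.unique([find(k) for k in occupied])
    C = _refit_locations(model, z, K)

    # maximum-posterior reassignment over the called clusters
    counts = np.bincount(z, minlength=K).astype(float)
    L = model._lik.loglik_matrix(C[occupied])
    logw = np.log(np.maximum(counts[occupied], 0.5) / counts.sum())
    z = occupied[np.argmax(L + logw[None, :], axis=1)]
    occupied = np.unique(z)
    C = _refit_locations(model, z, K)

    order = np.argsort(-np.bincount(z, minlength=K)[occupied])
    occupied = occupied[order]
    ids = [f"C{i + 1}" for i in range(len(occupied))]
    remap = {k: cid for k, cid in zip(occupied, ids)}

    rows = {}
    for k, cid in remap.items():
        loc = np.clip(C[k], 0.0, 1.0)  # summaries cap super-clonal mass
        rows[cid] = {"n_snvs": int((z == k).sum()),
                     **{f"ccf_{s}": loc[j] for j, s in enumerate(trace.samples)}}
    clusters = pd.DataFrame.from_dict(rows, orient="index")
    clusters.index.name = "cluster_id"

    assignments = pd.Series([remap[k] for k in z], index=trace.snv_ids,
                            name="cluster_id", dtype=object)
    # SNVs excluded from clustering (implausible CCF) stay unassigned
    if model is not None and len(model.all_snv_ids) > len(trace.snv_ids):
        assignments = assignments.reindex(model.all_snv_ids)
    return ClusterSet(clusters=clusters, assignments=assignments,
                      samples=list(trace.samples))


def filter_small_clusters(cluster_set: ClusterSet,
                          min_fraction: float) -> ClusterSet:
    """Drop clusters holding fewer than ``min_fraction`` of the clustered
    SNVs (inclusive threshold: exactly the fraction is retained); their SNVs
    become unassigned."""
    if not 0 <= min_fraction < 1:
        raise ValueError("min_fraction must lie in [0, 1)")
    total = cluster_set.clusters["n_snvs"].sum()
    if total == 0:
        return cluster_set
    keep = cluster_set.clusters["n_snvs"] / total >= min_fraction
    clusters = cluster_set.clusters[keep]
    assignments = cluster_set.assignments.where(
        cluster_set.assignments.isin(clusters.index))
    return ClusterSet(clusters=clusters, assignments=assignments,
                      samples=cluster_set.samples)


def annotate_clonality(cluster_set: ClusterSet, clonal_tol: float = 0.1,
                       absence_tol: float = 0.05) -> ClusterSet:
    """Label each cluster per sample as clonal (CCF within ``clonal_tol`` of
    1), absent (CCF <= ``absence_tol``) or subclonal; flag as truncal the
    cluster that is clonal in every sample (the largest, if several)."""
    clusters = cluster_set.clusters.copy()
    loc = clusters[[f"ccf_{s}" for s in cluster_set.samples]].to_numpy(float)
    lab = np.where(np.abs(loc - 1.0) <= clonal_tol, "clonal",
                   np.where(loc <= absence_tol, "absent", "subclonal"))
    for j, s in enumerate(cluster_set.samples):
        clusters[f"clonality_{s}"] = lab[:, j]
    all_clonal = (lab == "clonal").all(axis=1)
    truncal = np.zeros(len(clusters), dtype=bool)
    if all_clonal.any():
        cand = np.flatnonzero(all_clonal)
        truncal[cand[np.argmax(clusters["n_snvs"].to_numpy()[cand])]] = True
    clusters["truncal"] = truncal
    return ClusterSet(clusters=clusters, assignments=cluster_set.assignments,
                      samples=cluster_set.samples)
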