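"""Cancer cell fraction (CCF) estimation from read counts, purity and copy number.

The CCF of an SNV is the fraction of tumour cells that carry it. It is
obtained from the variant allele frequency (VAF) in two steps: first the
mutation copy number

    n_mut = VAF * (rho * CNt + (1 - rho) * CNn) / rho

(the product of CCF and the number of mutated chromosomal copies), then
division by the multiplicity m, the number of copies carrying the SNV,
chosen by binomial maximum likelihood over m = 1..major_cn. For targeted
data without copy-number calls, purity can be estimated as twice the VAF of
the clonal peak of the VAF density, and CCFs computed under an assumed
diploid genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy, xlog1py

from .io import SnvReadTable
from .simulate import expected_vaf

__all__ = [
    "CcfMatrix",
    "mutation_copy_number",
    "assign_multiplicity",
    "compute_ccf_matrix",
    "estimate_purity_from_vaf_peak",
    "ccf_assuming_diploid",
]

#: CCF estimates in (1, CAP_MAX] are clipped to 1 (binomial noise around a
#: clonal mutation); estimates above CAP_MAX are flagged implausible and
#: excluded from clustering.
CAP_MAX = 1.5

#: Depth below which a cell is flagged low-depth (still used in likelihoods).
LOW_DEPTH = 10

CN_NORMAL = 2


@dataclass
class CcfMatrix:
    """Per-SNV, per-sample CCF estimates with their copy-number context.

    All fields are DataFrames indexed by snv_id with one column per sample.
    ``ccf`` is capped at 1; ``ccf_raw`` is the uncapped estimate n_mut / m.
    ``clonal_vaf`` is the VAF expected if the SNV were fully clonal given its
    assigned multiplicity — the per-cell scale factor linking CCF to VAF,
    used by the clustering likelihood. Flag frames: ``missing`` (no CCF:
    depth 0 or no covering copy-number segment), ``low_depth``, ``capped``,
    ``implausible`` (raw CCF > 1.5, excluded from clustering).
    """

    vaf: pd.DataFrame
    ccf: pd.DataFrame
    ccf_raw: pd.DataFrame
    multiplicity: pd.DataFrame
    n_mut: pd.DataFrame
    cn_total: pd.DataFrame
    cn_major: pd.DataFrame
    cn_minor: pd.DataFrame
    clonal_vaf: pd.DataFrame
    missing: pd.DataFrame
    low_depth: pd.DataFrame
    capped: pd.DataFrame
    implausible: pd.DataFrame
    purity: dict = field(default_factory=dict)

    @property
    def samples(self) -> list:
        return list(self.ccf.columns)

    @property
    def snv_ids(self) -> pd.Index:
        return self.ccf.index

    def usable_snvs(self) -> pd.Index:
        """SNVs eligible for clustering: no implausible cell, and at least
        one sample with an estimate."""
        ok = ~self.implausible.any(axis=1) & ~self.missing.all(axis=1)
        return self.ccf.index[ok]

    def subset(self, snv_ids) -> "CcfMatrix":
        kw = {f.name: getattr(self, f.name).loc[snv_ids]
              for f in self.__dataclass_fields__.values() if f.name != "purity"}
        return CcfMatrix(**kw, purity=dict(self.purity))


def mutation_copy_number(vaf, purity, cn_tumour, cn_normal=CN_NORMAL):
    """Mutation copy number: VAF rescaled to copies per tumour cell.

    Inverse of ``expected_vaf`` times multiplicity: equals CCF * m.
    """
    rho = np.asarray(purity, dtype=float)
    if np.any(rho <= 0):
        raise ValueError("purity must be > 0")
    v = np.asarray(vaf, dtype=float)
    out = v * (rho * np.asarray(cn_tumour, float)
               + (1.0 - rho) * np.asarray(cn_normal, float)) / rho
    return float(out) if out.ndim == 0 else out


def _multiplicity_ll(alt, depth, purity, cn_tumour, m):
    p = expected_vaf(1.0, m, purity, cn_tumour, CN_NORMAL)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return xlogy(alt, p) + xlog1py(depth - alt, -p)


def assign_multiplicity(alt, depth, purity, cn_tumour, cn_major):
    """Choose the SNV multiplicity by binomial maximum likelihood.

    Evaluates Binomial(alt | depth, expected_vaf(1, m, rho, CNt)) for every
    m in 1..cn_major and returns ``(m, ccf)`` with the capped CCF
    n_mut / m. Raises on depth 0 (no evidence).
    """
    if depth <= 0:
        raise ValueError("depth must be > 0 to assign multiplicity")
    if cn_major < 1:
        raise ValueError("cn_major must be >= 1")
    ms = np.arange(1, int(cn_major) + 1)
    ll = _multiplicity_ll(float(alt), float(depth), purity, cn_tumour, ms)
    m = int(ms[np.argmax(ll)])
    raw = mutation_copy_number(alt / depth, purity, cn_tumour) / m
    return m, float(min(raw, 1.0))


def _lookup_segments(segments: pd.DataFrame, sample: str,
                     chrom: np.ndarray, pos: np.ndarray):
    """Map 1-based SNV positions onto 0-based half-open segments.

    Returns (major, minor) int arrays with -1 where no segment covers.
    """
    n = len(pos)
    major = np.full(n, -1, dtype=np.int64)
    minor = np.full(n, -1, dtype=np.int64)
    seg = segments[segments["sample"] == sample]
    for ch, sub in seg.groupby("chrom"):
        sel = np.flatnonzero(chrom == ch)
        if sel.size == 0:
            continue
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        p0 = pos[sel] - 1  # to 0-based
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        hit = sel[ok]
        major[hit] = sub["major_cn"].to_numpy()[idx[ok]]
        minor[hit] = sub["minor_cn"].to_numpy()[idx[ok]]
    return major, minor


def _fill_sample(alt, depth, rho, cn_total, cn_major):
    """Vectorised multiplicity + CCF for one sample. Inputs are arrays;
    cells with cn_major < 1 or depth 0 are left as NaN/missing."""
    n = len(alt)
    ok = (depth > 0) & (cn_major >= 1)
    m = np.full(n, 0, dtype=np.int64)
    if ok.any():
        mmax = int(cn_major[ok].max())
        lls = np.full((n, mmax), -np.inf)
        for k in range(1, mmax + 1):
            valid = ok & (cn_major >= k)
            lls[valid, k - 1] = _multiplicity_ll(
                alt[valid].astype(float), depth[valid].astype(float),
                rho, cn_total[valid].astype(float), k)
        m[ok] = np.argmax(lls[ok], axis=1) + 1
    vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    n_mut = np.where(ok, mutation_copy_number(np.nan_to_num(vaf), rho,
                                              cn_total, CN_NORMAL), np.nan)
    raw = np.where(ok, n_mut / np.maximum(m, 1), np.nan)
    return m, vaf, n_mut, raw, ok


def compute_ccf_matrix(reads: SnvReadTable, segments: pd.DataFrame,
                       purities: pd.DataFrame) -> CcfMatrix:
    """Estimate per-SNV, per-sample CCFs with copy-number and purity context.

    Each cell looks up its sample's covering segment, assigns multiplicity by
    binomial maximum likelihood (m = 1..major_cn) and returns CCF = n_mut/m.
    Cells without a covering segment or without reads are flagged missing;
    raw CCFs in (1, 1.5] are capped at 1, above 1.5 flagged implausible.
    """
    samples = reads.samples
    rho_map = dict(zip(purities["sample"], purities["purity"]))
    unknown = [s for s in samples if s not in rho_map]
    if unknown:
        raise ValueError(f"no purity supplied for sample(s) {unknown}")

    idx = reads.variants.index
    chrom = reads.variants["chrom"].to_numpy()
    pos = reads.variants["pos"].to_numpy()
    cols = {name: {} for name in
            ("vaf", "ccf", "ccf_raw", "multiplicity", "n_mut", "cn_total",
             "cn_major", "cn_minor", "clonal_vaf", "missing", "low_depth",
             "capped", "implausible")}

    for s in samples:
        alt = reads.alt[s].to_numpy()
        depth = reads.depth[s].to_numpy()
        rho = rho_map[s]
        major, minor = _lookup_segments(segments, s, chrom, pos)
        covered = major >= 0
        cn_total = np.where(covered, major + np.maximum(minor, 0), -1)
        m, vaf, n_mut, raw, ok = _fill_sample(alt, depth, rho, cn_total, major)
        capped = ok & (raw > 1.0) & (raw <= CAP_MAX)
        implaus = ok & (raw > CAP_MAX)
        ccf = np.where(ok, np.minimum(raw, 1.0), np.nan)
        f = np.where(ok, expected_vaf(1.0, np.maximum(m, 1), rho,
                                      np.maximum(cn_total, 1), CN_NORMAL), np.nan)
        cols["vaf"][s] = vaf
        cols["ccf"][s] = ccf
        cols["ccf_raw"][s] = raw
        cols["multiplicity"][s] = m
        cols["n_mut"][s] = n_mut
        cols["cn_total"][s] = cn_total
        cols["cn_major"][s] = major
        cols["cn_minor"][s] = minor
        cols["clonal_vaf"][s] = f
        cols["missing"][s] = ~ok
        cols["low_depth"][s] = depth < LOW_DEPTH
        cols["capped"][s] = capped
        cols["implausible"][s] = implaus

    frames = {k: pd.DataFrame(v, index=idx) for k, v in cols.items()}
    return CcfMatrix(**frames, purity=dict(rho_map))


def ccf_assuming_diploid(reads: SnvReadTable, purity) -> CcfMatrix:
    """CCFs under an assumed fully diploid genome (CNt = CNn = 2, m = 1).

    Used for targeted sequencing without copy-number calls, restricted
    beforehand to loci known to be diploid. ``purity`` is a scalar applied
    to all samples, or a mapping sample -> purity.
    """
    samples = reads.samples
    if np.isscalar(purity):
        purities = pd.DataFrame({"sample": samples,
                                 "purity": [float(purity)] * len(samples)})
    else:
        purities = pd.DataFrame({"sample": list(purity.keys()),
                                 "purity": list(purity.values())})
    # one whole-genome diploid segment per sample and chromosome
    chroms = reads.variants["chrom"].unique()
    maxpos = int(reads.variants["pos"].max()) if len(reads.variants) else 1
    segs = pd.DataFrame([
        {"sample": s, "chrom": c, "start": 0, "end": maxpos + 1,
         "major_cn": 1, "minor_cn": 1}
        for s in samples for c in chroms
    ])
    return compute_ccf_matrix(reads, segs, purities)


def estimate_purity_from_vaf_peak(vafs, min_snvs: int = 10,
                                  grid_size: int = 512):
    """Estimate tumour purity from the clonal peak of a VAF density.

    A Gaussian kernel density (Silverman bandwidth) is fitted to the VAFs on
    a grid over [0, 1]; among strict local maxima the one at the highest VAF
    is taken as the clonal peak and purity = min(1, 2 * peak VAF).
    """
    v = np.asarray(list(vafs), dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < min_snvs:
        raise ValueError(f"need at least {min_snvs} VAF values, got {len(v)}")
    if np.allclose(v, 0):
        raise ValueError("degenerate VAF distribution (all zero)")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] > dens[:-2]) & (dens[1:-1] > dens[2:])) + 1
    # ignore negligible wiggles in the KDE tail
    interior = interior[dens[interior] >= 0.05 * dens.max()]
    if interior.size == 0:
        peak = grid[np.argmax(dens)]
    else:
        peak = grid[interior.max()]
    return float(min(1.0, 2.0 * peak))
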