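"""Pseudo-heterogeneity filtering.

Apparent inter-sample heterogeneity of an SNV can be an artefact of copy
number: a sample that has lost the mutated allele (LOH, or any copy-number
decrease at the locus) will show VAF ~ 0 even if every tumour cell of that
sample descends from a mutated ancestor. Before clustering, SNVs are removed
when (a) the allele-specific copy-number state at their locus differs across
samples, or (b) their apparent absence in a sample is explainable by allele
loss in that sample. Removing these is essential: they would otherwise seed
spurious "subclonal" clusters shared only by CN-concordant samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ccf import CcfMatrix
from .io import SnvReadTable

__all__ = [
    "cna_consistent_loci",
    "filter_pseudo_heterogeneity",
    "apply_heterogeneity_filters",
]

#: An SNV is "absent" in a sample when its CCF is below this and it has at
#: most ABSENT_MAX_ALT supporting reads (joint condition resists depth noise).
ABSENT_CCF = 0.05
ABSENT_MAX_ALT = 1

REASON_DISCORDANT = "cna-discordant"
REASON_LOH = "loh-explains-loss"
REASON_AMBIGUOUS = "ambiguous-cn"


def cna_consistent_loci(ccf: CcfMatrix) -> pd.Series:
    """Boolean mask: SNVs whose (major, minor) copy-number state is identical
    across all samples. SNVs uncovered by a segment in any sample are False."""
    major = ccf.cn_major.to_numpy()
    minor = ccf.cn_minor.to_numpy()
    covered = (major >= 0).all(axis=1)
    same_major = (major == major[:, :1]).all(axis=1)
    same_minor = (minor == minor[:, :1]).all(axis=1)
    return pd.Series(covered & same_major & same_minor, index=ccf.snv_ids)


def _absence(ccf: CcfMatrix, reads: SnvReadTable) -> np.ndarray:
    est = ccf.ccf.to_numpy()
    alt = reads.alt.loc[ccf.snv_ids].to_numpy()
    with np.errstate(invalid="ignore"):
        absent = (np.nan_to_num(est, nan=0.0) < ABSENT_CCF) & (alt <= ABSENT_MAX_ALT)
    return absent


def filter_pseudo_heterogeneity(ccf: CcfMatrix, reads: SnvReadTable):
    """Remove SNVs whose per-sample absence is explainable by allele loss.

    An SNV apparently absent in sample s is removed when s shows LOH
    (minor_cn = 0 while every SNV-bearing sample retains both alleles) or a
    lower total copy number than every SNV-bearing sample at that locus —
    the conservative reading of "copy number could explain the loss".

    Returns ``(kept CcfMatrix, report)`` where the report lists every input
    SNV with kept/removed status and a reason code.
    """
    major = ccf.cn_major.to_numpy()
    minor = ccf.cn_minor.to_numpy()
    total = ccf.cn_total.to_numpy()
    absent = _absence(ccf, reads)
    present = ~absent & ~ccf.missing.to_numpy()

    n = len(ccf.snv_ids)
    removed = np.zeros(n, dtype=bool)
    reasons = np.full(n, "", dtype=object)

    has_both = present.any(axis=1) & absent.any(axis=1)
    for i in np.flatnonzero(has_both):
        pres = present[i]
        abst = absent[i] & (major[i] >= 0)
        if not abst.any():
            continue
        min_total_present = total[i][pres].min()
        all_present_retain_minor = (minor[i][pres] > 0).all()
        loss = (total[i][abst] < min_total_present) | \
               ((minor[i][abst] == 0) & all_present_retain_minor)
        if loss.any():
            removed[i] = True
            reasons[i] = REASON_LOH

    report = pd.DataFrame(
        {"kept": ~removed, "reason": np.where(removed, reasons, "")},
        index=ccf.snv_ids)
    return ccf.subset(ccf.snv_ids[~removed]), report


def apply_heterogeneity_filters(ccf: CcfMatrix, reads: SnvReadTable):
    """CN-concordance filter followed by the allele-loss filter.

    Returns ``(kept CcfMatrix, report)``; the report covers every input SNV
    exactly once with reason codes cna-discordant, ambiguous-cn or
    loh-explains-loss.
    """
    consistent = cna_consistent_loci(ccf)
    uncovered = (ccf.cn_major.to_numpy() < 0).any(axis=1)
    reason = np.full(len(ccf.snv_ids), "", dtype=object)
    reason[~consistent.to_numpy()] = REASON_DISCORDANT
    reason[uncovered] = REASON_AMBIGUOUS

    kept_ids = ccf.snv_ids[consistent.to_numpy()]
    kept_ccf, loh_report = filter_pseudo_heterogeneity(ccf.subset(kept_ids), reads)

    report = pd.DataFrame({"kept": consistent.to_numpy(), "reason": reason},
                          index=ccf.snv_ids)
    report.loc[loh_report.index, "kept"] = loh_report["kept"]
    report.loc[loh_report.index[~loh_report["kept"]], "reason"] = REASON_LOH
    return kept_ccf, report


def write_filter_report(report: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# pseudo-heterogeneity filter report\n")
        report.to_csv(fh, sep="\t", index_label="snv_id")
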