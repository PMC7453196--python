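"""Orthogonal validation of SNV calls and primary-tumour detection.

A discovery call (e.g. from WGS) is validated when an independent capture
experiment shows at least ``min_alt`` reads supporting the alternate allele;
cells with capture coverage below ``min_cov`` are excluded from the
denominator. Detection in an archival primary tumour uses the supporting-read
threshold alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SnvReadTable

__all__ = ["validate_somatic", "detect_in_primary", "validation_rates"]

VALIDATED = "validated"
NOT_VALIDATED = "not-validated"
LOW_COVERAGE = "low-coverage-excluded"
NOT_COVERED = "not-covered"


def validate_somatic(wgs_calls, capture_reads: SnvReadTable,
                     min_alt: int = 2, min_cov: int = 30):
    """Validate discovery calls against capture sequencing.

    ``wgs_calls`` is an iterable of snv_ids called in the discovery
    experiment. Returns ``(table, rates)``: a long DataFrame with one row
    per SNV x sample and a status column, and a dict with the overall
    validation rate (validated / (validated + not-validated), low-coverage
    cells excluded from the denominator).
    """
    calls = list(wgs_calls)
    rows = []
    for snv_id in calls:
        if snv_id not in capture_reads.variants.index:
            for s in capture_reads.samples:
                rows.append((snv_id, s, np.nan, np.nan, NOT_COVERED))
            continue
        for s in capture_reads.samples:
            a = int(capture_reads.alt.loc[snv_id, s])
            d = int(capture_reads.depth.loc[snv_id, s])
            if d < min_cov:
                status = LOW_COVERAGE
            elif a >= min_alt:
                status = VALIDATED
            else:
                status = NOT_VALIDATED
            rows.append((snv_id, s, a, d, status))
    table = pd.DataFrame(rows, columns=["snv_id", "sample", "alt", "depth",
                                        "status"])
    return table, validation_rates(table)


def validation_rates(table: pd.DataFrame, by=None) -> dict:
    """Validation rate(s) from a status table: validated over assessable
    (validated + not-validated) cells. With ``by`` (a mapping snv_id ->
    group, e.g. cluster assignments) returns per-group rates as well."""
    def rate(sub):
        v = int((sub["status"] == VALIDATED).sum())
        nv = int((sub["status"] == NOT_VALIDATED).sum())
        return {"validated": v, "not_validated": nv,
                "excluded": int(len(sub) - v - nv),
                "rate": v / (v + nv) if v + nv else float("nan")}

    out = {"overall": rate(table)}
    if by is not None:
        groups = table["snv_id"].map(by)
        out["per_group"] = {g: rate(table[groups == g])
                            for g in groups.dropna().unique()}
    return out


def detect_in_primary(targeted_reads: SnvReadTable,
                      min_alt: int = 2) -> pd.DataFrame:
    """Flag SNVs detected in targeted sequencing of a primary tumour:
    detected iff alt reads >= ``min_alt`` (per sample)."""
    alt = targeted_reads.alt
    return (alt >= min_alt).astype(bool)
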