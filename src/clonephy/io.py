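"""Readers, writers and core tabular containers.

Coordinate conventions: SNV positions are 1-based (VCF convention) in every
input and output; copy-number segments are 0-based half-open (BED convention).
Conversions happen only in the segment-lookup code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SnvReadTable",
    "read_snv_table",
    "read_segments",
    "read_purities",
    "write_snv_table",
]


@dataclass
class SnvReadTable:
    """Per-SNV, per-sample sequencing evidence.

    ``variants`` is indexed by snv_id with columns chrom, pos (1-based),
    ref, alt; ``alt`` and ``depth`` are integer DataFrames with the same
    index and one column per sample.
    """

    variants: pd.DataFrame
    alt: pd.DataFrame
    depth: pd.DataFrame

    def __post_init__(self):
        if not (self.variants.index.equals(self.alt.index)
                and self.variants.index.equals(self.depth.index)):
            raise ValueError("variants/alt/depth must share the same SNV index")
        if list(self.alt.columns) != list(self.depth.columns):
            raise ValueError("alt and depth must share the same sample columns")
        bad = (self.alt.to_numpy() > self.depth.to_numpy()) | (self.alt.to_numpy() < 0)
        if bad.any():
            offenders = self.alt.index[bad.any(axis=1)].tolist()[:5]
            raise ValueError(f"alt counts must satisfy 0 <= alt <= depth; bad SNVs: {offenders}")
        key = self.variants[["chrom", "pos", "alt"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, alt) keys in SNV table")

    @property
    def samples(self) -> list:
        return list(self.alt.columns)

    @property
    def n_snvs(self) -> int:
        return len(self.variants)

    def vaf(self) -> pd.DataFrame:
        """VAF per cell; NaN where depth is 0."""
        d = self.depth.to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(d > 0, self.alt.to_numpy(dtype=float) / d, np.nan)
        return pd.DataFrame(v, index=self.variants.index, columns=self.samples)

    def subset(self, snv_ids) -> "SnvReadTable":
        return SnvReadTable(self.variants.loc[snv_ids],
                            self.alt.loc[snv_ids], self.depth.loc[snv_ids])


def _table_from_wide(df: pd.DataFrame, path: str) -> SnvReadTable:
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    alt_cols = [c for c in df.columns if c.startswith("alt_")]
    depth_cols = [c for c in df.columns if c.startswith("depth_")]
    samples = [c[4:] for c in alt_cols]
    if samples != [c[6:] for c in depth_cols] or not samples:
        raise ValueError(f"{path}: need paired alt_<sample>/depth_<sample> columns")

    # reject malformed rows with their 1-based data line numbers (header = line 1)
    bad_lines = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        for s in samples:
            a, d = row[f"alt_{s}"], row[f"depth_{s}"]
            if pd.isna(a) or pd.isna(d) or a < 0 or d < 0 or a > d:
                bad_lines.append(i)
                break
    if bad_lines:
        raise ValueError(f"{path}: malformed read counts on line(s) {bad_lines}")

    ids = df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" \
        + df["ref"].astype(str) + ">" + df["alt"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate SNV keys")
    idx = pd.Index(ids.to_numpy(), name="snv_id")
    variants = pd.DataFrame(
        {"chrom": df["chrom"].astype(str).to_numpy(),
         "pos": df["pos"].astype(np.int64).to_numpy(),
         "ref": df["ref"].astype(str).to_numpy(),
         "alt": df["alt"].astype(str).to_numpy()},
        index=idx)
    alt = pd.DataFrame({s: df[f"alt_{s}"].astype(np.int64).to_numpy() for s in samples}, index=idx)
    depth = pd.DataFrame({s: df[f"depth_{s}"].astype(np.int64).to_numpy() for s in samples}, index=idx)
    return SnvReadTable(variants, alt, depth)


def _read_snv_vcf(path: str) -> SnvReadTable:
    """Read per-sample alt counts and depths from a VCF with AD (or AD+DP)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    rows, alts, depths = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(f"{path}: multi-allelic record at {var.CHROM}:{var.POS}; split first")
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"{path}: missing per-sample AD field at {var.CHROM}:{var.POS}")
        a = np.maximum(ad[:, 1], 0).astype(np.int64)
        dp = var.format("DP")
        d = (np.maximum(ad, 0).sum(axis=1) if dp is None
             else np.maximum(dp[:, 0], 0)).astype(np.int64)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        alts.append(a)
        depths.append(np.maximum(d, a))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    for j, s in enumerate(samples):
        df[f"alt_{s}"] = [a[j] for a in alts]
        df[f"depth_{s}"] = [d[j] for d in depths]
    return _table_from_wide(df, str(path))


def read_snv_table(path, fmt: str = "tsv") -> SnvReadTable:
    """Load an SNV read table from a TSV (wide, alt_/depth_ columns) or VCF."""
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        return _table_from_wide(df, str(path))
    if fmt == "vcf":
        return _read_snv_vcf(path)
    raise ValueError(f"unknown SNV table format: {fmt!r}")


def write_snv_table(reads: SnvReadTable, path) -> None:
    df = reads.variants.copy()
    for s in reads.samples:
        df[f"alt_{s}"] = reads.alt[s]
        df[f"depth_{s}"] = reads.depth[s]
    with open(path, "w") as fh:
        fh.write("# SNV read table; pos is 1-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Allele-specific copy-number segments, BED-like (0-based half-open).

    Columns: sample, chrom, start, end, major_cn, minor_cn.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "start", "end", "major_cn", "minor_cn"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.astype({"start": np.int64, "end": np.int64,
                    "major_cn": np.int64, "minor_cn": np.int64})
    df["chrom"] = df["chrom"].astype(str)
    if (df["major_cn"] < df["minor_cn"]).any() or (df["minor_cn"] < 0).any():
        raise ValueError(f"{path}: require major_cn >= minor_cn >= 0")
    return df


def read_purities(path) -> pd.DataFrame:
    """Per-sample purity table: columns sample, purity and optional ploidy."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sample", "purity"} <= set(df.columns):
        raise ValueError(f"{path}: need columns sample, purity")
    if "ploidy" not in df.columns:
        df["ploidy"] = 2.0
    if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
        raise ValueError(f"{path}: purity must lie in (0, 1]")
    return df[["sample", "purity", "ploidy"]]
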