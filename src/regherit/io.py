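"""Readers/writers for on-disk formats, SNP-panel harmonization, GWAS filtering.

Conventions: BED intervals are 0-based half-open; SNP positions are 1-based
(GWAS convention).  Conversion happens only at these I/O boundaries.  Strand is
ignored throughout; allele columns (A1/A2) are carried but never used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed on-disk input."""


#: canonical sumstats columns, in output order
SUMSTATS_COLUMNS = ("snp", "chrom", "pos", "n", "chi2", "pval")

# permissive alias superset; the originating sumstats dialect is not pinned
_ALIASES = {
    "snp": {"snp", "snp_id", "rsid", "id", "markername", "variant"},
    "chrom": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "bp", "position", "base_pair_location"},
    "n": {"n", "nsample", "n_samples", "sample_size", "neff"},
    "chi2": {"chisq", "chi2", "chi_square", "x2"},
    "z": {"z", "zscore", "z_score", "stat"},
    "pval": {"p", "pval", "p_value", "pvalue"},
    "a1": {"a1", "effect_allele", "allele1"},
    "a2": {"a2", "other_allele", "allele2"},
}

#: relative tolerance for chi2 / p consistency
CHI2_P_RTOL = 1e-6


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in columns:
        low = col.strip().lower()
        for canon, aliases in _ALIASES.items():
            if low in aliases and canon not in mapping.values():
                mapping[col] = canon
                break
    return mapping


def read_sumstats(path: str | Path) -> pd.DataFrame:
    """Read tab-delimited GWAS summary statistics.

    Requires columns naming SNP id, chromosome, position, sample size, and at
    least one of chi-square / Z / p-value.  chi2 is derived from z (``z**2``)
    or from p (upper-tail chi-square(1) quantile) when absent; p is derived
    from chi2 when absent.  When both chi2 and p are present but inconsistent
    beyond ``CHI2_P_RTOL`` relative, chi2 wins (it is the regression target)
    and p is recomputed with a warning.  Rows with missing or invalid values
    are dropped with a logged count.  Output is sorted by (chrom, pos).
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    mapping = _canonical_columns(raw.columns)
    df = raw.rename(columns=mapping)
    for required in ("snp", "chrom", "pos", "n"):
        if required not in df.columns:
            raise FormatError(f"sumstats file {path} lacks a '{required}' column")
    if not ({"chi2", "z", "pval"} & set(df.columns)):
        raise FormatError(
            f"sumstats file {path} lacks an association column (chi2/z/p)"
        )

    n_raw = len(df)
    df["snp"] = df["snp"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos", "n", "chi2", "z", "pval"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    valid = df["pos"].gt(0) & df["n"].gt(0) & df["snp"].ne("")
    if "chi2" in df.columns:
        valid &= df["chi2"].ge(0) | df["chi2"].isna()
    if "pval" in df.columns:
        valid &= (df["pval"].gt(0) & df["pval"].le(1)) | df["pval"].isna()
    # at least one association value must survive per row
    assoc = pd.Series(False, index=df.index)
    for col in ("chi2", "z", "pval"):
        if col in df.columns:
            assoc |= df[col].notna()
    valid &= assoc & df["pos"].notna() & df["n"].notna()
    df = df[valid].copy()
    if n_raw - len(df):
        logger.info("read_sumstats: dropped %d invalid rows", n_raw - len(df))
    if df.empty:
        raise FormatError(f"sumstats file {path} has no valid rows")

    if "chi2" not in df.columns or df["chi2"].isna().any():
        chi2 = df.get("chi2", pd.Series(np.nan, index=df.index))
        if "z" in df.columns:
            chi2 = chi2.fillna(df["z"] ** 2)
        if "pval" in df.columns:
            chi2 = chi2.fillna(pd.Series(
                stats.chi2.isf(df["pval"].to_numpy(), df=1), index=df.index))
        df["chi2"] = chi2
    if "pval" not in df.columns:
        df["pval"] = stats.chi2.sf(df["chi2"].to_numpy(), df=1)
    else:
        expected = stats.chi2.isf(df["pval"].to_numpy(), df=1)
        observed = df["chi2"].to_numpy(float)
        scale = np.maximum(np.abs(observed), np.abs(expected))
        bad = np.abs(observed - expected) > CHI2_P_RTOL * np.maximum(scale, 1e-300)
        # p == 1 maps to chi2 == 0 exactly; only flag true disagreements
        if bad.any():
            logger.warning(
                "read_sumstats: %d rows with chi2/p inconsistency; "
                "keeping chi2 and recomputing p", int(bad.sum()))
            pv = df["pval"].to_numpy(float)
            pv[bad] = stats.chi2.sf(observed[bad], df=1)
            df["pval"] = pv
    df["pval"] = df["pval"].clip(upper=1.0)

    dup = df["snp"].duplicated()
    if dup.any():
        logger.warning("read_sumstats: dropped %d duplicate SNP ids", int(dup.sum()))
        df = df[~dup]

    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    keep = list(SUMSTATS_COLUMNS) + [c for c in ("a1", "a2") if c in df.columns]
    out = df[keep].sort_values(["chrom", "pos"], kind="mergesort")
    return out.reset_index(drop=True)


def write_sumstats(ss: pd.DataFrame, path: str | Path) -> None:
    """Write summary statistics as TSV (round-trips bit-identically)."""
    header = {"snp": "SNP", "chrom": "CHR", "pos": "POS", "n": "N",
              "chi2": "CHISQ", "pval": "P", "a1": "A1", "a2": "A2"}
    cols = [c for c in header if c in ss.columns]
    out = ss[cols].rename(columns=header)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    id: str = field(default="", compare=False)

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end}: start >= end")
        if not self.id:
            object.__setattr__(
                self, "id", f"{self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+; returns intervals sorted by (chrom, start)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if len(parts) > 3 and parts[3] else ""
            intervals.append(GenomicInterval(chrom, start, end, name))
    return sorted(intervals)


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or book-ended intervals into a disjoint region set."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.id)
        else:
            merged.append(iv)
    return merged


def filter_gwas_catalog(
    records: pd.DataFrame,
    exclude_phenotypes: Iterable[str] | None = None,
    min_n: int = 50_000,
    min_cases: int = 10_000,
    min_signif_snps: int = 500,
) -> pd.DataFrame:
    """Filter a candidate-GWAS catalog to analysis-grade phenotypes.

    Drops sex-specific and raw-value GWAS, requires total sample size
    ``>= min_n``, for binary/categorical phenotypes requires both case and
    control counts ``>= min_cases``, and requires at least
    ``min_signif_snps`` genome-wide significant SNPs (the 5e-8 threshold is
    applied upstream when counting).  ``exclude_phenotypes`` supplies
    manual-curation exclusions.
    """
    df = records.copy()
    keep = ~df["sex_specific"].astype(bool)
    keep &= df["value_type"].astype(str).str.lower() != "raw"
    keep &= pd.to_numeric(df["n"], errors="coerce") >= min_n
    is_cc = df["value_type"].astype(str).str.lower().isin(
        {"binary", "categorical"})
    n_case = pd.to_numeric(df.get("n_case"), errors="coerce")
    n_control = pd.to_numeric(df.get("n_control"), errors="coerce")
    keep &= ~is_cc | ((n_case >= min_cases) & (n_control >= min_cases))
    keep &= pd.to_numeric(df["n_signif_snps"], errors="coerce") >= min_signif_snps
    if exclude_phenotypes is not None:
        keep &= ~df["phenotype"].isin(set(exclude_phenotypes))
    return df[keep.fillna(False)].reset_index(drop=True)


def harmonize_snps(
    ss: pd.DataFrame, panel_snps: Sequence[str], min_overlap: float = 0.9
) -> pd.DataFrame:
    """Intersect summary statistics with an LD-reference SNP panel on snp id.

    Commutative and idempotent; warns when the overlap covers less than
    ``min_overlap`` of either panel.
    """
    panel = pd.Index(panel_snps)
    common = pd.Index(ss["snp"]).intersection(panel)
    frac = len(common) / max(min(len(ss), len(panel)), 1)
    if frac < min_overlap:
        logger.warning(
            "harmonize_snps: only %.1f%% of SNPs shared between sumstats and panel",
            100 * frac)
    out = ss[ss["snp"].isin(set(common))]
    return out.reset_index(drop=True)
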