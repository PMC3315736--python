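"""Variant calling and coverage summaries for pooled resequencing data.

The pipeline starts from per-base read evidence (or post-filter counts). A
read contributes to a site's counts only if it clears stringent mapping- and
base-quality cutoffs (reads at or below MQ 50 or BQ 20 are discarded). A
site is then called a variant when the non-reference allele is supported by
at least ``min_alt_reads`` reads summed across both pools; per-pool allele
frequencies are the alt-read fraction of the post-filter depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError

__all__ = [
    "MQ_DISCARD_MAX",
    "BQ_DISCARD_MAX",
    "MIN_ALT_READS",
    "filter_pileup",
    "call_variants",
    "capture_summary",
    "CaptureStats",
]

#: reads with mapping quality <= this are discarded
MQ_DISCARD_MAX = 50
#: reads with base quality <= this are discarded
BQ_DISCARD_MAX = 20
#: minimum alt-supporting reads, summed across both pools, to call a variant
MIN_ALT_READS = 4

POOLS = ("low", "high")

_SITE_KEY = ["chrom", "pos", "ref", "alt"]


def filter_pileup(reads: pd.DataFrame,
                  mq_max: int = MQ_DISCARD_MAX,
                  bq_max: int = BQ_DISCARD_MAX) -> pd.DataFrame:
    """Reduce per-read pileup records to post-filter per-site counts.

    Parameters
    ----------
    reads
        One row per read observation with columns ``chrom, pos, ref, alt,
        pool, allele, mq, bq`` where ``allele`` is ``"ref"`` or ``"alt"``
        and ``mq``/``bq`` are integer qualities.
    mq_max, bq_max
        Inclusive discard thresholds: a read is kept iff ``mq > mq_max``
        and ``bq > bq_max``.

    Returns
    -------
    Long-format count table with columns ``chrom, pos, ref, alt, pool,
    ref_count, alt_count`` (sites with zero surviving reads keep a row of
    zeros for every pool present in the input).
    """
    required = set(_SITE_KEY + ["pool", "allele", "mq", "bq"])
    missing = required - set(reads.columns)
    if missing:
        raise FormatError(f"pileup records missing columns: {sorted(missing)}")
    if len(reads) and ((reads["mq"] < 0).any() or (reads["bq"] < 0).any()):
        raise FormatError("negative mapping or base qualities")
    bad = set(reads["allele"].unique()) - {"ref", "alt"}
    if bad:
        raise FormatError(f"unknown allele labels: {sorted(bad)}")

    kept = reads[(reads["mq"] > mq_max) & (reads["bq"] > bq_max)]
    sites = reads[_SITE_KEY + ["pool"]].drop_duplicates()
    if kept.empty:
        counts = sites.copy()
        counts["ref_count"] = 0
        counts["alt_count"] = 0
    else:
        tab = (kept.groupby(_SITE_KEY + ["pool", "allele"], sort=False)
               .size().unstack("allele", fill_value=0))
        for col in ("ref", "alt"):
            if col not in tab.columns:
                tab[col] = 0
        tab = (tab.rename(columns={"ref": "ref_count",
                                   "alt": "alt_count"})
               .rename_axis(columns=None).reset_index())
        counts = sites.merge(tab, on=_SITE_KEY + ["pool"], how="left")
        counts[["ref_count", "alt_count"]] = (
            counts[["ref_count", "alt_count"]].fillna(0).astype(np.int64))
    return (counts.sort_values(_SITE_KEY + ["pool"], kind="mergesort")
            .reset_index(drop=True))


def _pivot_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Long (one row per site x pool) to wide (one row per site)."""
    required = set(_SITE_KEY + ["pool", "ref_count", "alt_count"])
    missing = required - set(counts.columns)
    if missing:
        raise FormatError(f"count table missing columns: {sorted(missing)}")
    bad = set(counts["pool"].unique()) - set(POOLS)
    if bad:
        raise FormatError(f"unknown pool labels: {sorted(bad)}")
    wide = counts.pivot_table(
        index=_SITE_KEY, columns="pool",
        values=["ref_count", "alt_count"], fill_value=0,
        aggfunc="sum").reset_index()
    flat = []
    for col in wide.columns:
        if col[1]:
            flat.append(f"{col[0].split('_')[0]}_{col[1]}")
        else:
            flat.append(col[0])
    wide.columns = flat
    for pool in POOLS:
        for kind in ("ref", "alt"):
            col = f"{kind}_{pool}"
            if col not in wide.columns:
                wide[col] = 0
            wide[col] = wide[col].astype(np.int64)
    return wide


def call_variants(counts: pd.DataFrame,
                  min_alt_reads: int = MIN_ALT_READS) -> pd.DataFrame:
    """Call variants from post-filter pooled read counts.

    A site is called iff its alt reads summed over both pools reach
    ``min_alt_reads``. Uncalled sites are retained with ``called=False``.
    Allele frequency ``af_<pool> = alt/(ref+alt)`` where the pool has
    depth > 0, else missing (NaN) — a site may be called on one pool's
    evidence alone.

    Accepts the long count table emitted by the simulator
    (``chrom, pos, ref, alt, pool, ref_count, alt_count``) or an
    already-wide table with ``ref_low/alt_low/ref_high/alt_high`` columns.
    """
    if min_alt_reads < 1:
        raise ArgumentError("min_alt_reads must be >= 1")
    if "pool" in counts.columns:
        wide = _pivot_counts(counts)
    else:
        wide = counts.copy()
    calls = wide[_SITE_KEY + ["ref_low", "alt_low", "ref_high", "alt_high"]
                 ].copy()
    calls["depth_low"] = calls["ref_low"] + calls["alt_low"]
    calls["depth_high"] = calls["ref_high"] + calls["alt_high"]
    with np.errstate(invalid="ignore", divide="ignore"):
        calls["af_low"] = np.where(
            calls["depth_low"] > 0, calls["alt_low"] / calls["depth_low"],
            np.nan)
        calls["af_high"] = np.where(
            calls["depth_high"] > 0, calls["alt_high"] / calls["depth_high"],
            np.nan)
    calls["called"] = (calls["alt_low"] + calls["alt_high"]) >= min_alt_reads
    return (calls.sort_values(_SITE_KEY, kind="mergesort")
            .reset_index(drop=True))


@dataclass(frozen=True)
class CaptureStats:
    """Per-pool and combined capture/coverage summary (Table 1 analogue)."""

    target_length: int
    covered_length_low: int
    covered_length_high: int
    mean_coverage_low: float
    mean_coverage_high: float
    combined_mean_coverage: float
    combined_total_coverage: float

    @property
    def covered_fraction_low(self) -> float:
        return self.covered_length_low / self.target_length

    @property
    def covered_fraction_high(self) -> float:
        return self.covered_length_high / self.target_length

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "target_length": [self.target_length, self.target_length],
            "covered_length": [self.covered_length_low,
                               self.covered_length_high],
            "covered_fraction": [self.covered_fraction_low,
                                 self.covered_fraction_high],
            "mean_fold_coverage": [self.mean_coverage_low,
                                   self.mean_coverage_high],
        }
        df = pd.DataFrame(rows, index=pd.Index(POOLS, name="pool"))
        df.attrs["combined_mean_coverage"] = self.combined_mean_coverage
        df.attrs["combined_total_coverage"] = self.combined_total_coverage
        return df


def capture_summary(depth_low, depth_high,
                    target_length: int | None = None) -> CaptureStats:
    """Coverage summary over the capture target.

    Parameters
    ----------
    depth_low, depth_high
        Per-base depth vectors over the target, one per pool.
    target_length
        Length of the target in bases; defaults to the vector length.

    Notes
    -----
    Mean fold coverage per pool is the mean depth over that pool's covered
    (depth >= 1) bases, 0 when nothing is covered. The combined mean is the
    mean of the two per-pool means and the combined total is their sum —
    e.g. per-pool means of 56x and 32x give a combined mean of 44x and a
    combined total of 88x.
    """
    dl = np.asarray(depth_low, dtype=float)
    dh = np.asarray(depth_high, dtype=float)
    if dl.shape != dh.shape:
        raise ArgumentError("depth vectors must have equal length")
    if target_length is None:
        target_length = dl.size
    if target_length <= 0:
        raise ArgumentError("target_length must be positive")

    def pool_stats(d):
        covered = d >= 1
        n_cov = int(covered.sum())
        mean_cov = float(d[covered].mean()) if n_cov else 0.0
        return n_cov, mean_cov

    cov_l, mean_l = pool_stats(dl)
    cov_h, mean_h = pool_stats(dh)
    return CaptureStats(
        target_length=int(target_length),
        covered_length_low=cov_l,
        covered_length_high=cov_h,
        mean_coverage_low=mean_l,
        mean_coverage_high=mean_h,
        combined_mean_coverage=(mean_l + mean_h) / 2.0,
        combined_total_coverage=mean_l + mean_h,
    )
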