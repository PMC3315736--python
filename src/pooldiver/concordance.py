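"""Validation of pooled frequency estimates against individual genotypes,
and coverage-stratified false-negative rates against a reference SNP set.

Actual allele frequencies come from diploid genotypes (alt-copy counts out
of 2N alleles); estimated frequencies come from pooled read counts. Each
SNP is compared per pool with a two-tailed Fisher's exact test on the
(method x allele) 2x2 table and BH-adjusted across all SNP-by-pool tests;
a SNP is concordant when its adjusted p is not below the experiment-wise
level (default 0.1).

False-negative rates take a set of loci known to segregate in the cohort
and ask what fraction the pooled pipeline failed to call, within coverage
tiers (default at least 4x / 10x / 30x combined depth). The denominator is
the full reference set at every tier (the "5/67" convention) unless
``tier_denominator`` is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .difftest import bh_adjust, fisher_exact_vector
from .errors import ArgumentError

__all__ = [
    "genotype_frequencies",
    "concordance_test",
    "false_negative_report",
    "tukey_hinges",
    "FNRReport",
]


def genotype_frequencies(genotypes: pd.DataFrame) -> pd.Series:
    """Alt-allele frequency per SNP from a SNP x animal genotype matrix.

    Entries are alt-copy counts in {0, 1, 2} or NaN for missing;
    frequency = sum(alt copies) / (2 x non-missing animals). SNPs with no
    non-missing genotype are dropped (they carry no frequency).
    """
    g = genotypes.astype(float)
    valid = ((g.isin([0.0, 1.0, 2.0])) | g.isna()).all(axis=None)
    if not valid:
        raise ArgumentError("genotypes must be 0, 1, 2 or missing")
    n_obs = g.notna().sum(axis=1)
    freq = g.sum(axis=1, skipna=True) / (2.0 * n_obs)
    return freq[n_obs > 0]


def concordance_test(tests: pd.DataFrame, alpha: float = 0.1
                     ) -> pd.DataFrame:
    """Fisher/BH concordance between genotyped and pooled frequencies.

    Parameters
    ----------
    tests
        One row per SNP x pool with columns ``snp_id, pool, actual_alt,
        actual_total, est_alt, est_depth`` (actual counts are allele
        copies out of 2N; estimated counts are reads).
    alpha
        Experiment-wise BH level, default 0.1.

    Returns
    -------
    Input rows plus ``actual_freq, est_freq, p, q, concordant, excluded,
    exclude_reason``; rows with zero estimated depth are excluded from
    testing but retained with a reason.
    """
    df = tests.copy()
    if (df[["actual_alt", "actual_total", "est_alt", "est_depth"]] < 0
            ).any().any():
        raise ArgumentError("counts must be non-negative")
    if (df["actual_alt"] > df["actual_total"]).any() or \
            (df["est_alt"] > df["est_depth"]).any():
        raise ArgumentError("alt counts cannot exceed totals")
    df["excluded"] = df["est_depth"] == 0
    df["exclude_reason"] = np.where(df["excluded"], "zero_depth", "")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["actual_freq"] = df["actual_alt"] / df["actual_total"]
        df["est_freq"] = np.where(
            df["est_depth"] > 0, df["est_alt"] / df["est_depth"], np.nan)
    tested = ~df["excluded"]
    p = np.full(len(df), np.nan)
    if tested.any():
        sub = df[tested]
        p[tested.to_numpy()] = fisher_exact_vector(
            (sub["actual_total"] - sub["actual_alt"]).to_numpy(),
            sub["actual_alt"].to_numpy(),
            (sub["est_depth"] - sub["est_alt"]).to_numpy(),
            sub["est_alt"].to_numpy())
    df["p"] = p
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested.to_numpy()] = bh_adjust(p[tested.to_numpy()])
    df["q"] = q
    df["concordant"] = tested & (df["q"] >= alpha)
    return df


def tukey_hinges(x) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge): medians of the sorted halves,
    each half including the overall median when n is odd."""
    v = np.sort(np.asarray(x, dtype=float))
    n = v.size
    if n == 0:
        raise ArgumentError("empty vector has no quartiles")
    med = float(np.median(v))
    half = (n + 1) // 2
    lower = float(np.median(v[:half]))
    upper = float(np.median(v[n - half:]))
    return lower, med, upper


@dataclass
class FNRReport:
    tiers: pd.DataFrame          # per coverage tier: counts and FNR (%)
    depth_quartiles: pd.DataFrame  # Tukey hinges by detection status

    def __repr__(self):
        return f"FNRReport(\n{self.tiers}\n{self.depth_quartiles}\n)"


def false_negative_report(reference: pd.DataFrame, detected: pd.DataFrame,
                          tiers=(4, 10, 30),
                          tier_denominator: bool = False) -> FNRReport:
    """Coverage-stratified false-negative rates against a reference SNP set.

    Parameters
    ----------
    reference
        Loci asserted to segregate in the cohort, with columns ``chrom,
        pos, depth`` (combined read depth observed at the locus).
    detected
        Called variants (any table with ``chrom, pos``; when a ``called``
        column is present only called rows count as detected).
    tiers
        Coverage thresholds; tier t considers reference loci with
        depth >= t.
    tier_denominator
        When False (default) FNR(t) = undetected-with-depth>=t / all
        reference loci, the fixed-denominator convention behind figures
        like "7.5% (5/67)". When True the denominator is the tier-
        restricted locus count instead (the convention needed for
        database-style comparisons).
    """
    if reference.empty:
        raise ArgumentError("reference SNP set is empty")
    ref = reference.copy()
    if ref.duplicated(["chrom", "pos"]).any():
        raise ArgumentError("reference loci must be unique")
    det = detected
    if "called" in det.columns:
        det = det[det["called"]]
    det_keys = set(zip(det["chrom"], det["pos"]))
    ref["detected"] = [
        (c, p) in det_keys for c, p in zip(ref["chrom"], ref["pos"])]
    n_total = len(ref)
    rows = []
    for t in tiers:
        in_tier = ref["depth"] >= t
        undet = int((in_tier & ~ref["detected"]).sum())
        denom = int(in_tier.sum()) if tier_denominator else n_total
        rows.append({
            "tier": t,
            "n_reference": denom,
            "n_in_tier": int(in_tier.sum()),
            "n_undetected": undet,
            "fnr_pct": 100.0 * undet / denom if denom else np.nan,
        })
    qrows = []
    for status, grp in (("detected", ref[ref["detected"]]),
                        ("undetected", ref[~ref["detected"]])):
        if len(grp):
            q1, med, q3 = tukey_hinges(grp["depth"])
        else:
            q1 = med = q3 = np.nan
        qrows.append({"status": status, "n": len(grp),
                      "q1": q1, "median": med, "q3": q3})
    return FNRReport(tiers=pd.DataFrame(rows),
                     depth_quartiles=pd.DataFrame(qrows))
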