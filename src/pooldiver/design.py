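"""Detection limits and power for pooled resequencing designs.

Calling a variant requires ``min_alt_reads`` non-reference reads summed
across both pools. At a combined average coverage C this implies an
average-case minimum detectable minor allele frequency of
``min_alt_reads / C`` — e.g. 4 reads at 88x combined coverage gives 4.5%.
That ratio is an average-case bound, not a probabilistic guarantee; the
exact detection probability under binomial read sampling, and Monte-Carlo
power for the two-pool Fisher comparison, are computed separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom

from .difftest import fisher_exact_vector
from .errors import ArgumentError

__all__ = [
    "min_detectable_maf",
    "detection_probability",
    "fisher_power",
    "design_table",
]


def min_detectable_maf(min_alt_reads: int, combined_coverage: float) -> float:
    """Average-case minimum detectable MAF, ``min_alt_reads / coverage``.

    Returns a frequency in [0, 1]; multiply by 100 and round to one
    decimal for display in percent (4 reads at 88x -> 4.5%).
    """
    if combined_coverage <= 0:
        raise ArgumentError("combined coverage must be positive")
    if min_alt_reads < 0:
        raise ArgumentError("min_alt_reads must be non-negative")
    return min_alt_reads / combined_coverage


def _effective_freq(maf: float, error: float) -> float:
    # sequencing error folds symmetrically into the read-level alt rate
    return maf * (1.0 - error) + (1.0 - maf) * error


def detection_probability(maf: float, depth_low: int, depth_high: int,
                          min_alt_reads: int = 4,
                          error: float = 0.0) -> float:
    """Exact probability that a site reaches the alt-read calling threshold.

    Alt reads per pool are binomial(depth, f') with
    f' = maf(1-e) + (1-maf)e, pools independent;
    ``P(total alt >= min_alt_reads)`` is computed by exact convolution of
    the two binomials.
    """
    if depth_low < 0 or depth_high < 0:
        raise ArgumentError("depths must be non-negative")
    if not 0 <= maf <= 1:
        raise ArgumentError("maf must be in [0, 1]")
    if not 0 <= error <= 1:
        raise ArgumentError("error must be in [0, 1]")
    if min_alt_reads <= 0:
        return 1.0
    f = _effective_freq(maf, error)
    dl, dh = int(depth_low), int(depth_high)
    # P(X + Y <= k-1) via convolution of the two pmfs up to k-1
    k = min_alt_reads
    t = np.arange(k)
    pl = binom.pmf(t, dl, f)
    ph = binom.pmf(t, dh, f)
    p_below = 0.0
    for total in range(k):
        j = np.arange(total + 1)
        p_below += float(np.sum(pl[j] * ph[total - j]))
    return float(np.clip(1.0 - p_below, 0.0, 1.0))


def fisher_power(af_low: float, af_high: float, depth_low: int,
                 depth_high: int, alpha: float = 0.01,
                 n_reps: int = 1000, seed: int = 0
                 ) -> tuple[float, float]:
    """Monte-Carlo power of the two-pool Fisher comparison at one site.

    Simulates ``n_reps`` 2x2 read-count tables with alt counts binomial at
    the given true frequencies and returns ``(power, mc_standard_error)``
    where power is the fraction of tables with two-tailed p < alpha.
    """
    if n_reps < 100:
        raise ArgumentError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    alt_l = rng.binomial(depth_low, af_low, size=n_reps)
    alt_h = rng.binomial(depth_high, af_high, size=n_reps)
    p = fisher_exact_vector(depth_low - alt_l, alt_l,
                            depth_high - alt_h, alt_h)
    power = float(np.mean(p < alpha))
    se = float(np.sqrt(power * (1.0 - power) / n_reps))
    return power, se


def design_table(depth_low: int, depth_high: int, min_alt_reads: int = 4,
                 error: float = 0.0,
                 maf_grid=None) -> pd.DataFrame:
    """Detection-limit / detection-probability table over a MAF grid."""
    if maf_grid is None:
        maf_grid = np.arange(0.01, 0.51, 0.01)
    combined = depth_low + depth_high
    rows = [{
        "maf": float(m),
        "detection_probability": detection_probability(
            float(m), depth_low, depth_high, min_alt_reads, error),
    } for m in maf_grid]
    df = pd.DataFrame(rows)
    df.attrs["min_detectable_maf"] = min_detectable_maf(
        min_alt_reads, combined)
    return df
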