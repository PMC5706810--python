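"""Pooled variant calling from per-pool read counts, plus detection power.

A variant is called in a **case pool** when its alternate-allele fraction
clears the global 2% screen, lies inside the inclusive 10-50% minor-allele
window (one heterozygote among 3 pooled diploid samples contributes
1/6 ~ 16.7% of reads), and the site has >= 50 reads.  A variant is deemed
**present in a control pool** under a looser presence rule (>= 2% alt
fraction and >= 2 supporting reads) — control pools only serve to remove
variants that are not case-only.

``detection_power`` computes the probability that a single pool-site is
called, by exact binomial summation over the acceptance region, with the
same error model the simulator uses:
``alt ~ Binomial(depth, f*(1-e) + (1-f)*e/3)``, ``f = carrier alleles /
(2 * pool size)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .models import CallThresholds, ConfigError, MalformedInputError, Pool, PoolCall, PoolSiteCounts

__all__ = [
    "call_case_pool",
    "call_control_pool",
    "call_all",
    "detection_power",
    "detection_power_depth_averaged",
    "alt_read_probability",
    "per_sample_depth",
]

import pandas as pd


def alt_read_probability(f: float, error: float) -> float:
    """Per-read probability of observing the alternate allele.

    True alt fraction ``f`` attenuated by the error rate ``error``, with
    misincorporations spread uniformly over the three non-reference bases
    (so only ``error/3`` of errors hit the specific alternate base).
    """
    return f * (1.0 - error) + (1.0 - f) * error / 3.0


def per_sample_depth(pool_depth: float, pool_size: int) -> float:
    """Mean per-member depth under equimolar pooling (pool depth / pool size)."""
    if pool_size < 1:
        raise ConfigError("pool_size must be >= 1")
    return pool_depth / pool_size


def _case_reason(depth: int, alt_reads: int, frac: float,
                 t: CallThresholds) -> str:
    reads_ok = (alt_reads if t.min_reads_on_alt else depth) >= t.min_reads
    if not reads_ok:
        return "insufficient_reads"
    if frac < t.min_alt_fraction_screen:
        return "below_screen"
    if frac < t.case_window_low:
        return "below_window"
    if frac > t.case_window_high:
        return "above_window"
    return "pass"


def call_case_pool(counts: PoolSiteCounts,
                   thresholds: CallThresholds | None = None) -> PoolCall:
    """Apply the case-pool calling rule to one pool-site.

    Window bounds are inclusive at both ends; ``alt_fraction`` is defined
    as 0 when depth is 0.
    """
    t = thresholds or CallThresholds()
    frac = counts.alt_fraction
    reason = _case_reason(counts.depth, counts.alt_reads, frac, t)
    return PoolCall(counts.pool_id, counts.variant_id,
                    reason == "pass", frac, reason)


def call_control_pool(counts: PoolSiteCounts,
                      thresholds: CallThresholds | None = None) -> PoolCall:
    """Decide whether the variant is present in a control pool."""
    t = thresholds or CallThresholds()
    frac = counts.alt_fraction
    if frac < t.control_presence_fraction:
        reason = "below_screen"
    elif counts.alt_reads < t.control_min_alt_reads:
        reason = "insufficient_reads"
    else:
        reason = "pass"
    return PoolCall(counts.pool_id, counts.variant_id,
                    reason == "pass", frac, reason)


def call_all(counts: pd.DataFrame, pools: list[Pool],
             thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Apply the arm-appropriate rule to every row of a pooled counts table.

    ``counts`` needs columns pool_id, variant_id, depth, alt_reads.  Output
    has one row per input row with alt_fraction, detected, and reason
    columns appended; row order follows the input.  Vectorised so study
    scale (hundreds of pools x thousands of sites) stays fast.
    """
    t = thresholds or CallThresholds()
    arm_of = {p.pool_id: p.arm for p in pools}
    unknown = set(counts["pool_id"]) - set(arm_of)
    if unknown:
        raise MalformedInputError(f"unknown pool ids in counts: {sorted(unknown)[:5]}")
    if (counts["alt_reads"] > counts["depth"]).any():
        raise MalformedInputError("alt_reads > depth in counts table")

    depth = counts["depth"].to_numpy(dtype=np.int64)
    alt = counts["alt_reads"].to_numpy(dtype=np.int64)
    frac = np.divide(alt, depth, out=np.zeros(len(counts)), where=depth > 0)
    is_case = counts["pool_id"].map(arm_of).to_numpy() == "case"

    reads_val = alt if t.min_reads_on_alt else depth
    case_reason = np.select(
        [reads_val < t.min_reads,
         frac < t.min_alt_fraction_screen,
         frac < t.case_window_low,
         frac > t.case_window_high],
        ["insufficient_reads", "below_screen", "below_window", "above_window"],
        default="pass",
    )
    ctrl_reason = np.select(
        [frac < t.control_presence_fraction,
         alt < t.control_min_alt_reads],
        ["below_screen", "insufficient_reads"],
        default="pass",
    )
    reason = np.where(is_case, case_reason, ctrl_reason)
    out = counts[["pool_id", "variant_id", "depth", "alt_reads"]].copy()
    out["alt_fraction"] = frac
    out["detected"] = reason == "pass"
    out["reason"] = reason
    return out


def _acceptance_mask(depth: int, t: CallThresholds) -> np.ndarray:
    """Boolean mask over k = 0..depth of alt-read counts that pass the case rule."""
    k = np.arange(depth + 1)
    frac = k / depth
    reads_val = k if t.min_reads_on_alt else np.full_like(k, depth)
    return (
        (reads_val >= t.min_reads)
        & (frac >= t.min_alt_fraction_screen)
        & (frac >= t.case_window_low)
        & (frac <= t.case_window_high)
    )


def detection_power(
    pool_size: int,
    n_carrier_alleles: int,
    depth: int,
    error: float,
    thresholds: CallThresholds | None = None,
    method: str = "exact",
    n_reps: int = 100_000,
    seed: int | None = None,
) -> float:
    """Probability that a case pool-site with the given carrier load is called.

    ``method="exact"`` sums the binomial pmf over exactly the alt-read
    counts that :func:`call_case_pool` accepts, so the two can never
    disagree on the acceptance region.  ``method="mc"`` estimates the same
    probability by seeded Monte-Carlo draws (useful as a cross-check).
    """
    t = thresholds or CallThresholds()
    if pool_size < 1:
        raise ConfigError("pool_size must be >= 1")
    if not 0 <= n_carrier_alleles <= 2 * pool_size:
        raise ConfigError("n_carrier_alleles must lie in [0, 2*pool_size]")
    if depth < 0:
        raise ConfigError("depth must be >= 0")
    if not 0.0 <= error <= 1.0:
        raise ConfigError("error must lie in [0,1]")
    if depth == 0:
        return 0.0

    f = n_carrier_alleles / (2 * pool_size)
    p = alt_read_probability(f, error)
    if method == "exact":
        mask = _acceptance_mask(depth, t)
        if not mask.any():
            return 0.0
        k = np.nonzero(mask)[0]
        return float(stats.binom.pmf(k, depth, p).sum())
    if method == "mc":
        rng = np.random.default_rng(seed)
        alts = rng.binomial(depth, p, size=n_reps)
        mask = _acceptance_mask(depth, t)
        return float(mask[alts].mean())
    raise ConfigError(f"unknown method {method!r}")


def detection_power_depth_averaged(
    pool_size: int,
    n_carrier_alleles: int,
    mean_depth: int,
    error: float,
    thresholds: CallThresholds | None = None,
    distribution: str = "poisson",
    dispersion: float = float("inf"),
) -> float:
    """Exact detection power marginalised over a random site depth.

    Matches the simulator's depth model: Poisson around ``mean_depth`` or
    negative-binomial with the given dispersion.  Sums
    ``P(depth = d) * power(d)`` over the essential support of the depth
    distribution.
    """
    if distribution == "poisson" or np.isinf(dispersion):
        dist = stats.poisson(mean_depth)
    elif distribution == "negative_binomial":
        dist = stats.nbinom(dispersion, dispersion / (dispersion + mean_depth))
    elif distribution == "fixed":
        return detection_power(pool_size, n_carrier_alleles, mean_depth,
                               error, thresholds)
    else:
        raise ConfigError(f"unknown distribution {distribution!r}")
    lo = int(dist.ppf(1e-10))
    hi = int(dist.isf(1e-10)) + 1
    depths = np.arange(max(lo, 0), hi + 1)
    weights = dist.pmf(depths)
    total = 0.0
    for d, w in zip(depths, weights):
        if w > 0:
            total += w * detection_power(pool_size, n_carrier_alleles,
                                         int(d), error, thresholds)
    return float(total)
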