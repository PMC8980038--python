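"""Library QC, median-of-ratios normalization, interval retention and testing.

Order of operations: libraries with too few class-filtered fragments are
excluded first; intervals are retained when their mean RAW extremity count
over kept libraries is >= ``min_mean`` (default 5); size factors are then
computed on the retained intervals by the median-of-ratios procedure; fold
changes (mutant mean / control mean) and two-sided Mann-Whitney p-values are
computed on the normalized counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import GenomeBinning
from .mannwhitney import rowwise_mannwhitney

logger = logging.getLogger(__name__)

CONTROL = "control"
MUTANT = "mutant"


@dataclass
class LibraryProfile:
    """Per-library metadata: id, genotype group, depth, size factor."""

    library_id: str
    group: str  # "control" | "mutant"
    total_fragments: int
    size_factor: float = 1.0
    excluded_reason: str | None = None

    def __post_init__(self) -> None:
        if self.group not in (CONTROL, MUTANT):
            raise ValueError(f"group must be control|mutant, got {self.group!r}")
        if self.size_factor <= 0:
            raise ValueError("size factor must be positive")


def exclude_low_count_libraries(
    profiles: Sequence[LibraryProfile], min_reads: float = 1.0e7
) -> tuple[list[LibraryProfile], list[LibraryProfile]]:
    """Drop libraries whose class-filtered fragment total is below ``min_reads``.

    Shallow sub-libraries leave a large fraction of genome intervals without
    counts and distort the rank test; they are excluded up front.  Raises if
    either genotype group is left with fewer than two libraries (the rank
    test is undefined).
    """
    kept, excluded = [], []
    for p in profiles:
        if p.total_fragments < min_reads:
            p.excluded_reason = (
                f"low count: {p.total_fragments:.3g} < min_reads {min_reads:.3g}"
            )
            excluded.append(p)
        else:
            kept.append(p)
    n_ctrl = sum(1 for p in kept if p.group == CONTROL)
    n_mut = sum(1 for p in kept if p.group == MUTANT)
    logger.info(
        "library exclusion: kept %d control + %d mutant, excluded %d",
        n_ctrl, n_mut, len(excluded),
    )
    if n_ctrl < 2 or n_mut < 2:
        raise ValueError(
            f"after exclusion a group has < 2 libraries "
            f"(control={n_ctrl}, mutant={n_mut}); rank test undefined"
        )
    return kept, excluded


def retention_filter(counts: np.ndarray, min_mean: float = 5.0) -> np.ndarray:
    """Indices of intervals whose mean raw count across libraries is >= ``min_mean``.

    The threshold is inclusive ("a mean of 5 or more read extremities").
    """
    counts = np.asarray(counts)
    means = counts.mean(axis=1)
    retained = np.flatnonzero(means >= min_mean)
    logger.info(
        "retention filter: %d / %d intervals retained (%.3g%%)",
        retained.size, counts.shape[0], 100.0 * retained.size / max(1, counts.shape[0]),
    )
    return retained


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, one per library (column).

    For each interval with a strictly positive geometric mean across
    libraries, the ratio count/geomean is formed; a library's size factor is
    the median of its ratios.  Normalized counts are raw / size factor.

    The factors are rescaled to unit geometric mean, which keeps normalized
    counts on the raw count scale and makes normalization idempotent
    (re-estimating size factors on a normalized matrix returns all ones);
    fold changes and rank tests are invariant to this rescaling.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a (intervals x >=2 libraries) matrix")
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_pos = np.isfinite(logc).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no interval has positive counts in every library; "
            "lower bin sparsity or use a pseudo-reference"
        )
    log_geomean = logc[all_pos].mean(axis=1)
    log_ratios = logc[all_pos] - log_geomean[:, None]
    log_s = np.median(log_ratios, axis=0)
    return np.exp(log_s - log_s.mean())


@dataclass
class IntervalStat:
    """Differential-accessibility statistics for one retained interval."""

    chrom: str
    start: int
    end: int
    mean_control: float
    mean_mutant: float
    fold_change: float  # mutant / control; nan when control mean is 0
    p_value: float


def interval_test(
    row: np.ndarray, groups: Sequence[str]
) -> tuple[float, float, float, float]:
    """Test one interval: (mean_control, mean_mutant, fold_change, p).

    ``row`` holds the per-library normalized counts; ``groups`` the matching
    labels.  Fold change is mean(mutant)/mean(control) (nan when the control
    mean is zero); p is the two-sided Mann-Whitney p-value.
    """
    groups = np.asarray(groups)
    stats_df = interval_tests(np.asarray(row, float)[None, :], groups)
    r = stats_df.iloc[0]
    return (
        float(r["mean_control"]),
        float(r["mean_mutant"]),
        float(r["fold_change"]),
        float(r["p_value"]),
    )


def interval_tests(norm_counts: np.ndarray, groups: Sequence[str]) -> pd.DataFrame:
    """Vectorized per-interval fold change + rank test over a matrix.

    Returns a DataFrame with columns mean_control, mean_mutant, fold_change,
    p_value, fc_defined.  Intervals with a zero control mean get
    ``fold_change = nan`` and ``fc_defined = False``; they are excluded from
    the downstream ratio curve and tallied by the caller.
    """
    groups = np.asarray(groups)
    g_ctrl = np.flatnonzero(groups == CONTROL)
    g_mut = np.flatnonzero(groups == MUTANT)
    if g_ctrl.size < 2 or g_mut.size < 2:
        raise ValueError("both groups need >= 2 libraries")
    norm_counts = np.asarray(norm_counts, dtype=float)
    mean_c = norm_counts[:, g_ctrl].mean(axis=1)
    mean_m = norm_counts[:, g_mut].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_c > 0, mean_m / mean_c, np.nan)
    _, p, _ = rowwise_mannwhitney(norm_counts, g_mut, g_ctrl)
    return pd.DataFrame(
        {
            "mean_control": mean_c,
            "mean_mutant": mean_m,
            "fold_change": fc,
            "p_value": p,
            "fc_defined": mean_c > 0,
        }
    )


def per_base_test(
    ctrl_positions: np.ndarray, mut_positions: np.ndarray
) -> tuple[float, float]:
    """Alternative, per-base unit of replication for one interval.

    Applies the two-sided Mann-Whitney test to the per-position extremity
    counts pooled across libraries within each group (one observation per
    base of the interval, e.g. 100 per group for 100-bp bins) instead of one
    observation per library.  This trades the library as the unit of
    replication for the base pair, producing far smaller attainable
    p-values; it is speculative and not the default analysis.
    """
    from .mannwhitney import mannwhitney_two_sided

    return mannwhitney_two_sided(np.asarray(mut_positions), np.asarray(ctrl_positions))


@dataclass
class DifferentialResult:
    """Full output of :func:`differential_analysis`."""

    stats: pd.DataFrame  # chrom,start,end,mean_control,mean_mutant,fold_change,p_value,fc_defined
    retained_index: np.ndarray  # global bin indices of retained intervals
    size_factors: np.ndarray
    libraries: list[LibraryProfile]
    n_zero_control: int
    norm_counts: np.ndarray | None = None  # retained x libraries, normalized


def differential_analysis(
    counts: np.ndarray,
    profiles: Sequence[LibraryProfile],
    binning: GenomeBinning,
    min_mean: float = 5.0,
) -> DifferentialResult:
    """Retention filter -> size factors -> normalized per-interval tests.

    ``counts`` is the (bins x libraries) raw extremity matrix restricted to
    the kept libraries, columns ordered as ``profiles``.
    """
    counts = np.asarray(counts)
    retained = retention_filter(counts, min_mean=min_mean)
    if retained.size == 0:
        raise ValueError("no interval passes the retention filter")
    sub = counts[retained].astype(float)
    s = size_factors(sub)
    for p, sj in zip(profiles, s):
        p.size_factor = float(sj)
    norm = sub / s[None, :]
    groups = np.array([p.group for p in profiles])
    stats_df = interval_tests(norm, groups)
    coords = binning.bin_table(retained)
    stats_df = pd.concat([coords.reset_index(drop=True), stats_df], axis=1)
    n_zero = int((~stats_df["fc_defined"]).sum())
    if n_zero:
        logger.info("%d retained intervals have zero control mean (FC undefined)", n_zero)
    return DifferentialResult(
        stats=stats_df,
        retained_index=retained,
        size_factors=s,
        libraries=list(profiles),
        n_zero_control=n_zero,
        norm_counts=norm,
    )
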