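"""Enhanced/repressed accessibility ratio over sliding windows of p-ranked intervals.

Intervals are ranked by increasing p-value and the ratio
(# fold change > 1) / (# fold change < 1) is computed over sliding windows
of ``window`` intervals (default 1000, step 1).  A sustained departure from
1 at the low-p end of the curve indicates a genome-wide directional shift in
accessibility; the curve falling below ~0.6 at the lowest p-values is the
signature of broad accessibility loss in the mutant group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def rank_intervals(stats: pd.DataFrame) -> pd.DataFrame:
    """Order intervals for windowing: p ascending, then |log2 FC| descending,
    then genomic coordinate (deterministic tie-break).

    Intervals with undefined fold change (zero control mean) are dropped.
    """
    df = stats[stats["fc_defined"]].copy() if "fc_defined" in stats else stats.copy()
    df = df[np.isfinite(df["fold_change"]) & (df["fold_change"] > 0)]
    with np.errstate(divide="ignore"):
        abslfc = np.abs(np.log2(df["fold_change"].to_numpy()))
    df["_abslfc"] = abslfc
    df = df.sort_values(
        ["p_value", "_abslfc", "chrom", "start"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop(columns="_abslfc")
    return df.reset_index(drop=True)


@dataclass
class RatioCurve:
    """Sliding-window ratio curve over p-ranked intervals."""

    window: int
    step: int
    points: pd.DataFrame  # start_rank, leading_p, n_enhanced, n_repressed, n_ties, ratio

    @property
    def ratios(self) -> np.ndarray:
        return self.points["ratio"].to_numpy()


def build_ratio_curve(stats: pd.DataFrame, window: int = 1000, step: int = 1) -> RatioCurve:
    """Compute the enhanced/repressed ratio over sliding windows.

    ``stats`` needs columns fold_change and p_value (fc_defined honoured if
    present).  Within each window, intervals with FC > 1 count as enhanced
    and FC < 1 as repressed; FC exactly 1 is a tie, kept in the window but
    excluded from both counts.  ``leading_p`` is the p-value of the window's
    first (lowest-p) interval.  The ratio is NaN (flagged) when a window has
    no repressed interval.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    ranked = rank_intervals(stats)
    n = len(ranked)
    if n < window:
        raise ValueError(
            f"only {n} intervals with defined fold change; need >= window={window} "
            "(use a smaller window)"
        )
    fc = ranked["fold_change"].to_numpy()
    p = ranked["p_value"].to_numpy()
    enh = np.concatenate([[0], np.cumsum(fc > 1)])
    rep = np.concatenate([[0], np.cumsum(fc < 1)])
    starts = np.arange(0, n - window + 1, step)
    n_enh = enh[starts + window] - enh[starts]
    n_rep = rep[starts + window] - rep[starts]
    n_ties = window - n_enh - n_rep
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_rep > 0, n_enh / np.maximum(n_rep, 1), np.nan)
    points = pd.DataFrame(
        {
            "start_rank": starts,
            "leading_p": p[starts],
            "n_enhanced": n_enh,
            "n_repressed": n_rep,
            "n_ties": n_ties,
            "ratio": ratio,
        }
    )
    return RatioCurve(window=window, step=step, points=points)


@dataclass
class RatioSelection:
    """Intervals selected at a ratio cutoff (a prefix of the p-ranked list)."""

    cutoff: float
    selected: pd.DataFrame
    boundary_p: float | None  # leading p of the first window exceeding the cutoff


def select_by_ratio(
    curve: RatioCurve,
    stats: pd.DataFrame,
    cutoff: float = 0.60,
    mode: str = "prefix",
) -> RatioSelection:
    """Select the low-p intervals where the curve sits at or below ``cutoff``.

    ``mode="prefix"`` (default): all intervals ranked before the start of the
    first window whose ratio exceeds the cutoff.  ``mode="windows"``: all
    intervals belonging to any window with ratio <= cutoff.  An empty
    selection (first window already above the cutoff) emits a warning.
    """
    if mode == "prefix" and curve.step != 1:
        raise ValueError("prefix selection requires a curve built with step=1")
    ranked = rank_intervals(stats)
    # a window with no repressed interval (flagged NaN) exceeds any finite cutoff
    ratios = np.where(
        curve.points["n_repressed"].to_numpy() > 0,
        curve.points["ratio"].to_numpy(),
        np.inf,
    )
    starts = curve.points["start_rank"].to_numpy()
    above = np.flatnonzero(ratios > cutoff)
    if mode == "prefix":
        if above.size == 0:
            boundary_rank = len(ranked)  # never exceeds: whole list selected
            boundary_p = None
        else:
            first = above[0]
            boundary_rank = int(starts[first])
            boundary_p = float(curve.points["leading_p"].iloc[first])
        selected = ranked.iloc[:boundary_rank]
    elif mode == "windows":
        mask = np.zeros(len(ranked), dtype=bool)
        for s, r in zip(starts, ratios):
            if np.isfinite(r) and r <= cutoff:
                mask[s : s + curve.window] = True
        selected = ranked[mask]
        boundary_p = float(selected["p_value"].max()) if len(selected) else None
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if len(selected) == 0:
        warnings.warn(
            f"no window ratio at or below cutoff {cutoff}; selection is empty",
            stacklevel=2,
        )
    logger.info(
        "ratio selection (mode=%s, cutoff=%.3g): %d intervals", mode, cutoff, len(selected)
    )
    return RatioSelection(cutoff=cutoff, selected=selected.reset_index(drop=True), boundary_p=boundary_p)


def null_ratio_band(
    window: int, n_windows: int, step: int = 1, conf: float = 0.99
) -> tuple[float, float]:
    """Simultaneous null band for the whole ratio curve.

    Under no group difference each interval is enhanced or repressed with
    probability 1/2 (ties are measure-zero on normalized counts), so a
    window's enhanced count is Binomial(window, 1/2).  Overlapping windows
    are strongly correlated; the per-window level is Sidak-adjusted by the
    effective number of non-overlapping windows, n_windows*step/window,
    giving a conservative simultaneous ``conf`` band for the curve.
    """
    from scipy import stats as sps

    m_eff = max(1.0, n_windows * step / window)
    alpha_per = 1.0 - conf ** (1.0 / m_eff)
    lo_q = sps.binom.ppf(alpha_per / 2, window, 0.5)
    hi_q = sps.binom.ppf(1 - alpha_per / 2, window, 0.5)
    lo = lo_q / (window - lo_q)
    hi = hi_q / (window - hi_q)
    return float(lo), float(hi)


def max_log_ratio_deviation(curve: RatioCurve) -> float:
    """Largest |log(ratio)| over the curve's defined windows (0 = perfectly flat)."""
    r = curve.points["ratio"].to_numpy()
    r = r[np.isfinite(r) & (r > 0)]
    if r.size == 0:
        return np.inf
    return float(np.abs(np.log(r)).max())


def permutation_flatness_envelope(
    norm_counts: np.ndarray,
    groups: np.ndarray,
    coords: pd.DataFrame,
    window: int = 1000,
    step: int = 1,
    n_permutations: int = 99,
    seed: int = 0,
    quantile: float = 0.99,
) -> tuple[np.ndarray, float]:
    """Exact null envelope for the curve's flatness by label permutation.

    The binomial band assumes intervals are independent with P(FC>1) = 1/2;
    real interval sets violate both (intervals of one accessible locus share
    per-library sampling noise, and normalization error shifts all intervals
    of a library together).  Permuting the genotype labels of the normalized
    count matrix preserves that correlation structure exactly, so the
    distribution of the curve's maximum |log ratio| across permutations is
    the correct null reference: under no group effect the observed curve is
    exchangeable with the permuted ones.

    Returns the permuted max-deviation values and their ``quantile``.
    """
    from .diffaccess import interval_tests

    rng = np.random.default_rng(seed)
    groups = np.asarray(groups)
    devs = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(groups)
        stats = interval_tests(norm_counts, perm)
        stats = pd.concat([coords.reset_index(drop=True), stats], axis=1)
        curve = build_ratio_curve(stats, window=window, step=step)
        devs[b] = max_log_ratio_deviation(curve)
    return devs, float(np.quantile(devs, quantile))


def plot_ratio_curve(curve: RatioCurve, path=None, cutoff: float | None = 0.60):
    """Plot ratio vs leading p-value (log10 x-axis); optionally save to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    pts = curve.points
    ax.plot(pts["leading_p"], pts["ratio"], lw=0.8, color="tab:blue")
    ax.set_xscale("log")
    ax.axhline(1.0, color="grey", lw=0.5)
    if cutoff is not None:
        ax.axhline(cutoff, color="tab:red", lw=0.5, ls="--")
    ax.set_xlabel("leading window p-value")
    ax.set_ylabel("enhanced / repressed ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
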