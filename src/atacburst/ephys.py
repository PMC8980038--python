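"""In vivo spike-train analysis: burst segmentation, %SWB, windowed metrics.

A burst opens when two consecutive spikes fall within an interval < 80 ms,
extends while inter-spike intervals stay <= 160 ms, and terminates at the
first interval > 160 ms (spikes with an ISI in the 80-160 ms zone can extend
an open burst but never open one).  %SWB is the percentage of all spikes
falling inside bursts.  Firing rate and %SWB are measured on successive 60-s
windows overlapping by 45 s (15-s step) over a 300-s epoch, giving 17 full
windows.  Dopamine neurons are identified by a triphasic waveform with a
marked negative deflection, an action-potential duration > 2.0 ms, a
start-to-trough width > 1.1 ms and a slow firing rate between 1 and 10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

BURST_ONSET_ISI = 0.080  # s; onset requires an ISI strictly below this
BURST_OFFSET_ISI = 0.160  # s; burst terminates at the first ISI strictly above


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one neuron over a recording epoch."""

    neuron_id: str
    times: np.ndarray
    duration: float = 300.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise ValueError(f"{self.neuron_id}: spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError(f"{self.neuron_id}: spike times outside [0, {self.duration}]")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def mean_rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass
class BurstSegmentation:
    """Bursts as inclusive (first_spike_index, last_spike_index) pairs."""

    bursts: list[tuple[int, int]]

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def spike_mask(self, n_spikes: int) -> np.ndarray:
        mask = np.zeros(n_spikes, dtype=bool)
        for a, b in self.bursts:
            mask[a : b + 1] = True
        return mask

    @property
    def n_burst_spikes(self) -> int:
        return sum(b - a + 1 for a, b in self.bursts)


def detect_bursts(
    train: SpikeTrain | np.ndarray,
    onset_isi: float = BURST_ONSET_ISI,
    offset_isi: float = BURST_OFFSET_ISI,
) -> BurstSegmentation:
    """Greedy left-to-right burst segmentation under the 80/160 ms rule.

    Scanning the inter-spike intervals left to right, a burst opens at the
    first ISI < ``onset_isi``, extends while the next ISI <= ``offset_isi``,
    and closes at the first ISI > ``offset_isi`` (or the end of the train).
    Scanning resumes at the spike after the closed burst, so a terminating
    boundary spike never seeds the next burst.  Every burst has >= 2 spikes.
    """
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    if times.size and (np.diff(times) <= 0).any():
        raise ValueError("spike times must be strictly increasing")
    isis = np.diff(times)
    bursts: list[tuple[int, int]] = []
    i = 0
    n_isi = isis.size
    while i < n_isi:
        if isis[i] < onset_isi:
            j = i + 1
            while j < n_isi and isis[j] <= offset_isi:
                j += 1
            bursts.append((i, j))  # spikes i..j inclusive
            i = j + 1
        else:
            i += 1
    return BurstSegmentation(bursts)


def percent_swb(train: SpikeTrain | np.ndarray, seg: BurstSegmentation | None = None) -> float:
    """Percentage of spikes within bursts (0 for an empty train)."""
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, dtype=float)
    if times.size == 0:
        return 0.0
    if seg is None:
        seg = detect_bursts(times)
    return 100.0 * seg.n_burst_spikes / times.size


@dataclass
class WindowedMetrics:
    """Per-window firing rate (Hz) and %SWB, plus across-window means."""

    windows: pd.DataFrame  # start, end, rate_hz, pct_swb, n_spikes
    mean_rate: float
    mean_pct_swb: float


def windowed_metrics(
    train: SpikeTrain,
    window: float = 60.0,
    overlap: float = 45.0,
    epoch: float | None = None,
) -> WindowedMetrics:
    """Firing rate and %SWB on successive overlapping windows.

    Windows start at 0, window-overlap, 2*(window-overlap), ... while a full
    window fits in the epoch; membership of a spike is by its timestamp
    (half-open [start, start+window)).  %SWB uses the global burst
    segmentation, so a burst spanning a window edge contributes only its
    in-window spikes.  The summary is the unweighted mean across windows.
    """
    if overlap >= window:
        raise ValueError("overlap must be smaller than window")
    if epoch is None:
        epoch = train.duration
    if window > epoch:
        raise ValueError("window longer than epoch")
    step = window - overlap
    n_win = int(np.floor((epoch - window) / step + 1e-9)) + 1
    starts = np.arange(n_win) * step
    seg = detect_bursts(train)
    burst_mask = seg.spike_mask(train.n_spikes)
    rows = []
    for s in starts:
        e = s + window
        in_win = (train.times >= s) & (train.times < e)
        n = int(in_win.sum())
        n_burst = int((in_win & burst_mask).sum())
        rows.append(
            {
                "start": s,
                "end": e,
                "n_spikes": n,
                "rate_hz": n / window,
                "pct_swb": 100.0 * n_burst / n if n else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    return WindowedMetrics(
        windows=df,
        mean_rate=float(df["rate_hz"].mean()),
        mean_pct_swb=float(df["pct_swb"].mean()),
    )


@dataclass
class NeuronFeatures:
    """Waveform/rate features used for dopamine-neuron identification."""

    triphasic_negative_deflection: bool
    ap_duration_ms: float
    start_to_trough_ms: float
    mean_rate_hz: float


def classify_dopamine(features: NeuronFeatures) -> tuple[bool, dict[str, bool]]:
    """Apply the four in vivo dopamine-neuron inclusion criteria.

    (i) triphasic action potential with a marked negative deflection;
    (ii) duration > 2.0 ms; (iii) start-to-negative-trough width > 1.1 ms;
    (iv) slow firing rate, above 1 Hz and below 10 Hz.  All four must hold.
    """
    report = {
        "triphasic": bool(features.triphasic_negative_deflection),
        "duration_gt_2ms": features.ap_duration_ms > 2.0,
        "start_to_trough_gt_1.1ms": features.start_to_trough_ms > 1.1,
        "rate_1_to_10hz": 1.0 < features.mean_rate_hz < 10.0,
    }
    return all(report.values()), report


def delta_f_over_f(f0: float, ft: float) -> float:
    """Relative fluorescence change (Ft - F0) / F0 (calcium imaging)."""
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    return (ft - f0) / f0


def read_spike_csv(path, duration: float = 300.0) -> list[SpikeTrain]:
    """Read spike trains from a CSV with columns ``neuron_id,time_s``."""
    df = pd.read_csv(path)
    if not {"neuron_id", "time_s"}.issubset(df.columns):
        raise ValueError("spike CSV needs columns neuron_id,time_s")
    trains = []
    for nid, sub in df.groupby("neuron_id", sort=False):
        trains.append(SpikeTrain(str(nid), np.sort(sub["time_s"].to_numpy()), duration))
    return trains


def summarize_trains(trains: Sequence[SpikeTrain], **window_kwargs) -> pd.DataFrame:
    """Per-neuron summary table: mean rate, %SWB, burst count, window means."""
    rows = []
    for tr in trains:
        seg = detect_bursts(tr)
        wm = windowed_metrics(tr, **window_kwargs)
        rows.append(
            {
                "neuron_id": tr.neuron_id,
                "n_spikes": tr.n_spikes,
                "mean_rate_hz": tr.mean_rate,
                "pct_swb": percent_swb(tr, seg),
                "n_bursts": seg.n_bursts,
                "window_mean_rate_hz": wm.mean_rate,
                "window_mean_pct_swb": wm.mean_pct_swb,
            }
        )
    return pd.DataFrame(rows)
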