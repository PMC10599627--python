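"""Multielectrode-array (MEA) spike-train neurotoxicity metrics.

Implements the spike-level processing used to quantify drug effects on
cultured human neurons: threshold spike detection on raw voltage traces,
active-neuron filtering (>5 spikes/min), single-neuron burst detection
(>=5 spikes with all inter-spike intervals <=100 ms), well-level network
events (>=50 pooled spikes with ISIs <=80 ms), smoothed population event
vectors, per-phase area under the curve of metric time series, and
control-normalized percent-change matrices.

Bursts and network events are maximal runs: a run cannot be extended by
any adjacent spike without violating the ISI rule, which makes the
(min spikes, max ISI) parameters the complete definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SpikeData",
    "Event",
    "detect_spikes",
    "filter_active",
    "detect_bursts",
    "detect_network_events",
    "population_vector",
    "MetricTimeSeries",
    "treatment_auc",
    "normalized_percent_change",
]


@dataclass
class SpikeData:
    """Per-neuron sorted spike timestamps within a recording window.

    ``trains`` maps neuron id -> strictly increasing timestamps (seconds);
    ``wells`` maps neuron id -> well id; ``window`` is (start, end) of the
    recording.  The 12.5 kHz acquisition rate is provenance only — all
    processing is in seconds.
    """

    trains: dict[int, np.ndarray]
    wells: dict[int, str] = field(default_factory=dict)
    window: tuple[float, float] = (0.0, 420.0)
    sampling_rate_hz: float = 12_500.0

    def __post_init__(self) -> None:
        t0, t1 = self.window
        if t1 <= t0:
            raise ValueError("recording window must have positive length")
        for n, ts in self.trains.items():
            ts = np.asarray(ts, dtype=float)
            if ts.size and ((np.diff(ts) <= 0).any() or ts[0] < t0 or ts[-1] > t1):
                raise ValueError(
                    f"neuron {n}: timestamps must be strictly increasing and "
                    "inside the recording window"
                )
            self.trains[n] = ts
            self.wells.setdefault(n, "W1")

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    def neurons(self, well: str | None = None) -> list[int]:
        if well is None:
            return sorted(self.trains)
        return sorted(n for n in self.trains if self.wells[n] == well)

    def well_ids(self) -> list[str]:
        return sorted(set(self.wells[n] for n in self.trains))

    def rate_per_min(self, neuron: int) -> float:
        return len(self.trains[neuron]) / self.duration * 60.0

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, window: tuple[float, float] | None = None
    ) -> "SpikeData":
        """Build from a long table with columns neuron, well, timestamp."""
        if window is None:
            tmax = float(df["timestamp"].max()) if len(df) else 420.0
            window = (0.0, max(tmax, 1e-9))
        trains, wells = {}, {}
        for (neuron, well), grp in df.groupby(["neuron", "well"], observed=True):
            trains[int(neuron)] = np.unique(np.asarray(grp["timestamp"], float))
            wells[int(neuron)] = str(well)
        return cls(trains=trains, wells=wells, window=window)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"neuron": n, "well": self.wells[n], "timestamp": t}
            for n in sorted(self.trains)
            for t in self.trains[n]
        ]
        return pd.DataFrame(rows, columns=["neuron", "well", "timestamp"])


@dataclass
class Event:
    """A detected burst or network event."""

    start: float
    end: float
    n_spikes: int
    neurons: tuple[int, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_spikes(
    trace: np.ndarray,
    sampling_rate_hz: float,
    threshold_sd: float = 6.0,
    noise_window_s: float = 0.010,
    refractory_s: float = 0.001,
) -> np.ndarray:
    """Detect spikes as upward crossings of an adaptive threshold.

    The threshold is the rolling mean plus ``threshold_sd`` rolling standard
    deviations of the trace (window ``noise_window_s``); a refractory
    hold-off suppresses re-triggering.  Returns sorted timestamps (s).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        return np.array([], dtype=float)
    if not np.isfinite(trace).all():
        raise ValueError("voltage trace contains non-finite values")
    w = max(int(round(noise_window_s * sampling_rate_hz)), 1)
    mean = uniform_filter1d(trace, size=w, mode="nearest")
    sq = uniform_filter1d(trace**2, size=w, mode="nearest")
    sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
    thr = mean + threshold_sd * sd
    above = trace > thr
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.insert(crossings, 0, 0)
    times = []
    last = -np.inf
    for i in crossings:
        t = i / sampling_rate_hz
        if t - last >= refractory_s:
            times.append(t)
            last = t
    return np.asarray(times, dtype=float)


def filter_active(sd: SpikeData, min_rate_per_min: float = 5.0) -> SpikeData:
    """Keep neurons firing strictly more than ``min_rate_per_min`` spikes/min."""
    if sd.duration <= 0:
        raise ValueError("zero-length recording window")
    keep = [n for n in sd.trains if sd.rate_per_min(n) > min_rate_per_min]
    return SpikeData(
        trains={n: sd.trains[n].copy() for n in keep},
        wells={n: sd.wells[n] for n in keep},
        window=sd.window,
        sampling_rate_hz=sd.sampling_rate_hz,
    )


def _maximal_runs(ts: np.ndarray, min_spikes: int, max_isi: float) -> list[tuple[int, int]]:
    """Indices (i, j) of maximal runs with all consecutive ISIs <= max_isi
    and run length >= min_spikes.  Runs are disjoint and non-extendable."""
    if ts.size == 0:
        return []
    gaps = np.flatnonzero(np.diff(ts) > max_isi)
    starts = np.concatenate(([0], gaps + 1))
    ends = np.concatenate((gaps, [ts.size - 1]))
    return [(int(i), int(j)) for i, j in zip(starts, ends) if j - i + 1 >= min_spikes]


def detect_bursts(
    sd: SpikeData, min_spikes: int = 5, max_isi: float = 0.100
) -> dict[int, list[Event]]:
    """Per-neuron bursts: maximal spike runs with every ISI <= ``max_isi``
    seconds and at least ``min_spikes`` spikes."""
    bursts: dict[int, list[Event]] = {}
    for n in sorted(sd.trains):
        ts = sd.trains[n]
        bursts[n] = [
            Event(start=float(ts[i]), end=float(ts[j]), n_spikes=j - i + 1, neurons=(n,))
            for i, j in _maximal_runs(ts, min_spikes, max_isi)
        ]
    return bursts


def detect_network_events(
    sd: SpikeData,
    min_spikes: int = 50,
    max_isi: float = 0.080,
    well: str | None = None,
) -> dict[str, list[Event]]:
    """Well-level network events on the pooled spike train of all neurons.

    The pooled timestamps of a well are sorted and the same maximal-run rule
    applied with the network thresholds; each event records the neurons
    contributing at least one spike.
    """
    wells = [well] if well is not None else sd.well_ids()
    out: dict[str, list[Event]] = {}
    for w in wells:
        neurons = sd.neurons(w)
        if not neurons:
            out[w] = []
            continue
        pooled = np.concatenate([sd.trains[n] for n in neurons])
        owner = np.concatenate([np.full(len(sd.trains[n]), n) for n in neurons])
        order = np.argsort(pooled, kind="stable")
        pooled, owner = pooled[order], owner[order]
        events = []
        for i, j in _maximal_runs(pooled, min_spikes, max_isi):
            events.append(
                Event(
                    start=float(pooled[i]),
                    end=float(pooled[j]),
                    n_spikes=j - i + 1,
                    neurons=tuple(sorted(set(owner[i : j + 1].tolist()))),
                )
            )
        out[w] = events
    return out


def population_vector(
    sd: SpikeData,
    frame: float = 0.001,
    window: float = 0.5,
    well: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed population activity: spikes binarized per neuron per frame,
    summed across neurons, then smoothed with a centered rolling mean over
    ``window`` seconds (500 ms default).

    Returns ``(times, values)`` with times at frame centers.
    """
    if frame <= 0:
        raise ValueError("frame must be positive")
    t0, t1 = sd.window
    n_frames = int(np.ceil((t1 - t0) / frame))
    neurons = sd.neurons(well)
    total = np.zeros(n_frames)
    for n in neurons:
        ts = sd.trains[n]
        if ts.size == 0:
            continue
        idx = np.minimum(((ts - t0) / frame).astype(int), n_frames - 1)
        binarized = np.zeros(n_frames, dtype=bool)
        binarized[idx] = True
        total += binarized
    w = max(int(round(window / frame)), 1)
    smoothed = uniform_filter1d(total, size=w, mode="constant")
    times = t0 + (np.arange(n_frames) + 0.5) * frame
    return times, smoothed


@dataclass
class MetricTimeSeries:
    """Per-well metric values over recording timepoints.

    ``values``: DataFrame indexed by timepoint (hours or days), one column
    per well.  ``treatment``: (start, end) of the treatment phase; earlier
    timepoints are the pretreatment baseline, later ones the recovery phase.
    """

    values: pd.DataFrame
    treatment: tuple[float, float]

    def __post_init__(self) -> None:
        idx = np.asarray(self.values.index, dtype=float)
        if (np.diff(idx) <= 0).any():
            raise ValueError("timepoints must be strictly increasing")
        if not (idx < self.treatment[0]).any():
            raise ValueError("no pretreatment baseline timepoints")

    def phase_index(self, phase: str) -> np.ndarray:
        t = np.asarray(self.values.index, dtype=float)
        start, end = self.treatment
        if phase == "treatment":
            return (t >= start) & (t <= end)
        if phase == "recovery":
            return t > end
        if phase == "pre":
            return t < start
        raise ValueError(f"unknown phase {phase!r}")


def treatment_auc(
    ts: MetricTimeSeries, phase: str = "treatment", smooth: bool = False
) -> pd.Series:
    """Trapezoidal area under each well's series over the given phase.

    With ``smooth=True`` a two-point moving average is applied to each
    series before integration, mirroring the smoothing used for display.
    """
    mask = ts.phase_index(phase)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 timepoints in phase {phase!r}")
    t = np.asarray(ts.values.index, dtype=float)[mask]
    out = {}
    for well in ts.values.columns:
        v = ts.values[well].to_numpy(dtype=float)
        if smooth:
            v = np.convolve(v, [0.5, 0.5], mode="same")
            v[0] = ts.values[well].iloc[0]  # edge keeps its raw value
        out[well] = float(np.trapezoid(v[mask], t))
    return pd.Series(out, name=f"auc_{phase}")


def normalized_percent_change(
    ts: MetricTimeSeries,
    control_wells: Sequence[str],
    mode: str = "ratio",
) -> pd.DataFrame:
    """Percent change from pretreatment, normalized to the control wells.

    Per well ``w`` and timepoint ``t`` with baseline ``v(w, pre)`` (the mean
    of the pretreatment timepoints):

    * raw percent change  ``pc(w,t) = 100 * (v(w,t)/v(w,pre) - 1)``
    * ``mode="ratio"`` (default): ratio of ratios against the mean control
      trajectory, ``100 * ((v(w,t)/v(w,pre)) / (vc(t)/vc(pre)) - 1)``
    * ``mode="subtract"``: ``pc(w,t) - pc_ctrl(t)``

    Wells with a zero baseline are reported as missing (NaN).
    """
    if mode not in ("ratio", "subtract"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [w for w in control_wells if w not in ts.values.columns]
    if missing:
        raise KeyError(f"control wells not in table: {missing}")
    pre = ts.phase_index("pre")
    base = ts.values.loc[pre].mean(axis=0)
    base = base.replace(0.0, np.nan)
    rel = ts.values / base  # v(w,t)/v(w,pre)
    ctrl_series = ts.values[list(control_wells)].mean(axis=1)
    ctrl_base = float(ctrl_series.loc[pre].mean())
    if ctrl_base == 0:
        raise ValueError("control baseline is zero")
    ctrl_rel = ctrl_series / ctrl_base
    if mode == "ratio":
        return 100.0 * (rel.div(ctrl_rel, axis=0) - 1.0)
    pc = 100.0 * (rel - 1.0)
    pc_ctrl = 100.0 * (ctrl_rel - 1.0)
    return pc.sub(pc_ctrl, axis=0)
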