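"""Spike-event containers, CSV I/O and windowing/histogram primitives.

Times are stored in seconds in files and in the :class:`Recording` container;
binning and windowing work in milliseconds with half-open 1-ms bins
``[t, t + 1 ms)``.  A spike is assigned to the most recent stimulus onset, so
each spike belongs to exactly one stimulus window; spikes after the last onset
but before the train end belong to the last stimulus.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import ProtocolError, StimulusProtocol, lem_protocol, prv_protocol

__all__ = [
    "EventsFormatError",
    "Recording",
    "CycleHistogram",
    "window_counts",
    "cycle_histogram",
    "final_sequence_histogram",
    "psth",
    "read_events",
    "write_events",
]

REGIONS = ("PrV", "LEM")
CONDITIONS = ("intact", "decorticated")
SEGMENTS = ("train", "spontaneous", "final_seq")

EVENTS_COLUMNS = (
    "neuron_id",
    "region",
    "condition",
    "segment",
    "frequency_hz",
    "trial",
    "spike_time_s",
)

_EPS_MS = 1e-9
# guard for binning/window comparisons: 1 ns in ms units, far above float
# rounding error from onset arithmetic and far below any real time structure
_BIN_EPS_MS = 1e-6


class EventsFormatError(ValueError):
    """Malformed events CSV; the message carries the offending line numbers."""


@dataclass
class Recording:
    """One neuron's spike times for a full stimulation protocol.

    ``trains`` maps ``(frequency_hz, trial)`` to sorted spike times in seconds
    relative to train onset.  ``spontaneous`` and ``final_seq_spikes`` are
    sorted spike times relative to the onset of their own segment.
    """

    neuron_id: str
    region: str
    condition: str
    protocol: StimulusProtocol
    trains: dict[tuple[float, int], np.ndarray] = field(default_factory=dict)
    spontaneous: np.ndarray = field(default_factory=lambda: np.empty(0))
    final_seq_spikes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.trains = {
            (float(f), int(tr)): np.asarray(t, dtype=float) for (f, tr), t in self.trains.items()
        }
        self.spontaneous = np.asarray(self.spontaneous, dtype=float)
        self.final_seq_spikes = np.asarray(self.final_seq_spikes, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for (f, tr), t in self.trains.items():
            self.protocol.require_frequency(f)
            if not (0 <= tr < self.protocol.repetitions):
                raise ValueError(f"trial {tr} outside protocol grid (neuron {self.neuron_id})")
            # the last stimulus owns a full period, which may extend past the
            # nominal train end into the inter-train gap
            _check_sorted_bounded(t, self.protocol.train_extent_s(f), f"train f={f} trial={tr}")
        _check_sorted_bounded(self.spontaneous, self.protocol.spontaneous_s, "spontaneous")
        _check_sorted_bounded(
            self.final_seq_spikes, self.protocol.final_seq.duration_s, "final_seq"
        )

    def trials(self, f: float) -> list[int]:
        """Trial indices recorded at frequency ``f``, sorted."""
        f = self.protocol.require_frequency(f)
        return sorted(tr for (g, tr) in self.trains if g == f)


def _check_sorted_bounded(t: np.ndarray, duration_s: float, what: str) -> None:
    if t.size == 0:
        return
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{what}: spike times not sorted")
    if t[0] < 0 or t[-1] > duration_s:
        raise ValueError(f"{what}: spike times outside [0, {duration_s}] s")


@dataclass
class CycleHistogram:
    """Per-cycle spike histogram averaged over cycles and trials."""

    period_ms: float
    bin_ms: float
    counts: np.ndarray  # mean spikes per bin per cycle
    n_cycles: int  # total cycles entering the average (cycles x trials)

    @property
    def times_ms(self) -> np.ndarray:
        """Left edges of the bins, in ms."""
        return np.arange(len(self.counts)) * self.bin_ms


def _assign_to_onsets(t_ms: np.ndarray, onsets_ms: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus index and time-since-onset for each spike (most recent onset)."""
    idx = np.searchsorted(onsets_ms, t_ms + _EPS_MS, side="right") - 1
    keep = idx >= 0
    idx = idx[keep]
    rel = t_ms[keep] - onsets_ms[idx]
    return idx, rel


def window_counts(
    rec: Recording, f: float, window_ms: tuple[float, float] = (0.0, 15.0)
) -> np.ndarray:
    """Spike counts in a half-open post-stimulus window, per stimulus and trial.

    Returns an array of shape ``(n_stimuli, n_trials)`` counting spikes with
    ``onset + a <= t < onset + b`` (times in ms). The window may not exceed the
    stimulus period.
    """
    f = rec.protocol.require_frequency(f)
    a, b = float(window_ms[0]), float(window_ms[1])
    if not (0 <= a < b):
        raise ValueError(f"invalid window [{a}, {b}) ms")
    if b - a > rec.protocol.period_ms(f) + _EPS_MS:
        raise ValueError(f"window [{a}, {b}) ms longer than the {f} Hz period")
    onsets_ms = rec.protocol.onsets_s(f) * 1000.0
    trials = rec.trials(f)
    counts = np.zeros((len(onsets_ms), len(trials)))
    for j, tr in enumerate(trials):
        t_ms = rec.trains[(f, tr)] * 1000.0
        idx, rel = _assign_to_onsets(t_ms, onsets_ms)
        sel = (rel >= a - _BIN_EPS_MS) & (rel < b - _BIN_EPS_MS)
        counts[:, j] = np.bincount(idx[sel], minlength=len(onsets_ms))
    return counts


def cycle_histogram(
    rec: Recording, f: float, exclude_first: bool = True, bin_ms: float = 1.0
) -> CycleHistogram:
    """Average cycle histogram: spikes folded modulo the stimulus period.

    Spikes are binned at ``bin_ms`` resolution relative to their own stimulus
    onset and averaged across all included cycles and trials.  By default the
    response to the first stimulus of each train is excluded so that the
    histogram reflects the adapted, steady-state response.
    """
    f = rec.protocol.require_frequency(f)
    period = rec.protocol.period_ms(f)
    n_bins = max(1, int(round(period / bin_ms)))
    n_stim = rec.protocol.n_stimuli(f)
    first = 1 if exclude_first else 0
    trials = rec.trials(f)
    cycles_per_trial = n_stim - first
    if cycles_per_trial <= 0 or not trials:
        raise ValueError(f"no cycles to average at {f} Hz")
    onsets_ms = rec.protocol.onsets_s(f) * 1000.0
    counts = np.zeros(n_bins)
    for tr in trials:
        t_ms = rec.trains[(f, tr)] * 1000.0
        idx, rel = _assign_to_onsets(t_ms, onsets_ms)
        rel = rel[idx >= first]
        bins = np.floor((rel + _BIN_EPS_MS) / bin_ms).astype(int)
        bins = bins[bins < n_bins]  # a sliver past round(period) is dropped
        counts += np.bincount(bins, minlength=n_bins)
    total_cycles = cycles_per_trial * len(trials)
    return CycleHistogram(period, bin_ms, counts / total_cycles, total_cycles)


def final_sequence_histogram(rec: Recording, bin_ms: float = 1.0) -> CycleHistogram:
    """Cycle histogram of the terminal long-pulse sequence (all pulses)."""
    fs = rec.protocol.final_seq
    n_bins = int(round(fs.period_ms / bin_ms))
    t_ms = rec.final_seq_spikes * 1000.0
    rel = np.mod(t_ms, fs.period_ms)
    bins = np.floor((rel + _BIN_EPS_MS) / bin_ms).astype(int)
    bins = bins[bins < n_bins]
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    return CycleHistogram(fs.period_ms, bin_ms, counts / fs.n_pulses, fs.n_pulses)


def psth(rec: Recording, f: float, bin_ms: float = 1.0) -> np.ndarray:
    """Peristimulus time histogram over the whole train, averaged over trials.

    Returns mean spike counts per ``bin_ms`` bin over ``[0, train_duration)``.
    """
    f = rec.protocol.require_frequency(f)
    n_bins = int(round(rec.protocol.train_duration_s * 1000.0 / bin_ms))
    trials = rec.trials(f)
    if not trials:
        raise ValueError(f"no trials at {f} Hz")
    counts = np.zeros(n_bins)
    for tr in trials:
        bins = np.floor((rec.trains[(f, tr)] * 1000.0 + _BIN_EPS_MS) / bin_ms).astype(int)
        bins = bins[bins < n_bins]
        counts += np.bincount(bins, minlength=n_bins)
    return counts / len(trials)


# ---------------------------------------------------------------------------
# events CSV
# ---------------------------------------------------------------------------


def _default_protocols() -> dict[str, StimulusProtocol]:
    return {"PrV": prv_protocol(), "LEM": lem_protocol()}


def read_events(path, protocols=None) -> list[Recording]:
    """Read an events CSV into a list of :class:`Recording`.

    ``protocols`` may be a single :class:`StimulusProtocol` (applied to every
    region) or a mapping ``region -> protocol``; by default PrV neurons get the
    full 5-s protocol and LEM neurons the reduced 2-s one.  Malformed rows,
    unknown regions/conditions and unsorted spike times are reported with their
    CSV line numbers.
    """
    if protocols is None:
        protocols = _default_protocols()
    elif isinstance(protocols, StimulusProtocol):
        protocols = {r: protocols for r in REGIONS}

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise EventsFormatError(f"missing columns: {missing}")

    errors: list[str] = []

    def bad(i: int, msg: str) -> None:
        if len(errors) < 20:
            errors.append(f"line {i + 2}: {msg}")  # +2: header + 0-based index

    seg = df["segment"].to_numpy()
    times = np.full(len(df), np.nan)
    freqs = np.full(len(df), np.nan)
    trials = np.full(len(df), -1)
    for i in range(len(df)):
        row = df.iloc[i]
        if row["region"] not in REGIONS:
            bad(i, f"unknown region {row['region']!r}")
            continue
        if row["condition"] not in CONDITIONS:
            bad(i, f"unknown condition {row['condition']!r}")
            continue
        if seg[i] not in SEGMENTS:
            bad(i, f"unknown segment {seg[i]!r}")
            continue
        try:
            times[i] = float(row["spike_time_s"])
        except ValueError:
            bad(i, f"bad spike_time_s {row['spike_time_s']!r}")
            continue
        if times[i] < 0:
            bad(i, "negative spike time")
            continue
        if seg[i] == "train":
            try:
                freqs[i] = float(row["frequency_hz"])
                trials[i] = int(row["trial"])
            except ValueError:
                bad(i, "train row needs numeric frequency_hz and trial")
                continue
        elif row["frequency_hz"] != "" or row["trial"] != "":
            bad(i, f"{seg[i]} row must leave frequency_hz and trial empty")
            continue
    if errors:
        raise EventsFormatError("; ".join(errors))

    # monotonicity within each (neuron, segment, frequency, trial) group
    key = list(zip(df["neuron_id"], seg, freqs, trials))
    last_time: dict[tuple, tuple[float, int]] = {}
    for i, k in enumerate(key):
        prev = last_time.get(k)
        if prev is not None and times[i] < prev[0]:
            bad(i, f"spike times not sorted (previous at line {prev[1] + 2})")
        last_time[k] = (times[i], i)
    if errors:
        raise EventsFormatError("; ".join(errors))

    recordings = []
    for nid, grp in df.assign(_t=times, _f=freqs, _tr=trials).groupby("neuron_id", sort=True):
        region = grp["region"].iloc[0]
        condition = grp["condition"].iloc[0]
        if grp["region"].nunique() > 1 or grp["condition"].nunique() > 1:
            raise EventsFormatError(f"neuron {nid}: inconsistent region/condition")
        proto = protocols[region]
        trains: dict[tuple[float, int], np.ndarray] = {}
        tr_rows = grp[grp["segment"] == "train"]
        if len(tr_rows) and tr_rows["_tr"].max() >= proto.repetitions:
            # simulated files may carry more repetitions than the protocol
            from dataclasses import replace as _replace

            proto = _replace(proto, repetitions=int(tr_rows["_tr"].max()) + 1)
        for (f, tr), g in tr_rows.groupby(["_f", "_tr"]):
            try:
                f = proto.require_frequency(f)
            except ProtocolError as exc:
                raise EventsFormatError(f"neuron {nid}: {exc}") from exc
            trains[(f, int(tr))] = np.sort(g["_t"].to_numpy())
        spont = np.sort(grp.loc[grp["segment"] == "spontaneous", "_t"].to_numpy())
        fin = np.sort(grp.loc[grp["segment"] == "final_seq", "_t"].to_numpy())
        recordings.append(
            Recording(
                neuron_id=str(nid),
                region=region,
                condition=condition,
                protocol=proto,
                trains=trains,
                spontaneous=spont,
                final_seq_spikes=fin,
            )
        )
    return recordings


def _fmt_time(t: float) -> str:
    return f"{t:.9f}"


def write_events(recordings, path) -> None:
    """Write recordings to the events CSV dialect (UTF-8, '.' decimal).

    Output is deterministic: neurons sorted by id, segments in train /
    spontaneous / final_seq order, trains sorted by (frequency, trial).
    """
    buf = io.StringIO()
    buf.write(",".join(EVENTS_COLUMNS) + "\n")
    for rec in sorted(recordings, key=lambda r: r.neuron_id):
        head = f"{rec.neuron_id},{rec.region},{rec.condition}"
        for (f, tr) in sorted(rec.trains):
            for t in rec.trains[(f, tr)]:
                buf.write(f"{head},train,{f:g},{tr},{_fmt_time(t)}\n")
        for t in rec.spontaneous:
            buf.write(f"{head},spontaneous,,,{_fmt_time(t)}\n")
        for t in rec.final_seq_spikes:
            buf.write(f"{head},final_seq,,,{_fmt_time(t)}\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
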