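"""Per-frequency response metrics for periodically stimulated neurons.

Four response functions characterise a neuron across the stimulation grid:

* **RRTF** (repetition rate transfer function) — mean early-window spike count
  of stimuli 2..n relative to the first stimulus; values above 1 indicate
  potentiation, below 1 adaptation.
* **TSR** (total spike rate) — total spikes evoked by an entire train, mean
  over trials; ``TSRn`` normalises the profile by its across-frequency
  maximum.
* **MRL** (mean response latency) — post-stimulus time at which the average
  cycle histogram (first stimuli excluded) first reaches 50% of its peak;
  ``MRLn`` is its across-frequency normalisation and ``MRL0`` the baseline
  latency measured from the terminal long-pulse sequence.
* **VS** (vector strength) — resultant length of unit phase vectors of all
  spikes in the train; 1 means perfect phase locking, 0 uniform phases.

Effectiveness (fraction of stimuli evoking at least one early spike) and the
RRTF restricted to effective stimuli complete the fingerprint.

Undefined metrics are represented as NaN and excluded pairwise downstream —
never imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recordings import (
    Recording,
    cycle_histogram,
    final_sequence_histogram,
    window_counts,
)

__all__ = [
    "MetricProfile",
    "METRICS",
    "half_rise_time",
    "compute_rrtf",
    "compute_tsr",
    "normalize_profile",
    "compute_mrl",
    "compute_vs",
    "compute_effectiveness",
    "compute_effective_rrtf",
    "compute_mrl0",
    "compute_profile",
    "profiles_to_frame",
]

METRICS = ("RRTF", "TSR", "MRL", "VS")

EARLY_WINDOW_MS = 15.0


def compute_rrtf(rec: Recording, f: float, early_ms: float = EARLY_WINDOW_MS) -> float:
    """Repetition rate transfer function at frequency ``f``.

    ``sp(j)`` is the mean over trials of the spike count in the first
    ``early_ms`` after the onset of stimulus ``j``; the statistic is
    ``mean(sp(2..n)) / sp(1)``.  NaN when the first stimulus evoked no spikes.
    """
    counts = window_counts(rec, f, (0.0, early_ms))
    if counts.shape[1] == 0 or counts.shape[0] < 2:
        return np.nan
    sp = counts.mean(axis=1)
    if sp[0] <= 0:
        return np.nan
    return float(sp[1:].mean() / sp[0])


def compute_tsr(rec: Recording, f: float) -> float:
    """Total spikes evoked by the whole train, mean over trials."""
    f = rec.protocol.require_frequency(f)
    trials = rec.trials(f)
    if not trials:
        return np.nan
    dur = rec.protocol.train_duration_s
    totals = [np.count_nonzero(rec.trains[(f, tr)] < dur) for tr in trials]
    return float(np.mean(totals))


def normalize_profile(values) -> np.ndarray:
    """Divide a profile by its across-frequency maximum (NaN-aware).

    NaN everywhere when the profile is all-NaN or its maximum is not positive.
    """
    v = np.asarray(values, dtype=float)
    if not np.any(np.isfinite(v)):
        return np.full_like(v, np.nan)
    m = np.nanmax(v)
    if m <= 0:
        return np.full_like(v, np.nan)
    return v / m


def half_rise_time(counts, bin_ms: float = 1.0, threshold: float = 0.5) -> float:
    """Time at which a histogram first reaches ``threshold`` x its peak.

    The crossing is linearly interpolated between the bracketing bins; when
    the response rises directly out of an empty bin the crossing is placed at
    the left edge of the first suprathreshold bin.  NaN for an empty histogram.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0 or not np.any(c > 0):
        return np.nan
    peak = c.max()
    half = threshold * peak
    k = int(np.argmax(c >= half))
    if k == 0 or c[k - 1] <= 0:
        return k * bin_ms
    return (k - 1 + (half - c[k - 1]) / (c[k] - c[k - 1])) * bin_ms


def compute_mrl(rec: Recording, f: float, threshold: float = 0.5) -> float:
    """Mean response latency (ms) from the steady-state cycle histogram."""
    try:
        hist = cycle_histogram(rec, f, exclude_first=True)
    except ValueError:
        return np.nan
    return half_rise_time(hist.counts, hist.bin_ms, threshold)


def compute_vs(rec: Recording, f: float) -> float:
    """Vector strength of phase locking to the stimulus at frequency ``f``.

    Each spike is a unit vector with phase ``2*pi*t_i/T`` where ``t_i`` is the
    time since the most recent stimulus onset and ``T`` the stimulus period;
    VS is the length of the mean resultant, pooled over all trials.
    """
    from .recordings import _assign_to_onsets  # shared onset-assignment rule

    f = rec.protocol.require_frequency(f)
    period = rec.protocol.period_ms(f)
    onsets_ms = rec.protocol.onsets_s(f) * 1000.0
    phases = []
    for tr in rec.trials(f):
        t_ms = rec.trains[(f, tr)] * 1000.0
        _, rel = _assign_to_onsets(t_ms, onsets_ms)
        phases.append(2.0 * np.pi * rel / period)
    theta = np.concatenate(phases) if phases else np.empty(0)
    if theta.size == 0:
        return np.nan
    return float(np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / theta.size)


def compute_effectiveness(rec: Recording, f: float, window_ms: float = EARLY_WINDOW_MS) -> float:
    """Fraction of delivered stimuli that evoke >= 1 early-window spike.

    Stimulus presentations are pooled over trials: the denominator is
    ``n_stimuli(f) * n_trials``.
    """
    counts = window_counts(rec, f, (0.0, window_ms))
    if counts.size == 0:
        return np.nan
    return float(np.count_nonzero(counts > 0) / counts.size)


def compute_effective_rrtf(rec: Recording, f: float, early_ms: float = EARLY_WINDOW_MS) -> float:
    """RRTF computed over effective stimuli only.

    For each stimulus index the early count is averaged over the trials in
    which that stimulus was effective (evoked >= 1 spike); the first index
    that was ever effective plays the role of the reference stimulus.  NaN
    when fewer than two stimulus indices were ever effective.
    """
    counts = window_counts(rec, f, (0.0, early_ms))
    if counts.size == 0:
        return np.nan
    eff = counts > 0
    with np.errstate(invalid="ignore"):
        sp_eff = np.where(eff.any(axis=1), (counts * eff).sum(axis=1) / eff.sum(axis=1), np.nan)
    defined = np.flatnonzero(np.isfinite(sp_eff))
    if defined.size < 2:
        return np.nan
    j0 = defined[0]
    rest = sp_eff[defined[1:]]
    return float(rest.mean() / sp_eff[j0])


def compute_mrl0(rec: Recording, threshold: float = 0.5) -> float:
    """Baseline latency (ms) from the terminal long-pulse sequence."""
    if rec.final_seq_spikes.size == 0:
        return np.nan
    hist = final_sequence_histogram(rec)
    return half_rise_time(hist.counts, hist.bin_ms, threshold)


@dataclass
class MetricProfile:
    """Per-frequency metric fingerprint of one neuron."""

    frequencies_hz: np.ndarray
    rrtf: np.ndarray
    tsr: np.ndarray
    tsrn: np.ndarray
    mrl_ms: np.ndarray
    mrln: np.ndarray
    vs: np.ndarray
    effectiveness: np.ndarray
    rrtf_effective: np.ndarray
    mrl0_ms: float

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        n = self.frequencies_hz.size
        for name in ("rrtf", "tsr", "tsrn", "mrl_ms", "mrln", "vs", "effectiveness", "rrtf_effective"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            setattr(self, name, arr)

    def values(self, metric: str) -> np.ndarray:
        """Raw values of one of the four response functions."""
        return {
            "RRTF": self.rrtf,
            "TSR": self.tsr,
            "MRL": self.mrl_ms,
            "VS": self.vs,
        }[metric.upper()]

    def at(self, f: float) -> dict[str, float]:
        i = int(np.argmin(np.abs(self.frequencies_hz - f)))
        if abs(self.frequencies_hz[i] - f) > 1e-9:
            raise ValueError(f"{f} Hz not in profile grid")
        return {m: float(self.values(m)[i]) for m in METRICS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies_hz,
                "rrtf": self.rrtf,
                "tsr": self.tsr,
                "tsrn": self.tsrn,
                "mrl_ms": self.mrl_ms,
                "mrln": self.mrln,
                "vs": self.vs,
                "effectiveness": self.effectiveness,
                "rrtf_effective": self.rrtf_effective,
                "mrl0_ms": self.mrl0_ms,
            }
        )


def compute_profile(rec: Recording, early_ms: float = EARLY_WINDOW_MS) -> MetricProfile:
    """Compute the full metric fingerprint of one recording.

    When the terminal long-pulse sequence is absent the baseline latency falls
    back to the smallest defined per-frequency MRL.
    """
    freqs = np.asarray(rec.protocol.frequencies_hz)
    rrtf = np.array([compute_rrtf(rec, f, early_ms) for f in freqs])
    tsr = np.array([compute_tsr(rec, f) for f in freqs])
    mrl = np.array([compute_mrl(rec, f) for f in freqs])
    vs = np.array([compute_vs(rec, f) for f in freqs])
    eff = np.array([compute_effectiveness(rec, f, early_ms) for f in freqs])
    rrtf_eff = np.array([compute_effective_rrtf(rec, f, early_ms) for f in freqs])
    mrl0 = compute_mrl0(rec)
    if not np.isfinite(mrl0) and np.any(np.isfinite(mrl)):
        mrl0 = float(np.nanmin(mrl))
    return MetricProfile(
        frequencies_hz=freqs,
        rrtf=rrtf,
        tsr=tsr,
        tsrn=normalize_profile(tsr),
        mrl_ms=mrl,
        mrln=normalize_profile(mrl),
        vs=vs,
        effectiveness=eff,
        rrtf_effective=rrtf_eff,
        mrl0_ms=mrl0,
    )


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Long-format table (one row per neuron x frequency) of metric profiles."""
    frames = []
    for nid, prof in profiles.items():
        df = prof.to_frame()
        df.insert(0, "neuron_id", nid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["neuron_id"])
    return pd.concat(frames, ignore_index=True)
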