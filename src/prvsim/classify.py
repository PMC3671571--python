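"""Filtering-profile (LP/HP/BP/NF) and tonic/phasic classification.

A metric profile over the stimulation grid is labelled band-pass (BP) when
some interior frequency exceeds the mean of its two adjacent measured
frequencies by at least 20%, no-filtering (NF) when all values stay within
10% of the profile mean, and otherwise low-pass (LP) or high-pass (HP)
according to the trend between the lowest and highest thirds of the grid.

For latency profiles (MRL) the LP/HP sense is inverted: a latency that grows
with stimulation frequency degrades transmission of fast stimuli and is the
latency signature of a low-pass neuron, so a rising MRL profile is labelled
LP (and a falling one HP).  BP and NF are unaffected.

Band-pass peaks are located relative to the rodent whisking range: below
(W_BE, < 4 Hz), inside (W_IN) and above (W_AB) whisking.  The upper edge of
the whisking band defaults to 12 Hz and is configurable (14 Hz is also in
common use).

The tonic/phasic distinction is made from responses to long (100-ms) pulses:
tonic (slowly adapting) neurons keep firing through the pulse while phasic
(rapidly adapting) neurons respond only at its onset.  The sustained ratio —
spikes in (25, 100] ms over spikes in [0, 25] ms, pooled over pulses — is
thresholded at 0.2 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recordings import Recording, _assign_to_onsets

__all__ = [
    "UnclassifiableError",
    "ProfileClass",
    "NeuronClass",
    "BANDS",
    "band_of",
    "classify_profile",
    "classify_profiles",
    "classify_neuron",
    "bp_peak_distribution",
]

BANDS = ("W_BE", "W_IN", "W_AB")

DEFAULT_BAND_EDGES = (4.0, 12.0)

#: Metrics whose LP/HP trend sense is inverted (latency-like: bigger = slower).
LATENCY_METRICS = ("MRL",)


class UnclassifiableError(ValueError):
    """Raised when a profile or neuron cannot be assigned a label."""


@dataclass(frozen=True)
class ProfileClass:
    """LP/HP/BP/NF label of one metric of one neuron."""

    metric: str
    label: str
    bp_peak_hz: float | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        if (self.label == "BP") != (self.bp_peak_hz is not None):
            raise ValueError("bp_peak_hz must be present iff label is BP")


@dataclass(frozen=True)
class NeuronClass:
    """Tonic/phasic label with the sustained-response ratio it derives from."""

    label: str
    sustained_ratio: float


def band_of(f: float, edges: tuple[float, float] = DEFAULT_BAND_EDGES) -> str:
    """Whisking band of a frequency: W_BE below, W_IN inside, W_AB above."""
    low, high = edges
    if f <= 0:
        raise ValueError("frequency must be positive")
    if f < low:
        return "W_BE"
    if f <= high:
        return "W_IN"
    return "W_AB"


def classify_profile(
    frequencies,
    values,
    metric: str = "",
    *,
    bp_excess: float = 0.20,
    nf_deviation: float = 0.10,
    band_edges: tuple[float, float] = DEFAULT_BAND_EDGES,
    latency_like: bool | None = None,
) -> ProfileClass:
    """Assign the LP/HP/BP/NF label to one metric profile.

    Decision order: BP first (an interior frequency at least ``bp_excess``
    above the mean of its two adjacent measured frequencies; the largest
    relative excess picks the peak), then NF (all deviations from the profile
    mean within ``nf_deviation``), then the LP/HP trend (means of the lowest
    vs highest third of the measured grid; exact ties fall back to NF).  The
    classification is a pure function of values and thresholds, and invariant
    to positive rescaling of the profile.
    """
    freqs = np.asarray(frequencies, dtype=float)
    vals = np.asarray(values, dtype=float)
    if freqs.shape != vals.shape:
        raise ValueError("frequencies and values must have the same shape")
    if latency_like is None:
        latency_like = metric.upper() in LATENCY_METRICS

    defined = np.isfinite(vals)
    if defined.sum() < 5:
        raise UnclassifiableError(
            f"{metric or 'profile'}: only {int(defined.sum())} defined frequencies (need >= 5)"
        )
    fd, vd = freqs[defined], vals[defined]

    # (1) band-pass: interior point >= (1 + bp_excess) x neighbour mean
    best_excess, best_peak = 0.0, None
    for i in range(1, len(vd) - 1):
        neigh = 0.5 * (vd[i - 1] + vd[i + 1])
        if neigh > 0:
            excess = vd[i] / neigh - 1.0
            if excess >= bp_excess and excess > best_excess:
                best_excess, best_peak = excess, fd[i]
    if best_peak is not None:
        return ProfileClass(metric, "BP", float(best_peak), band_of(best_peak, band_edges))

    # (2) no-filtering: flat relative to the profile mean
    mean = vd.mean()
    if mean > 0 and np.max(np.abs(vd - mean)) / mean <= nf_deviation:
        return ProfileClass(metric, "NF")
    if mean <= 0:  # all-zero profile carries no trend
        return ProfileClass(metric, "NF")

    # (3) trend between lowest and highest thirds of the measured grid
    k = max(1, len(vd) // 3)
    low, high = vd[:k].mean(), vd[-k:].mean()
    if low == high:
        return ProfileClass(metric, "NF")
    label = "LP" if low > high else "HP"
    if latency_like:
        label = "HP" if label == "LP" else "LP"
    return ProfileClass(metric, label)


def classify_profiles(profile, **kwargs) -> dict[str, ProfileClass]:
    """Label all four response functions of a :class:`MetricProfile`.

    Metrics with too few defined frequencies are omitted from the result.
    """
    from .metrics import METRICS

    out = {}
    for m in METRICS:
        try:
            out[m] = classify_profile(profile.frequencies_hz, profile.values(m), m, **kwargs)
        except UnclassifiableError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return out


def classify_neuron(
    rec: Recording,
    threshold: float = 0.2,
    split_ms: float = 25.0,
    window_ms: float = 100.0,
) -> NeuronClass:
    """Tonic/phasic label from the sustained-response ratio.

    Uses the terminal 100-ms-pulse sequence when present; otherwise falls back
    to the trains at the lowest stimulation frequency.  The ratio is spikes in
    ``(split, window]`` ms over spikes in ``[0, split]`` ms after pulse onset,
    pooled over pulses (and trials for the fallback).
    """
    if rec.final_seq_spikes.size:
        fs = rec.protocol.final_seq
        onsets = np.arange(fs.n_pulses) * fs.period_ms
        _, rel = _assign_to_onsets(rec.final_seq_spikes * 1000.0, onsets)
        rels = [rel]
    else:
        f = rec.protocol.frequencies_hz[0]
        if rec.protocol.period_ms(f) < window_ms:
            raise UnclassifiableError(
                f"lowest-frequency period shorter than the {window_ms} ms window"
            )
        onsets = rec.protocol.onsets_s(f) * 1000.0
        rels = []
        for tr in rec.trials(f):
            _, rel = _assign_to_onsets(rec.trains[(f, tr)] * 1000.0, onsets)
            rels.append(rel)
    rel = np.concatenate(rels) if rels else np.empty(0)
    early = int(np.count_nonzero(rel <= split_ms))
    late = int(np.count_nonzero((rel > split_ms) & (rel <= window_ms)))
    if early == 0:
        raise UnclassifiableError(f"neuron {rec.neuron_id}: no onset spikes")
    ratio = late / early
    return NeuronClass("tonic" if ratio >= threshold else "phasic", ratio)


def bp_peak_distribution(
    classes, edges: tuple[float, float] = DEFAULT_BAND_EDGES
) -> dict[str, int]:
    """Tally band-pass peak frequencies by whisking band."""
    tally = {b: 0 for b in BANDS}
    for pc in classes:
        if pc.label == "BP":
            tally[band_of(pc.bp_peak_hz, edges)] += 1
    return tally
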