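"""Stimulation protocol for periodic whisker air-puff experiments.

A protocol is a grid of stimulation frequencies delivered as fixed-length
trains of brief air puffs, repeated a number of times per frequency, preceded
by a spontaneous-activity segment and terminated by a slow sequence of long
pulses used to measure a baseline response latency.

The first stimulus of a train is delivered at t = 0, so a train of duration
``D`` seconds at frequency ``f`` contains ``floor(D * f) + 1`` stimuli: a 5-s
train holds 6 stimuli at 1 Hz and 11 at 2 Hz.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

__all__ = [
    "ProtocolError",
    "FinalSequence",
    "StimulusProtocol",
    "PRV_FREQUENCIES_HZ",
    "LEM_FREQUENCIES_HZ",
    "prv_protocol",
    "lem_protocol",
]

#: Full 13-frequency grid used for brainstem (PrV) recordings.
PRV_FREQUENCIES_HZ = (1.0, 2.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0, 20.0, 25.0, 30.0, 35.0, 40.0)

#: Reduced 9-frequency grid used for medial-lemniscus (LEM) recordings.
LEM_FREQUENCIES_HZ = (3.0, 5.0, 8.0, 10.0, 12.0, 15.0, 20.0, 30.0, 40.0)

_FREQ_TOL = 1e-9


class ProtocolError(ValueError):
    """Raised for requests inconsistent with the stimulation protocol."""


@dataclass(frozen=True)
class FinalSequence:
    """Terminal sequence of long pulses delivered at a slow, fixed rate."""

    n_pulses: int = 50
    pulse_ms: float = 100.0
    rate_hz: float = 1.0

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_pulses / self.rate_hz


@dataclass(frozen=True)
class StimulusProtocol:
    """The stimulation grid from which per-train stimulus onsets derive.

    Parameters
    ----------
    frequencies_hz
        Strictly increasing stimulation frequencies, all positive.
    train_duration_s
        Length of one stimulus train (5 s for PrV, 2 s for the reduced
        lemniscal protocol).
    pulse_duration_ms
        Air-puff length within each cycle.
    repetitions
        Number of trains delivered per frequency.
    inter_train_s
        Silent gap between consecutive trains.
    spontaneous_s
        Duration of the pre-protocol spontaneous segment.
    final_seq
        The terminal long-pulse sequence.
    """

    frequencies_hz: tuple[float, ...] = PRV_FREQUENCIES_HZ
    train_duration_s: float = 5.0
    pulse_duration_ms: float = 14.0
    repetitions: int = 10
    inter_train_s: float = 3.0
    spontaneous_s: float = 180.0
    final_seq: FinalSequence = field(default_factory=FinalSequence)

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies_hz)
        object.__setattr__(self, "frequencies_hz", freqs)
        if not freqs:
            raise ProtocolError("protocol needs at least one stimulation frequency")
        if any(f <= 0 for f in freqs):
            raise ProtocolError("stimulation frequencies must be positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ProtocolError("stimulation frequencies must be strictly increasing")
        if self.train_duration_s <= 0:
            raise ProtocolError("train duration must be positive")
        if self.repetitions < 1:
            raise ProtocolError("repetitions must be >= 1")

    # -- grid queries ----------------------------------------------------

    def require_frequency(self, f: float) -> float:
        """Return the grid frequency matching ``f`` or raise ProtocolError."""
        for g in self.frequencies_hz:
            if abs(g - f) <= _FREQ_TOL:
                return g
        raise ProtocolError(f"{f} Hz is not a protocol frequency {self.frequencies_hz}")

    def n_stimuli(self, f: float) -> int:
        """Number of stimuli delivered in one train at frequency ``f``."""
        f = self.require_frequency(f)
        return int(math.floor(self.train_duration_s * f + _FREQ_TOL)) + 1

    def onsets_s(self, f: float) -> np.ndarray:
        """Stimulus onset times (s) within one train; first onset at 0."""
        f = self.require_frequency(f)
        return np.arange(self.n_stimuli(f), dtype=float) / f

    def period_ms(self, f: float) -> float:
        return 1000.0 / self.require_frequency(f)

    def train_extent_s(self, f: float) -> float:
        """End of the last stimulus window: ``n_stimuli(f) / f`` seconds.

        The last stimulus of a train may fall at (or just before) the nominal
        train end; its response is still recorded during the inter-train gap,
        so each stimulus owns a full period.
        """
        f = self.require_frequency(f)
        return max(self.train_duration_s, self.n_stimuli(f) / f)

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frequencies_hz"] = list(self.frequencies_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        if "final_seq" in d and isinstance(d["final_seq"], dict):
            d["final_seq"] = FinalSequence(**d["final_seq"])
        return cls(**d)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "StimulusProtocol":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def prv_protocol() -> StimulusProtocol:
    """Default full protocol: 5-s trains, 13 frequencies, 10 repetitions."""
    return StimulusProtocol()


def lem_protocol() -> StimulusProtocol:
    """Reduced lemniscal protocol: 2-s trains over 9 frequencies."""
    return StimulusProtocol(frequencies_hz=LEM_FREQUENCIES_HZ, train_duration_s=2.0)
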