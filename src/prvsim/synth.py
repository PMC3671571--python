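"""Synthetic neuron populations and spike-train datasets.

The generator emulates the recording protocol (5-s trains of 14-ms air puffs
at 13 frequencies between 1 and 40 Hz, 10 repetitions, a 180-s spontaneous
segment and a final sequence of 50 100-ms pulses at 1 Hz) for populations of
archetypal neurons:

* ``tonic_intact`` — slowly adapting brainstem neuron: band-pass RRTF with a
  potentiation peak inside the whisking range, a train total that grows with
  stimulus count but inherits the potentiation bump (band-pass TSR), latency
  growing with frequency (LP by the latency convention) and low-pass VS.
* ``phasic_intact`` — rapidly adapting neuron: sharp onset transient, steeply
  low-pass RRTF, no sustained firing.
* ``tonic_decorticated`` — tonic archetype at reduced excitability (lower
  rates, weaker potentiation, longer latencies).
* ``lem_projecting`` — the thalamic-projecting archetype as recorded in the
  medial lemniscus: tonic-like shapes at higher RRTF/latency/VS levels, used
  both for LEM reference populations and as a planted subpopulation among
  tonic brainstem neurons.

TSR curves are not free parameters: the per-frequency train total is derived
from the archetype's r0 template, RRTF curve and a late-gain curve through
the same expected-count identity the simulator enforces, so the generator is
self-consistent with the rate model by construction.

Profile noise is a per-neuron, per-metric lognormal gain (default sigma 0.10)
plus small independent per-frequency lognormal jitter (default sigma 0.04);
whole-profile gains leave filtering labels unchanged (all rules are relative)
while the per-frequency jitter perturbs them realistically.  All randomness
flows through one seeded generator; identical seeds give byte-identical
event files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import warnings

import numpy as np

from .classify import classify_profile
from .metrics import MetricProfile, half_rise_time, normalize_profile
from .protocol import StimulusProtocol, prv_protocol
from .recordings import Recording
from .simulate import RateBuildError, RateModel, expected_train_total, simulate_train

__all__ = [
    "R0Params",
    "NeuronArchetype",
    "ARCHETYPES",
    "SyntheticNeuron",
    "r0_template",
    "pulse_rate",
    "archetype_profile",
    "archetype_labels",
    "sample_profile_values",
    "generate_population",
    "generate_dataset",
]

DEFAULT_NOISE = 0.10  # per-neuron, per-metric lognormal gain sigma
DEFAULT_FREQ_NOISE = 0.04  # per-frequency lognormal jitter sigma

VS_CEILING = 1.0


@dataclass(frozen=True)
class R0Params:
    """First-stimulus rate template: onset transient + sustained component."""

    latency_ms: float
    peak_per_ms: float
    decay_ms: float
    sustained_per_ms: float
    spont_hz: float


@dataclass(frozen=True)
class NeuronArchetype:
    """Parametric response curves and rate template of one neuron class."""

    name: str
    neuron_type: str  # 'tonic' | 'phasic'
    rrtf: Callable[[np.ndarray], np.ndarray]
    mrl: Callable[[np.ndarray], np.ndarray]
    vs: Callable[[np.ndarray], np.ndarray]
    late_gain: object  # scalar, or a curve over frequency
    r0: R0Params

    def late_gain_at(self, f) -> np.ndarray:
        g = self.late_gain(f) if callable(self.late_gain) else self.late_gain
        return np.broadcast_to(np.asarray(g, dtype=float), np.shape(f)).copy()


def _lp(base: float, amp: float, tau: float):
    return lambda f: base + amp * np.exp(-np.asarray(f, dtype=float) / tau)


def _rise(base: float, amp: float, tau: float):
    return lambda f: base + amp * (1.0 - np.exp(-np.asarray(f, dtype=float) / tau))


def _bp(base: float, amp: float, peak: float, width: float):
    return lambda f: base + amp * np.exp(-((np.asarray(f, dtype=float) - peak) ** 2) / (2 * width**2))


def _vs_curve(base_instability: float, amp: float, tau: float):
    """Phase-locking curve: VS near 1, instability 1-VS growing with f."""
    return lambda f: 1.0 - (
        base_instability + amp * (1.0 - np.exp(-np.asarray(f, dtype=float) / tau))
    )


ARCHETYPES: dict[str, NeuronArchetype] = {
    "tonic_intact": NeuronArchetype(
        name="tonic_intact",
        neuron_type="tonic",
        rrtf=_bp(0.70, 0.80, 10.0, 1.5),
        mrl=_rise(5.0, 4.0, 15.0),
        vs=_vs_curve(0.05, 0.30, 18.0),
        late_gain=0.9,
        r0=R0Params(latency_ms=4.0, peak_per_ms=0.45, decay_ms=6.0,
                    sustained_per_ms=0.05, spont_hz=1.5),
    ),
    "phasic_intact": NeuronArchetype(
        name="phasic_intact",
        neuron_type="phasic",
        rrtf=_lp(0.03, 1.00, 5.0),
        mrl=_rise(4.0, 2.0, 15.0),
        vs=_vs_curve(0.03, 0.22, 18.0),
        late_gain=0.3,
        r0=R0Params(latency_ms=3.0, peak_per_ms=0.80, decay_ms=2.5,
                    sustained_per_ms=0.0, spont_hz=0.5),
    ),
    "tonic_decorticated": NeuronArchetype(
        name="tonic_decorticated",
        neuron_type="tonic",
        rrtf=_bp(0.55, 0.55, 8.0, 1.5),
        mrl=_rise(7.0, 5.0, 12.0),
        vs=_vs_curve(0.04, 0.24, 25.0),
        late_gain=0.7,
        r0=R0Params(latency_ms=5.0, peak_per_ms=0.30, decay_ms=6.0,
                    sustained_per_ms=0.03, spont_hz=0.8),
    ),
    # The projecting archetype sits a uniform ~1.6x away from tonic_intact in
    # every metric (less adaptation, longer latencies, steadier locking, more
    # spikes), mirroring the clear cluster separation of lemniscal references.
    "lem_projecting": NeuronArchetype(
        name="lem_projecting",
        neuron_type="tonic",
        rrtf=_bp(1.15, 0.90, 10.0, 1.5),
        mrl=_rise(8.0, 4.5, 15.0),
        vs=_vs_curve(0.015, 0.24, 18.0),
        # sustained-response resonance in the whisking band carries the
        # train-total potentiation peak (late rates are far from the
        # 1 spike/bin ceiling, unlike the latency-compressed early window)
        late_gain=_bp(1.0, 1.2, 10.0, 1.5),
        r0=R0Params(latency_ms=7.0, peak_per_ms=0.40, decay_ms=8.0,
                    sustained_per_ms=0.06, spont_hz=2.0),
    ),
}


def r0_template(params: R0Params, n_bins: int = 1000, pulse_ms: float = 14.0) -> np.ndarray:
    """First-stimulus rate (spikes per 1-ms bin) for a short air puff."""
    t = np.arange(n_bins) + 0.5
    r = np.full(n_bins, params.spont_hz / 1000.0)
    on = t >= params.latency_ms
    r[on] += params.peak_per_ms * np.exp(-(t[on] - params.latency_ms) / params.decay_ms)
    r[on & (t < params.latency_ms + pulse_ms)] += params.sustained_per_ms
    return r


def pulse_rate(params: R0Params, pulse_ms: float = 100.0, period_ms: float = 1000.0) -> np.ndarray:
    """Rate over one long-pulse cycle: onset transient + sustained firing.

    Tonic archetypes keep their sustained component for the whole pulse;
    phasic ones respond only at onset.
    """
    n_bins = int(round(period_ms))
    t = np.arange(n_bins) + 0.5
    r = np.full(n_bins, params.spont_hz / 1000.0)
    on = t >= params.latency_ms
    r[on] += params.peak_per_ms * np.exp(-(t[on] - params.latency_ms) / params.decay_ms)
    r[on & (t < pulse_ms)] += params.sustained_per_ms
    return r


def _derive_tsr(
    r0: np.ndarray,
    rrtf: np.ndarray,
    mrl: np.ndarray,
    mrl0: float,
    late_gain,
    protocol: StimulusProtocol,
) -> np.ndarray:
    gains = np.broadcast_to(np.asarray(late_gain, dtype=float), mrl.shape)
    tsr = np.empty_like(rrtf)
    for i, f in enumerate(protocol.frequencies_hz):
        t1 = max(0.0, mrl[i] - mrl0)
        tsr[i] = expected_train_total(r0, protocol, f, rrtf[i], gains[i], t1)
    return tsr


def archetype_profile(
    arch: NeuronArchetype, protocol: StimulusProtocol | None = None
) -> tuple[MetricProfile, np.ndarray, float]:
    """Noiseless metric profile of an archetype (plus its r0 and MRL0)."""
    protocol = protocol or prv_protocol()
    freqs = np.asarray(protocol.frequencies_hz)
    r0 = r0_template(arch.r0, pulse_ms=protocol.pulse_duration_ms)
    mrl0 = half_rise_time(r0)
    rrtf = arch.rrtf(freqs)
    mrl = arch.mrl(freqs)
    vs = np.clip(arch.vs(freqs), 0.0, VS_CEILING)  # curves stay below 1 by design
    tsr = _derive_tsr(r0, rrtf, mrl, mrl0, arch.late_gain_at(freqs), protocol)
    nan = np.full(freqs.shape, np.nan)
    profile = MetricProfile(
        frequencies_hz=freqs,
        rrtf=rrtf,
        tsr=tsr,
        tsrn=normalize_profile(tsr),
        mrl_ms=mrl,
        mrln=normalize_profile(mrl),
        vs=vs,
        effectiveness=nan.copy(),
        rrtf_effective=nan.copy(),
        mrl0_ms=mrl0,
    )
    return profile, r0, mrl0


_LABEL_CACHE: dict[tuple[str, tuple], dict[str, str]] = {}


def archetype_labels(arch: NeuronArchetype, protocol: StimulusProtocol | None = None) -> dict[str, str]:
    """Ground-truth filtering labels: the classifier's zero-noise output."""
    protocol = protocol or prv_protocol()
    key = (arch.name, protocol.frequencies_hz)
    if key not in _LABEL_CACHE:
        profile, _, _ = archetype_profile(arch, protocol)
        labels = {}
        for m in ("RRTF", "TSR", "MRL", "VS"):
            labels[m] = classify_profile(profile.frequencies_hz, profile.values(m), m).label
        _LABEL_CACHE[key] = labels
    return _LABEL_CACHE[key]


def sample_profile_values(
    arch: NeuronArchetype,
    metric: str,
    n: int,
    rng: np.random.Generator,
    noise: float = DEFAULT_NOISE,
    freq_noise: float = DEFAULT_FREQ_NOISE,
    frequencies=None,
) -> np.ndarray:
    """Draw ``n`` noisy copies of one archetype metric curve (rows = neurons).

    Convenience sampler for statistical null experiments; the curve is scaled
    by a per-neuron lognormal gain and per-frequency lognormal jitter exactly
    as in :func:`generate_population`.
    """
    freqs = np.asarray(frequencies if frequencies is not None else prv_protocol().frequencies_hz)
    curve = {"RRTF": arch.rrtf, "MRL": arch.mrl, "VS": arch.vs}[metric.upper()](freqs)
    gains = np.exp(noise * rng.standard_normal((n, 1)))
    jitter = np.exp(freq_noise * rng.standard_normal((n, freqs.size)))
    if metric.upper() == "VS":  # noise acts on the instability 1 - VS
        return np.clip(1.0 - (1.0 - curve[None, :]) * gains * jitter, 0.0, 1.0)
    return curve[None, :] * gains * jitter


@dataclass
class SyntheticNeuron:
    """One generated neuron: profile, rate templates and ground truth."""

    neuron_id: str
    archetype: str
    neuron_type: str
    profile: MetricProfile
    r0: np.ndarray
    pulse_r: np.ndarray
    mrl0_ms: float
    spont_hz: float
    true_labels: dict[str, str]


def generate_population(
    counts: dict[str, int],
    *,
    noise: float = DEFAULT_NOISE,
    freq_noise: float = DEFAULT_FREQ_NOISE,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
) -> list[SyntheticNeuron]:
    """Generate a neuron population with prescribed archetype counts.

    ``counts`` maps archetype name to a nonnegative neuron count (a
    composition mirroring the recorded populations would be, e.g., 105 tonic
    to 39 phasic with a 15-neuron projecting subpopulation planted among the
    tonic ones).  Reproducible given ``seed``; ``noise=0`` returns the
    archetype curves exactly.
    """
    protocol = protocol or prv_protocol()
    rng = np.random.default_rng(seed)
    freqs = np.asarray(protocol.frequencies_hz)
    neurons: list[SyntheticNeuron] = []
    idx = 0
    for name, count in counts.items():
        if count < 0:
            raise ValueError(f"negative count for archetype {name!r}")
        arch = ARCHETYPES[name]
        labels = archetype_labels(arch, protocol)
        base_r0 = r0_template(arch.r0, pulse_ms=protocol.pulse_duration_ms)
        base_pulse = pulse_rate(
            arch.r0,
            pulse_ms=protocol.final_seq.pulse_ms,
            period_ms=protocol.final_seq.period_ms,
        )
        for _ in range(count):
            g = {k: np.exp(noise * rng.standard_normal()) for k in ("rrtf", "mrl", "vs", "r0", "late")}
            jit = {
                k: np.exp(freq_noise * rng.standard_normal(freqs.size))
                for k in ("rrtf", "mrl", "vs", "late")
            }
            rrtf = arch.rrtf(freqs) * g["rrtf"] * jit["rrtf"]
            mrl = arch.mrl(freqs) * g["mrl"] * jit["mrl"]
            # VS is bounded by 1: the lognormal noise scales the instability
            # 1 - VS, keeping near-perfect phase locking near-perfect
            vs = np.clip(1.0 - (1.0 - arch.vs(freqs)) * g["vs"] * jit["vs"], 0.0, 1.0)
            r0 = base_r0 * g["r0"]
            mrl0 = half_rise_time(r0)
            late = arch.late_gain_at(freqs) * g["late"] * jit["late"]
            tsr = _derive_tsr(r0, rrtf, mrl, mrl0, late, protocol)
            nan = np.full(freqs.shape, np.nan)
            profile = MetricProfile(
                frequencies_hz=freqs,
                rrtf=rrtf,
                tsr=tsr,
                tsrn=normalize_profile(tsr),
                mrl_ms=mrl,
                mrln=normalize_profile(mrl),
                vs=vs,
                effectiveness=nan.copy(),
                rrtf_effective=nan.copy(),
                mrl0_ms=mrl0,
            )
            neurons.append(
                SyntheticNeuron(
                    neuron_id=f"{name}_{idx:03d}",
                    archetype=name,
                    neuron_type=arch.neuron_type,
                    profile=profile,
                    r0=r0,
                    pulse_r=base_pulse * g["r0"],
                    mrl0_ms=mrl0,
                    spont_hz=arch.r0.spont_hz,
                    true_labels=dict(labels),
                )
            )
            idx += 1
    return neurons


def _simulate_final_sequence(neuron: SyntheticNeuron, protocol, rng) -> np.ndarray:
    fs = protocol.final_seq
    n_bins = int(round(fs.period_ms))
    rate = np.clip(neuron.pulse_r[:n_bins], 0.0, 1.0)
    u = rng.random((fs.n_pulses, n_bins))
    pulse_idx, bins = np.nonzero(u < rate[None, :])
    times_ms = pulse_idx * fs.period_ms + bins + 0.5
    return np.sort(times_ms) / 1000.0


def generate_dataset(
    population,
    *,
    protocol: StimulusProtocol | None = None,
    region: str = "PrV",
    condition: str = "intact",
    seed: int = 0,
    trials: int | None = None,
    include_spontaneous: bool = True,
    include_final_seq: bool = True,
    jitter_sigma_ms: float = 1.0,
) -> list[Recording]:
    """Simulate the full protocol for every neuron of a population.

    Trains for every frequency and repetition, a homogeneous-Poisson
    spontaneous segment at each neuron's spontaneous rate, and the terminal
    long-pulse sequence.  Deterministic given ``seed`` (one independent
    substream per neuron).
    """
    protocol = protocol or prv_protocol()
    n_trials = trials if trials is not None else protocol.repetitions
    recordings = []
    for i, nrn in enumerate(population):
        rng = np.random.default_rng([seed, i])
        model = RateModel(r0=nrn.r0, profile=nrn.profile, mrl0_ms=nrn.mrl0_ms, protocol=protocol)
        trains = {}
        for f in protocol.frequencies_hz:
            try:
                for tr in range(n_trials):
                    trains[(f, tr)] = simulate_train(model, f, rng, jitter_sigma_ms)
            except RateBuildError as exc:
                # e.g. a silent neuron: no evoked trains, spontaneous only
                warnings.warn(f"neuron {nrn.neuron_id}: {exc}", stacklevel=2)
                trains = {k: v for k, v in trains.items() if k[0] != f}
        spont = np.empty(0)
        if include_spontaneous:
            n_sp = rng.poisson(nrn.spont_hz * protocol.spontaneous_s)
            spont = np.sort(rng.random(n_sp) * protocol.spontaneous_s)
        fin = np.empty(0)
        if include_final_seq:
            fin = _simulate_final_sequence(nrn, protocol, rng)
        recordings.append(
            Recording(
                neuron_id=nrn.neuron_id,
                region=region,
                condition=condition,
                protocol=protocol,
                trains=trains,
                spontaneous=spont,
                final_seq_spikes=fin,
            )
        )
    return recordings
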