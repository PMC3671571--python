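import numpy as np
import pytest

import prvsim as pv
from prvsim.metrics import half_rise_time

from conftest import make_recording, random_recording

PROTO = pv.prv_protocol()


def spikes_for_counts(f, counts, offset_ms=5.0, spacing_ms=0.5):
    """Place `counts[j]` early-window spikes after stimulus j."""
    onsets = PROTO.onsets_s(f)
    t = []
    for j, c in enumerate(counts):
        for k in range(c):
            t.append(onsets[j] + (offset_ms + k * spacing_ms) / 1000.0)
    return sorted(t)


# ---------------------------------------------------------------------------
# RRTF
# ---------------------------------------------------------------------------


def test_rrtf_equal_counts_is_one():
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [3] * 6)})
    assert pv.compute_rrtf(rec, 1.0) == pytest.approx(1.0)


def test_rrtf_hand_example():
    # sp = (2, 4, 4, 4, 4, 4) at 1 Hz -> (20/5) / 2 = 2
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [2, 4, 4, 4, 4, 4])})
    assert pv.compute_rrtf(rec, 1.0) == pytest.approx(2.0)


def test_rrtf_scale_invariant():
    a = make_recording({(1.0, 0): spikes_for_counts(1.0, [1, 2, 3, 2, 1, 2])})
    b = make_recording({(1.0, 0): spikes_for_counts(1.0, [3, 6, 9, 6, 3, 6])})
    assert pv.compute_rrtf(a, 1.0) == pytest.approx(pv.compute_rrtf(b, 1.0))


def test_rrtf_undefined_when_first_stimulus_silent():
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [0, 4, 4, 4, 4, 4])})
    assert np.isnan(pv.compute_rrtf(rec, 1.0))


# ---------------------------------------------------------------------------
# TSR and normalization
# ---------------------------------------------------------------------------


def test_tsr_is_mean_over_trials():
    rec = make_recording({(1.0, 0): [0.1, 0.2, 0.3], (1.0, 1): [0.5]})
    assert pv.compute_tsr(rec, 1.0) == pytest.approx(2.0)


@pytest.mark.parametrize(
    "values,expected",
    [
        ([10.0, 20.0, 40.0], [0.25, 0.5, 1.0]),
        ([7.0, 7.0, 7.0], [1.0, 1.0, 1.0]),
    ],
)
def test_normalize_profile(values, expected):
    np.testing.assert_allclose(pv.normalize_profile(values), expected)


def test_normalize_all_zero_is_undefined():
    assert np.all(np.isnan(pv.normalize_profile([0.0, 0.0])))


# ---------------------------------------------------------------------------
# MRL / half-rise
# ---------------------------------------------------------------------------


def test_half_rise_ramp():
    # ramp 0,1,...,10: 50% of peak (5) reached at bin 5
    assert half_rise_time(np.arange(11.0)) == pytest.approx(5.0)


def test_half_rise_single_bin():
    c = np.zeros(20)
    c[7] = 3.0
    assert half_rise_time(c) == pytest.approx(7.0)


def test_half_rise_interpolates_between_bins():
    assert half_rise_time(np.array([0.0, 2.0, 2.0, 10.0])) == pytest.approx(2.375)


def test_half_rise_empty_is_nan():
    assert np.isnan(half_rise_time(np.zeros(5)))


def test_compute_mrl_single_latency():
    f = 10.0
    onsets = PROTO.onsets_s(f)
    rec = make_recording({(f, 0): onsets + 0.007})
    assert pv.compute_mrl(rec, f) == pytest.approx(7.0)


# ---------------------------------------------------------------------------
# VS
# ---------------------------------------------------------------------------


def test_vs_perfect_locking_is_one():
    f = 10.0
    onsets = PROTO.onsets_s(f)
    rec = make_recording({(f, 0): onsets + 0.005})
    assert pv.compute_vs(rec, f) == pytest.approx(1.0)


def test_vs_opposing_phases_is_zero():
    # two spikes at phases 0 and pi (0 ms and 50 ms into a 100-ms period)
    rec = make_recording({(10.0, 0): [0.0, 0.050]})
    assert pv.compute_vs(rec, 10.0) == pytest.approx(0.0, abs=1e-12)


def test_vs_uniform_phases_near_zero(rng):
    # 10^4 uniform spikes in a 1-s period: Rayleigh expectation ~ 0.009
    t = np.sort(rng.random(10_000) * 5.0)
    rec = make_recording({(1.0, 0): t})
    assert pv.compute_vs(rec, 1.0) <= 0.05


def test_vs_no_spikes_is_nan():
    rec = make_recording({(10.0, 0): []})
    assert np.isnan(pv.compute_vs(rec, 10.0))


# ---------------------------------------------------------------------------
# effectiveness
# ---------------------------------------------------------------------------


def test_effectiveness_every_stimulus_hits():
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [1] * 6)})
    assert pv.compute_effectiveness(rec, 1.0) == pytest.approx(1.0)


def test_effectiveness_alternating():
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [1, 0, 1, 0, 1, 0])})
    assert pv.compute_effectiveness(rec, 1.0) == pytest.approx(0.5)


def test_effective_rrtf_ignores_late_misses():
    # misses concentrated in later stimuli deflate the crude RRTF only
    rec = make_recording({(1.0, 0): spikes_for_counts(1.0, [2, 2, 2, 2, 0, 0])})
    crude = pv.compute_rrtf(rec, 1.0)
    eff = pv.compute_effective_rrtf(rec, 1.0)
    assert eff > crude
    assert eff == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# brute-force oracle across metrics
# ---------------------------------------------------------------------------


def naive_metrics(rec, f):
    """Independent recomputation of RRTF/TSR/VS/effectiveness from raw times."""
    onsets = rec.protocol.onsets_s(f) * 1000.0
    trials = rec.trials(f)
    n = len(onsets)
    early = np.zeros((n, len(trials)))
    phases = []
    totals = []
    for j, tr in enumerate(trials):
        spikes = rec.trains[(f, tr)] * 1000.0
        totals.append(np.sum(spikes < rec.protocol.train_duration_s * 1000.0))
        for t in spikes:
            owners = [i for i, o in enumerate(onsets) if o <= t + 1e-9]
            if not owners:
                continue
            i = owners[-1]
            rel = t - onsets[i]
            if rel < 15.0:
                early[i, j] += 1
            phases.append(2 * np.pi * rel / rec.protocol.period_ms(f))
    sp = early.mean(axis=1)
    rrtf = sp[1:].mean() / sp[0] if sp[0] > 0 else np.nan
    tsr = float(np.mean(totals))
    ph = np.asarray(phases)
    vs = np.hypot(np.cos(ph).sum(), np.sin(ph).sum()) / len(ph) if len(ph) else np.nan
    eff = np.count_nonzero(early > 0) / early.size
    return rrtf, tsr, vs, eff


@pytest.mark.parametrize("seed", range(10))
def test_metrics_match_brute_force_on_random_recordings(seed):
    """Each metric equals an independent naive recomputation (10 recordings
    per seed x 10 seeds = 100 random recordings)."""
    rng = np.random.default_rng(seed)
    for _ in range(10):
        proto = pv.StimulusProtocol(frequencies_hz=(1.0, 8.0, 40.0))
        rec = random_recording(rng, proto, rate_hz=float(rng.uniform(2, 25)), trials=3)
        for f in proto.frequencies_hz:
            rrtf, tsr, vs, eff = naive_metrics(rec, f)
            np.testing.assert_allclose(pv.compute_rrtf(rec, f), rrtf, equal_nan=True)
            np.testing.assert_allclose(pv.compute_tsr(rec, f), tsr)
            np.testing.assert_allclose(pv.compute_vs(rec, f), vs, equal_nan=True)
            np.testing.assert_allclose(pv.compute_effectiveness(rec, f), eff)


def test_profile_invariants(small_dataset):
    for rec in small_dataset:
        prof = pv.compute_profile(rec)
        defined = np.isfinite(prof.vs)
        assert np.all((prof.vs[defined] >= 0) & (prof.vs[defined] <= 1))
        for norm in (prof.tsrn, prof.mrln):
            d = np.isfinite(norm)
            if d.any():
                assert np.nanmax(norm) == pytest.approx(1.0)
                assert np.all(norm[d] > 0)
        e = np.isfinite(prof.effectiveness)
        assert np.all((prof.effectiveness[e] >= 0) & (prof.effectiveness[e] <= 1))
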