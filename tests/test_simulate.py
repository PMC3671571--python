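import numpy as np
import pytest

import prvsim as pv
from prvsim.metrics import MetricProfile
from prvsim.simulate import (
    RateBuildError,
    RateModel,
    build_rate,
    compare_real_vs_sim,
    decortication_shift,
    estimate_r0,
    expected_train_total,
    simulate_train,
)

from conftest import make_recording

PROTO = pv.prv_protocol()
FREQS = np.asarray(PROTO.frequencies_hz)


def flat_profile(rrtf=1.0, tsr=10.0, mrl=4.0, vs=0.9):
    nan = np.full(FREQS.shape, np.nan)
    return MetricProfile(
        frequencies_hz=FREQS,
        rrtf=np.full(FREQS.shape, rrtf),
        tsr=np.full(FREQS.shape, tsr),
        tsrn=np.ones(FREQS.shape),
        mrl_ms=np.full(FREQS.shape, mrl),
        mrln=np.ones(FREQS.shape),
        vs=np.full(FREQS.shape, vs),
        effectiveness=nan.copy(),
        rrtf_effective=nan.copy(),
        mrl0_ms=mrl,
    )


def tophat_r0(start=3, width=5, height=0.4, n=1000):
    r0 = np.zeros(n)
    r0[start : start + width] = height
    return r0


# ---------------------------------------------------------------------------
# r0 estimation
# ---------------------------------------------------------------------------


def test_estimate_r0_deterministic_single_spike():
    # every first stimulus answers with one spike at 5 ms
    trains = {}
    for f in PROTO.frequencies_hz:
        for tr in range(2):
            trains[(f, tr)] = np.array([0.0055])
    rec = make_recording(trains)
    r0 = estimate_r0(rec)
    assert r0[5] == pytest.approx(1.0)
    assert r0.sum() == pytest.approx(1.0)


def test_estimate_r0_matches_naive_psth(rng):
    trains = {}
    for f in PROTO.frequencies_hz:
        dur = PROTO.train_extent_s(f)
        for tr in range(2):
            n = rng.poisson(8 * dur)
            trains[(f, tr)] = np.sort(rng.random(n) * dur)
    rec = make_recording(trains)
    got = estimate_r0(rec)
    counts = np.zeros(1000)
    denom = np.zeros(1000)
    for f in PROTO.frequencies_hz:
        first_win = min(PROTO.period_ms(f), PROTO.train_duration_s * 1000)
        L = int(np.ceil(first_win - 1e-9))
        for tr in range(2):
            for t in rec.trains[(f, tr)] * 1000:
                if t < first_win and int(t) < min(L, 1000):
                    counts[int(t)] += 1
        denom[: min(L, 1000)] += 2
    naive = np.divide(counts, denom, out=np.zeros(1000), where=denom > 0)
    np.testing.assert_allclose(got, naive)


def test_estimate_r0_empty_recording_warns():
    rec = make_recording({(1.0, 0): []})
    with pytest.warns(UserWarning, match="empty r0"):
        r0 = estimate_r0(rec)
    assert not np.any(r0 > 0)


# ---------------------------------------------------------------------------
# rate construction
# ---------------------------------------------------------------------------


def test_identity_case_reproduces_r0():
    """RRTF=1 and per-train totals equal to the r0 prediction leave the
    subsequent-stimulus rate equal to the first-stimulus rate."""
    r0 = tophat_r0()
    f = 10.0
    prof = flat_profile(rrtf=1.0, tsr=1.0, mrl=3.0)
    model = RateModel(r0=r0, profile=prof, protocol=PROTO, mrl0_ms=3.0)
    # choose TSR(f) = expected total when the late gain is exactly 1
    tsr = expected_train_total(r0, PROTO, f, 1.0, 1.0, 0.0)
    prof.tsr[:] = tsr
    rate = build_rate(model, f)
    np.testing.assert_allclose(rate, r0[: len(rate)], atol=1e-9)


def test_rate_zero_before_response_start():
    r0 = tophat_r0(start=0, width=10)
    prof = flat_profile(rrtf=1.0, tsr=5.0, mrl=9.0)
    model = RateModel(r0=r0, profile=prof, protocol=PROTO, mrl0_ms=3.0)
    rate = build_rate(model, 10.0)  # t1 = 6 ms
    assert np.all(rate[:6] == 0)


def test_undefined_metrics_cannot_build():
    prof = flat_profile()
    prof.tsr[:] = np.nan
    model = RateModel(r0=tophat_r0(), profile=prof, protocol=PROTO)
    with pytest.raises(RateBuildError):
        build_rate(model, 10.0)


@pytest.mark.parametrize("f", [1.0, 10.0, 40.0])
def test_expected_total_matches_monte_carlo(f):
    """Mean simulated train total tracks the expected-count identity."""
    nrn = pv.generate_population({"tonic_intact": 1}, seed=2, noise=0.0)[0]
    model = RateModel(r0=nrn.r0, profile=nrn.profile, protocol=PROTO)
    rng = np.random.default_rng(5)
    n_mc = 300
    dur = PROTO.train_duration_s
    totals = [
        np.count_nonzero(simulate_train(model, f, rng) < dur) for _ in range(n_mc)
    ]
    tsr = nrn.profile.at(f)["TSR"]
    se = np.std(totals, ddof=1) / np.sqrt(n_mc)
    assert np.mean(totals) == pytest.approx(tsr, abs=max(3 * se, 0.05 * tsr))


def test_early_counts_scale_with_rrtf():
    r0 = tophat_r0(start=3, width=5, height=0.1)
    f, t1 = 10.0, 0.0
    base = expected_train_total(r0, PROTO, f, 1.0, 0.0, t1)
    doubled = expected_train_total(r0, PROTO, f, 2.0, 0.0, t1)
    first = np.minimum(r0[:100], 1.0).sum()
    assert doubled - first == pytest.approx(2 * (base - first))


# ---------------------------------------------------------------------------
# train simulation
# ---------------------------------------------------------------------------


def test_zero_rate_gives_empty_train():
    prof = flat_profile(rrtf=1.0, tsr=0.0, vs=1.0)
    model = RateModel(r0=np.zeros(1000), profile=prof, protocol=PROTO)
    t = simulate_train(model, 10.0, np.random.default_rng(0))
    assert t.size == 0


def test_certain_single_bin_rate_locks_every_stimulus():
    # rate 1 in exactly one bin per stimulus, VS = 1: n_stim spikes, VS = 1
    f = 10.0
    r0 = np.zeros(1000)
    r0[5] = 1.0
    prof = flat_profile(rrtf=1.0, tsr=51.0, mrl=5.0, vs=1.0)
    model = RateModel(r0=r0, profile=prof, protocol=PROTO, mrl0_ms=5.0)
    t = simulate_train(model, f, np.random.default_rng(0))
    assert t.size == PROTO.n_stimuli(f)
    rec = make_recording({(f, 0): t})
    assert pv.compute_vs(rec, f) == pytest.approx(1.0)


def test_simulation_reproducible_bit_for_bit():
    nrn = pv.generate_population({"tonic_intact": 1}, seed=3)[0]
    model = RateModel(r0=nrn.r0, profile=nrn.profile, protocol=PROTO)
    a = pv.simulate_recording(model, "a", seed=77)
    b = pv.simulate_recording(model, "b", seed=77)
    for k in a.trains:
        np.testing.assert_array_equal(a.trains[k], b.trains[k])


def test_measured_vs_monotone_in_profile_vs():
    """More phase-locking in the profile never lowers the measured VS."""
    f = 40.0
    nrn = pv.generate_population({"tonic_intact": 1}, seed=4, noise=0.0)[0]
    measured = []
    for vs in (0.0, 0.5, 1.0):
        prof = nrn.profile
        prof.vs[:] = vs
        model = RateModel(r0=nrn.r0, profile=prof, protocol=PROTO)
        rng = np.random.default_rng(11)
        trains = {(f, tr): simulate_train(model, f, rng) for tr in range(10)}
        rec = make_recording(trains)
        measured.append(pv.compute_vs(rec, f))
    assert measured[0] <= measured[1] + 0.02
    assert measured[1] <= measured[2] + 0.02


def test_measured_mrl_tracks_profile_mrl():
    nrn = pv.generate_population({"tonic_intact": 1}, seed=6, noise=0.0)[0]
    model = RateModel(r0=nrn.r0, profile=nrn.profile, protocol=PROTO)
    rec = pv.simulate_recording(model, "m", seed=8)
    prof = pv.compute_profile(rec)
    d = np.isfinite(prof.mrl_ms)
    assert np.all(np.abs(prof.mrl_ms[d] - nrn.profile.mrl_ms[d]) <= 2.0)


# ---------------------------------------------------------------------------
# decortication shift
# ---------------------------------------------------------------------------


def _model(r0):
    return RateModel(r0=r0, profile=flat_profile(), protocol=PROTO)


def test_zero_shift_is_identity():
    m = _model(tophat_r0())
    (out,) = decortication_shift([m], np.zeros(1000), +1)
    np.testing.assert_array_equal(out.r0, m.r0)


def test_subtracting_r0_silences_model():
    m = _model(tophat_r0())
    (out,) = decortication_shift([m], m.r0, -1)
    assert not np.any(out.r0 > 0)


def test_binning_mismatch_rejected():
    m = _model(tophat_r0())
    with pytest.raises(ValueError, match="binning"):
        decortication_shift([m], np.zeros(500), +1)


def test_raised_excitability_moves_phasic_toward_tonic():
    """Adding the tonic-phasic mean r0 difference to a phasic model raises
    its simulated train totals toward the tonic regime."""
    ph = pv.generate_population({"phasic_intact": 1}, seed=9, noise=0.0)[0]
    to = pv.generate_population({"tonic_intact": 1}, seed=9, noise=0.0)[0]
    diff = np.clip(to.r0 - ph.r0, 0, None)
    m_ph = RateModel(r0=ph.r0, profile=ph.profile, protocol=PROTO)
    (m_plus,) = decortication_shift([m_ph], diff, +1)
    f, n_mc = 10.0, 40
    rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
    base = np.mean([simulate_train(m_ph, f, rng1).size for _ in range(n_mc)])
    plus = np.mean([simulate_train(m_plus, f, rng2).size for _ in range(n_mc)])
    assert plus > base


# ---------------------------------------------------------------------------
# real-vs-simulated comparison
# ---------------------------------------------------------------------------


def test_identical_recordings_give_r2_one(small_dataset):
    rec = small_dataset[0]
    r2, p = compare_real_vs_sim(rec, rec, 10.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-10


def test_comparison_matches_textbook_correlation():
    f = 10.0
    onsets = PROTO.onsets_s(f)
    a = make_recording({(f, 0): onsets + 0.005, (f, 1): onsets + 0.005})
    b = make_recording({(f, 0): onsets + 0.005, (f, 1): onsets + 0.008})
    r2, _ = compare_real_vs_sim(a, b, f)
    ha = pv.cycle_histogram(a, f, exclude_first=False).counts
    hb = pv.cycle_histogram(b, f, exclude_first=False).counts
    da, db = ha - ha.mean(), hb - hb.mean()
    expect = (da @ db) ** 2 / ((da @ da) * (db @ db))
    assert r2 == pytest.approx(expect)


def test_constant_histogram_flagged_undefined():
    a = make_recording({(10.0, 0): []})
    b = make_recording({(10.0, 0): [0.005]})
    r2, p = compare_real_vs_sim(a, b, 10.0)
    assert np.isnan(r2) and np.isnan(p)


def test_unrelated_noise_rarely_significant(rng):
    """Independent uniform spike trains: correlations are null in ~95% of
    repeats."""
    f = 10.0
    nonsig = 0
    n_rep = 40
    for _ in range(n_rep):
        a = make_recording({(f, 0): np.sort(rng.random(40) * 5)})
        b = make_recording({(f, 0): np.sort(rng.random(40) * 5)})
        _, p = compare_real_vs_sim(a, b, f)
        nonsig += p >= 0.05
    assert nonsig >= 0.9 * n_rep - 2
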