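import numpy as np
import pytest

import prvsim as pv


def make_recording(
    trains: dict,
    protocol=None,
    neuron_id: str = "n0",
    region: str = "PrV",
    condition: str = "intact",
    spontaneous=(),
    final_seq=(),
) -> pv.Recording:
    """Build a Recording from explicit spike-time lists (seconds)."""
    return pv.Recording(
        neuron_id=neuron_id,
        region=region,
        condition=condition,
        protocol=protocol or pv.prv_protocol(),
        trains={k: np.asarray(v, dtype=float) for k, v in trains.items()},
        spontaneous=np.asarray(spontaneous, dtype=float),
        final_seq_spikes=np.asarray(final_seq, dtype=float),
    )


def random_recording(rng, protocol=None, rate_hz: float = 6.0, trials: int = 3,
                     neuron_id: str = "r0") -> pv.Recording:
    """Homogeneous-Poisson recording over the full protocol grid."""
    protocol = protocol or pv.prv_protocol()
    trains = {}
    for f in protocol.frequencies_hz:
        dur = protocol.train_extent_s(f)
        for tr in range(trials):
            n = rng.poisson(rate_hz * dur)
            trains[(f, tr)] = np.sort(rng.random(n) * dur)
    return make_recording(trains, protocol, neuron_id=neuron_id)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_population():
    return pv.generate_population({"tonic_intact": 3, "phasic_intact": 3}, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_population):
    return pv.generate_dataset(small_population, seed=43)
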