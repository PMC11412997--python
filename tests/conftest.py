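import numpy as np
import pytest

from wmrsa import rsm, synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stim6x10():
    return synth.make_stimulus_set(6, 10)


@pytest.fixture(scope="session")
def small_stim():
    return synth.make_stimulus_set(6, 3)


@pytest.fixture(scope="session")
def small_spec():
    return synth.SyntheticSpec(
        n_channels=6,
        n_trials_per_session=18,
        epoch_span=(-0.5, 1.2),
        effect_band=(13.0, 29.0),
        effect_window=(0.1, 0.7),
        effect_snr=1.2,
    )


@pytest.fixture(scope="session")
def small_subject(small_stim, small_spec):
    """One simulated subject with a beta-band category effect (tf mode)."""
    g = np.random.default_rng(777)
    table = synth.simulate_trial_table(small_stim, small_spec, rng=g)
    return synth.simulate_epochs(table, small_spec, small_stim, mode="tf", rng=g)


@pytest.fixture(scope="session")
def small_item_power(small_subject):
    return rsm.average_repetitions(
        small_subject.encoding, small_subject.encoding_meta, phase="encoding"
    )


def brute_force_spearman(a, b):
    """Average-rank Spearman via the explicit Pearson-on-ranks formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def avg_ranks(x):
        order = np.argsort(x, kind="stable")
        ranks = np.empty(x.size)
        i = 0
        xs = x[order]
        while i < x.size:
            j = i
            while j + 1 < x.size and xs[j + 1] == xs[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom)
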