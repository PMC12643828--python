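"""Feature extraction against closed forms and a naive pair-counting oracle."""

import numpy as np
import pytest

from habclust.features import (
    compute_acg,
    compute_isi_histogram,
    compute_scalar_features,
)

from conftest import make_train, poisson_train, random_train, regular_train


# ---------------------------------------------------------------------------
# Independent oracles: O(n^2) enumeration over spike pairs / ISIs
# ---------------------------------------------------------------------------


def naive_isi_histogram(times, bin_width=0.005, isi_max=0.5):
    isis = np.diff(times)
    n_bins = int(round(isi_max / bin_width))
    counts = np.zeros(n_bins)
    for isi in isis:
        for b in range(n_bins):
            lo, hi = b * bin_width, (b + 1) * bin_width
            last = b == n_bins - 1
            if (lo <= isi < hi) or (last and isi == isi_max):
                counts[b] += 1
    return counts / max(isis.size, 1)


def naive_acg(times, bin_width=0.002, acg_max=0.1):
    n_half = int(round(acg_max / bin_width))
    edges = np.linspace(-acg_max, acg_max, 2 * n_half + 1)
    counts = np.zeros(2 * n_half)
    for i in range(len(times)):
        for j in range(len(times)):
            if i == j:
                continue
            dt = times[j] - times[i]
            if abs(dt) > acg_max:
                continue
            for b in range(2 * n_half):
                lo, hi = edges[b], edges[b + 1]
                last = b == 2 * n_half - 1
                if (lo <= dt < hi) or (last and dt == acg_max):
                    counts[b] += 1
                    break
    return counts / len(times)


@pytest.mark.parametrize("seed", range(8))
def test_histograms_match_enumeration_oracle(seed):
    """ISI histogram and ACG equal brute-force pair enumeration bin-for-bin."""
    rng = np.random.default_rng(seed)
    train = random_train(rng, n_spikes=int(rng.integers(5, 200)), duration=5.0)
    np.testing.assert_allclose(
        compute_isi_histogram(train).mass, naive_isi_histogram(train.spike_times),
        atol=1e-12,
    )
    np.testing.assert_allclose(
        compute_acg(train).counts_per_spike, naive_acg(train.spike_times), atol=1e-12
    )


def test_scalar_features_direct_counts():
    """Rate, CV and burst index from hand-countable spike times."""
    f = compute_scalar_features(make_train(np.linspace(0.25, 4.75, 10), duration=5.0))
    assert f.rate == pytest.approx(2.0)

    # ISIs [10, 10, 500, 500] ms: two of four below 25 ms
    f = compute_scalar_features(make_train([0, 0.010, 0.020, 0.520, 1.020], duration=2.0))
    assert f.burst_index == pytest.approx(0.5)
    isis = np.array([0.01, 0.01, 0.5, 0.5])
    assert f.cv == pytest.approx(isis.std() / isis.mean())


def test_cv_limits_regular_and_poisson():
    """CV vanishes for clock-like firing and is ~1 for Poisson firing."""
    assert compute_scalar_features(regular_train(10.0, 100.0)).cv < 0.05
    rng = np.random.default_rng(5)
    train = poisson_train(rng, rate=5.0, duration=2100.0)
    assert train.n_spikes > 10_000
    assert 0.95 < compute_scalar_features(train).cv < 1.05


def test_isi_histogram_mass_conventions():
    """In-range ISIs land in one bin; out-of-range ISIs keep their mass out."""
    h = compute_isi_histogram(make_train(np.arange(10) * 0.102, duration=1.2))
    nz = np.flatnonzero(h.mass)
    assert len(nz) == 1
    assert h.bin_edges[nz[0]] <= 0.102 <= h.bin_edges[nz[0] + 1]
    assert h.mass[nz[0]] == pytest.approx(1.0)

    h = compute_isi_histogram(make_train(np.arange(8) * 0.8, duration=8.0))
    assert np.all(h.mass == 0)


def test_isi_histogram_tracks_exponential_density():
    """For Poisson firing the histogram follows the exponential ISI law."""
    rng = np.random.default_rng(3)
    train = poisson_train(rng, rate=5.0, duration=4000.0)
    h = compute_isi_histogram(train)
    centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
    expected = 5.0 * np.exp(-5.0 * centers) * 0.005
    np.testing.assert_allclose(h.mass[:40], expected[:40], rtol=0.25, atol=5e-4)


def test_acg_two_spikes_and_singleton():
    acg = compute_acg(make_train([1.0, 1.049], duration=3.0))
    pos = np.flatnonzero(acg.counts_per_spike)
    assert len(pos) == 2
    # one pair at +49 ms and its mirror, each divided by n_spikes = 2
    np.testing.assert_allclose(acg.counts_per_spike[pos], [0.5, 0.5])
    lags = 0.5 * (acg.lag_edges[:-1] + acg.lag_edges[1:])
    np.testing.assert_allclose(sorted(lags[pos]), [-0.049, 0.049], atol=1e-9)

    assert np.all(compute_acg(make_train([1.0], duration=2.0)).counts_per_spike == 0)


def test_acg_regular_train_peaks_at_multiples_of_period():
    """A 20 Hz clock train has ACG mass only at the +/-50 and +/-100 ms lags.

    Period multiples sit exactly on 2 ms bin edges, so floating-point
    rounding may put them in either adjacent bin; both are accepted.
    """
    acg = compute_acg(regular_train(20.0, 60.0))
    lags = 0.5 * (acg.lag_edges[:-1] + acg.lag_edges[1:])
    nz = lags[np.flatnonzero(acg.counts_per_spike)]
    assert np.all(np.isin(np.round(np.abs(nz), 3), [0.049, 0.051, 0.099, 0.101]))


def test_acg_symmetry_exact():
    rng = np.random.default_rng(9)
    for _ in range(5):
        acg = compute_acg(random_train(rng, 150, duration=10.0))
        np.testing.assert_array_equal(
            acg.counts_per_spike, acg.counts_per_spike[::-1]
        )


def test_burst_index_monotone_under_short_isi_insertion():
    """Adding a spike within 25 ms of an existing one never lowers the index."""
    rng = np.random.default_rng(21)
    for _ in range(20):
        train = random_train(rng, 50, duration=50.0)
        before = compute_scalar_features(train).burst_index
        i = int(rng.integers(0, train.n_spikes - 1))
        gap = train.spike_times[i + 1] - train.spike_times[i]
        t_new = train.spike_times[i] + min(0.2 * gap, 0.01)
        augmented = make_train(
            np.sort(np.append(train.spike_times, t_new)), duration=train.duration
        )
        after = compute_scalar_features(augmented).burst_index
        assert after >= before - 1e-12


def test_too_few_spikes_flagged_undefined():
    f = compute_scalar_features(make_train([0.5, 1.0], duration=2.0))
    assert np.isnan(f.cv) and np.isnan(f.burst_index)
    assert f.rate == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_isi_histogram(make_train([], duration=1.0))
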