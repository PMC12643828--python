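"""Per-neuron spontaneous-activity features.

For each spike train we compute the mean firing rate, the interspike
interval (ISI) distribution over 0-0.5 s, the coefficient of variation
(CV = SD(ISI)/mean(ISI)), the burst index (fraction of ISIs shorter
than 25 ms), and the spike autocorrelogram (ACG) over +/-0.1 s with
the zero-lag self-pairs excluded.

Conventions that the literature leaves open, fixed here:

* CV uses the population (n-denominator) standard deviation.
* The ISI histogram mass is normalised by the *total* ISI count, so ISIs
  longer than 0.5 s leave mass outside the plotted range rather than
  being renormalised away.
* The ACG is normalised per spike (pair counts divided by the number of
  spikes).  Any per-neuron uniform scaling is removed later by z-scoring
  across neurons, so this choice does not affect the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import SpikeTrain

BURST_THRESHOLD = 0.025  # s; ISIs strictly below count as intra-burst


@dataclass(frozen=True)
class ScalarFeatures:
    """Rate, CV and burst index for one neuron.

    ``cv`` and ``burst_index`` are NaN when fewer than two ISIs exist;
    such neurons are excluded from clustering upstream.
    """

    neuron_id: str
    rate: float
    cv: float
    burst_index: float
    n_spikes: int

    @property
    def defined(self) -> bool:
        return not (np.isnan(self.cv) or np.isnan(self.burst_index))


@dataclass(frozen=True)
class ISIHistogram:
    bin_edges: np.ndarray  # s, over [0, isi_max]
    mass: np.ndarray  # per-bin fraction of all ISIs; sums to <= 1


@dataclass(frozen=True)
class Autocorrelogram:
    lag_edges: np.ndarray  # s, over [-acg_max, +acg_max]
    counts_per_spike: np.ndarray  # pair counts / n_spikes, zero-lag excluded


def compute_scalar_features(
    train: SpikeTrain, burst_threshold: float = BURST_THRESHOLD
) -> ScalarFeatures:
    """Mean rate, ISI coefficient of variation and burst index.

    rate = n_spikes / duration.  CV and burst index need at least two
    ISIs (three spikes); otherwise they are NaN.
    """
    isis = train.isis
    if isis.size < 2:
        cv = np.nan
        burst = np.nan
    else:
        mean = isis.mean()
        cv = isis.std(ddof=0) / mean
        burst = float(np.count_nonzero(isis < burst_threshold)) / isis.size
    return ScalarFeatures(
        neuron_id=train.neuron_id,
        rate=train.n_spikes / train.duration,
        cv=float(cv),
        burst_index=float(burst),
        n_spikes=train.n_spikes,
    )


def compute_isi_histogram(
    train: SpikeTrain, bin_width: float = 0.005, isi_max: float = 0.5
) -> ISIHistogram:
    """ISI histogram over ``[0, isi_max]``, mass normalised by all ISIs.

    ISIs beyond ``isi_max`` are not binned but still enter the
    denominator, so ``sum(mass) = (#ISIs <= isi_max) / (#ISIs)``.
    """
    isis = train.isis
    if isis.size < 1:
        raise ValueError(f"{train.neuron_id}: need >= 2 spikes for an ISI histogram")
    n_bins = int(round(isi_max / bin_width))
    edges = np.linspace(0.0, isi_max, n_bins + 1)
    counts, _ = np.histogram(isis, bins=edges)
    return ISIHistogram(bin_edges=edges, mass=counts / isis.size)


def compute_acg(
    train: SpikeTrain, bin_width: float = 0.002, acg_max: float = 0.1
) -> Autocorrelogram:
    """Spike autocorrelogram over ``[-acg_max, +acg_max]``.

    Every ordered spike pair with ``0 < |dt| <= acg_max`` increments the
    bin containing its lag; the zero-lag self-pairs are excluded; counts
    are divided by the number of spikes.  Exactly symmetric about zero
    by construction.
    """
    t = train.spike_times
    if t.size < 1:
        raise ValueError(f"{train.neuron_id}: need spikes for an ACG")
    n_half = int(round(acg_max / bin_width))
    edges = np.linspace(-acg_max, acg_max, 2 * n_half + 1)
    pos_edges = edges[n_half:]
    # positive lags only; negative side is the mirror image.  Iterate over
    # pair order k (t[i+k] - t[i]) rather than over spikes: the number of
    # in-window partners per spike is small, so k stays small.
    pos_counts = np.zeros(n_half, dtype=float)
    for k in range(1, t.size):
        lags = t[k:] - t[:-k]
        lags = lags[lags <= acg_max]
        if lags.size == 0:
            break
        # np.histogram includes the right edge of the last bin, so lags
        # exactly at acg_max are kept
        c, _ = np.histogram(lags, bins=pos_edges)
        pos_counts += c
    counts = np.concatenate([pos_counts[::-1], pos_counts]) / t.size
    return Autocorrelogram(lag_edges=edges, counts_per_spike=counts)


def histogram_bank(
    trains: list[SpikeTrain],
    kind: str = "isi",
    bin_width: float | None = None,
    max_range: float | None = None,
) -> np.ndarray:
    """Stack per-neuron ISI or ACG histograms into an ``n x bins`` matrix."""
    if kind == "isi":
        bw = 0.005 if bin_width is None else bin_width
        mx = 0.5 if max_range is None else max_range
        rows = [compute_isi_histogram(t, bw, mx).mass for t in trains]
    elif kind == "acg":
        bw = 0.002 if bin_width is None else bin_width
        mx = 0.1 if max_range is None else max_range
        rows = [compute_acg(t, bw, mx).counts_per_spike for t in trains]
    else:
        raise ValueError(f"unknown histogram kind {kind!r}")
    return np.vstack(rows)
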