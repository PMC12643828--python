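"""Foot-shock response analysis: PSTH, modulation index, response AUC.

The peristimulus time histogram (PSTH) spans -0.2 to +1.3 s around
stimulus onset in 20 ms bins.  The foot-shock modulation index

    FSMI = (FR_stimulus - FR_baseline) / (FR_stimulus + FR_baseline)

compares the mean rate during the 0.5 s stimulus with the mean rate
during the 1 s preceding onset, averaged over trials; neurons with
spontaneous rate below 1 Hz are excluded because they may fire less
than one spike per stimulus.  The sustained response is summarised by
the area under the z-scored PSTH during the first 300 ms after onset,
with the z-score baseline taken from the pre-stimulus PSTH bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import SpikeTrain, TrialSet


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged rate around stimulus onset."""

    bin_edges: np.ndarray  # s relative to onset
    rate: np.ndarray  # Hz per bin
    n_trials: int

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def z_rate(self, baseline_window: tuple[float, float] = (-0.2, 0.0)) -> np.ndarray:
        """Per-bin z-scores against the pre-stimulus baseline bins."""
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        base = (centers >= baseline_window[0]) & (centers < baseline_window[1])
        if base.sum() < 2:
            raise ValueError("baseline window covers fewer than two bins")
        mu = self.rate[base].mean()
        sd = self.rate[base].std(ddof=0)
        if sd == 0:
            raise ValueError("degenerate baseline: zero variance across baseline bins")
        return (self.rate - mu) / sd


@dataclass(frozen=True)
class FSRecord:
    """Per-neuron foot-shock modulation summary.

    ``excluded`` marks neurons whose spontaneous rate is below the
    1 Hz criterion; their ``fsmi`` is NaN.
    """

    neuron_id: str
    fr_baseline: float
    fr_stimulus: float
    fsmi: float
    excluded: bool
    n_trials: int
    auc_300: float = np.nan


def _usable_onsets(train: SpikeTrain, trials: TrialSet,
                   pre: float, post: float) -> np.ndarray:
    """Trial onsets whose analysis window fits inside the recording."""
    ok = (trials.onsets + pre >= 0) & (trials.onsets + post <= train.duration)
    dropped = trials.n_trials - int(ok.sum())
    if dropped:
        warnings.warn(
            f"{train.neuron_id}: dropping {dropped} trials truncated by recording edges"
        )
    return trials.onsets[ok]


def compute_psth(
    train: SpikeTrain,
    trials: TrialSet,
    window: tuple[float, float] = (-0.2, 1.3),
    bin_width: float = 0.02,
) -> PSTH:
    """PSTH in Hz: spike counts pooled over trials / (n_trials x bin)."""
    onsets = _usable_onsets(train, trials, window[0], window[1])
    if onsets.size == 0:
        raise ValueError(f"{train.neuron_id}: no usable trials for the PSTH window")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for onset in onsets:
        rel = train.spike_times - onset
        rel = rel[(rel >= window[0]) & (rel < window[1])]
        c, _ = np.histogram(rel, bins=edges)
        counts += c
    rate = counts / (onsets.size * bin_width)
    return PSTH(bin_edges=edges, rate=rate, n_trials=int(onsets.size))


def compute_fsmi(
    train: SpikeTrain,
    trials: TrialSet,
    baseline_window: float = 1.0,
    min_rate: float = 1.0,
) -> FSRecord:
    """Foot-shock modulation index with the low-rate exclusion.

    Baseline rate pools spikes over ``[-baseline_window, 0)`` before
    each usable onset; stimulus rate pools over ``[0, stim_duration)``.
    Neurons with spontaneous (whole-recording) rate below ``min_rate``
    are flagged excluded and get ``fsmi = NaN``.
    """
    onsets = _usable_onsets(train, trials, -baseline_window, trials.stim_duration)
    if onsets.size == 0:
        raise ValueError(f"{train.neuron_id}: no usable trials")
    t = train.spike_times
    n_base = n_stim = 0
    for onset in onsets:
        n_base += np.count_nonzero((t >= onset - baseline_window) & (t < onset))
        n_stim += np.count_nonzero((t >= onset) & (t < onset + trials.stim_duration))
    fr_base = n_base / (onsets.size * baseline_window)
    fr_stim = n_stim / (onsets.size * trials.stim_duration)
    spontaneous = train.n_spikes / train.duration
    excluded = spontaneous < min_rate
    if excluded or fr_base + fr_stim == 0:
        fsmi = np.nan
        if not excluded:
            warnings.warn(f"{train.neuron_id}: no spikes in either window; FSMI undefined")
    else:
        fsmi = (fr_stim - fr_base) / (fr_stim + fr_base)
    return FSRecord(
        neuron_id=train.neuron_id,
        fr_baseline=float(fr_base),
        fr_stimulus=float(fr_stim),
        fsmi=float(fsmi),
        excluded=bool(excluded),
        n_trials=int(onsets.size),
    )


def compute_auc300(
    psth: PSTH,
    response_window: float = 0.3,
    baseline_window: tuple[float, float] = (-0.2, 0.0),
) -> float:
    """Area under the z-scored PSTH during the first 300 ms after onset.

    Computed as the sum of per-bin z-scores over ``[0, response_window)``
    times the bin width (units: z * s).
    """
    z = psth.z_rate(baseline_window)
    centers = 0.5 * (psth.bin_edges[:-1] + psth.bin_edges[1:])
    resp = (centers >= 0) & (centers < response_window)
    return float(z[resp].sum() * psth.bin_width)


def analyze_fs_neuron(
    train: SpikeTrain,
    trials: TrialSet,
    psth_window: tuple[float, float] = (-0.2, 1.3),
    psth_bin: float = 0.02,
    baseline_window: float = 1.0,
    min_rate: float = 1.0,
    auc_window: float = 0.3,
) -> tuple[FSRecord, PSTH]:
    """Full per-neuron foot-shock summary: FSMI record plus PSTH/AUC."""
    psth = compute_psth(train, trials, psth_window, psth_bin)
    rec = compute_fsmi(train, trials, baseline_window, min_rate)
    try:
        auc = compute_auc300(psth, auc_window)
    except ValueError:
        auc = np.nan
    return FSRecord(**{**rec.__dict__, "auc_300": float(auc)}), psth
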