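"""Behavioral-state analysis: motion-energy epoching, BSMI, significance.

Behavior is partitioned by facial motion energy: samples above the
session's 80th percentile form "active" epochs, samples below the 20th
percentile form "quiet" epochs, and everything in between belongs to
neither.  The behavioral-state modulation index

    BSMI = (FR_active - FR_quiet) / (FR_active + FR_quiet)

compares the pooled firing rates across the two epoch sets.  Each
neuron is classified as significantly increasing, decreasing, or not
modulated using a two-sample (unpaired) Wilcoxon rank-sum test on the
per-epoch firing rates at the 0.05 level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import MotionTrace, SpikeTrain


@dataclass(frozen=True)
class StateEpochs:
    """Active/quiet intervals derived from a motion trace."""

    active: tuple[tuple[float, float], ...]  # [start, end) seconds
    quiet: tuple[tuple[float, float], ...]
    active_threshold: float
    quiet_threshold: float

    @property
    def active_time(self) -> float:
        return float(sum(e - s for s, e in self.active))

    @property
    def quiet_time(self) -> float:
        return float(sum(e - s for s, e in self.quiet))


@dataclass(frozen=True)
class BSRecord:
    """Per-neuron behavioral-state modulation summary."""

    neuron_id: str
    fr_active: float
    fr_quiet: float
    bsmi: float
    active_epoch_rates: np.ndarray
    quiet_epoch_rates: np.ndarray
    category: str  # {"increase", "decrease", "no_change"}
    p_value: float
    insufficient_data: bool = False


def _samples_to_epochs(
    mask: np.ndarray, dt: float, min_epoch: float
) -> tuple[tuple[float, float], ...]:
    """Merge consecutive True samples into [start, end) intervals."""
    if not mask.any():
        return ()
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    epochs = [
        (s * dt, e * dt) for s, e in zip(starts, ends) if (e - s) * dt >= min_epoch
    ]
    return tuple(epochs)


def partition_states(
    motion: MotionTrace,
    active_percentile: float = 80.0,
    quiet_percentile: float = 20.0,
    smooth: float = 0.5,
    min_epoch: float = 0.5,
) -> StateEpochs:
    """Threshold a motion trace into active and quiet epochs.

    The trace is lightly smoothed (moving average of ``smooth``
    seconds) before percentile thresholding to avoid single-sample
    flicker epochs; epochs shorter than ``min_epoch`` are dropped.
    Thresholds are the session's own empirical percentiles, so they are
    invariant to any monotone rescaling of the motion signal.
    """
    x = motion.samples
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError(
            f"{motion.session_id}: constant motion trace; percentiles coincide"
        )
    dt = 1.0 / motion.sample_rate
    if smooth > 0:
        w = max(int(round(smooth * motion.sample_rate)), 1)
        x = np.convolve(x, np.ones(w) / w, mode="same")
    hi = float(np.percentile(x, active_percentile))
    lo = float(np.percentile(x, quiet_percentile))
    if hi <= lo:
        raise ValueError(
            f"{motion.session_id}: degenerate trace; thresholds coincide"
        )
    # comparisons are inclusive so that traces with tied values (e.g. a
    # square wave whose high level IS the 80th percentile) still split;
    # for continuous traces the difference has measure zero
    active = _samples_to_epochs(x >= hi, dt, min_epoch)
    quiet = _samples_to_epochs(x <= lo, dt, min_epoch)
    return StateEpochs(
        active=active, quiet=quiet, active_threshold=hi, quiet_threshold=lo
    )


def _epoch_rates(t: np.ndarray, epochs: tuple[tuple[float, float], ...]) -> np.ndarray:
    rates = []
    for s, e in epochs:
        n = np.count_nonzero((t >= s) & (t < e))
        rates.append(n / (e - s))
    return np.asarray(rates)


def compute_bsmi(
    train: SpikeTrain,
    epochs: StateEpochs,
    min_state_time: float = 10.0,
    min_epochs: int = 3,
    alpha: float = 0.05,
) -> BSRecord:
    """BSMI and the per-neuron modulation category.

    Pooled rates: spikes in all active (quiet) epochs divided by total
    active (quiet) time.  The significance test is a two-sample
    rank-sum on the per-epoch rate vectors; with fewer than
    ``min_epochs`` epochs per state the neuron is categorised
    ``no_change`` with the insufficient-data flag set.
    """
    if epochs.active_time < min_state_time or epochs.quiet_time < min_state_time:
        raise ValueError(
            f"{train.neuron_id}: less than {min_state_time} s in a state"
        )
    t = train.spike_times
    a_rates = _epoch_rates(t, epochs.active)
    q_rates = _epoch_rates(t, epochs.quiet)
    fr_active = sum(
        np.count_nonzero((t >= s) & (t < e)) for s, e in epochs.active
    ) / epochs.active_time
    fr_quiet = sum(
        np.count_nonzero((t >= s) & (t < e)) for s, e in epochs.quiet
    ) / epochs.quiet_time
    if fr_active + fr_quiet == 0:
        bsmi = np.nan
    else:
        bsmi = (fr_active - fr_quiet) / (fr_active + fr_quiet)
    category, p_value, insufficient = _classify(
        a_rates, q_rates, fr_active - fr_quiet, alpha, min_epochs
    )
    return BSRecord(
        neuron_id=train.neuron_id,
        fr_active=float(fr_active),
        fr_quiet=float(fr_quiet),
        bsmi=float(bsmi),
        active_epoch_rates=a_rates,
        quiet_epoch_rates=q_rates,
        category=category,
        p_value=p_value,
        insufficient_data=insufficient,
    )


def _classify(
    a_rates: np.ndarray,
    q_rates: np.ndarray,
    rate_diff: float,
    alpha: float,
    min_epochs: int,
) -> tuple[str, float, bool]:
    if a_rates.size < min_epochs or q_rates.size < min_epochs:
        return "no_change", np.nan, True
    if np.ptp(np.concatenate([a_rates, q_rates])) == 0:
        return "no_change", 1.0, False
    stat = stats.mannwhitneyu(a_rates, q_rates, alternative="two-sided")
    p = float(stat.pvalue)
    if p < alpha:
        return ("increase" if rate_diff > 0 else "decrease"), p, False
    return "no_change", p, False


def classify_modulation(record: BSRecord, alpha: float = 0.05,
                        min_epochs: int = 3) -> str:
    """Category from an existing record's per-epoch rates (see
    :func:`compute_bsmi`); provided for re-testing at other levels."""
    cat, _, _ = _classify(
        record.active_epoch_rates,
        record.quiet_epoch_rates,
        record.fr_active - record.fr_quiet,
        alpha,
        min_epochs,
    )
    return cat
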