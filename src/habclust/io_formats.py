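"""Domain types and plain-text input/output.

All on-disk formats are diffable text: long-format CSV for spike times
(one row per spike), one metadata CSV per dataset, CSV for trial and
motion tables, JSON for structured results, YAML for run configuration.
Time is expressed in seconds everywhere, both in files and in APIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("habclust")

CONDITIONS = ("anesthetized", "awake")
ANESTHETICS = ("ketamine_xylazine", "isoflurane", "none")


class DatasetFormatError(ValueError):
    """Raised when an on-disk dataset violates the documented layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpikeTrain:
    """A single neuron's spike times over one recording.

    Parameters
    ----------
    neuron_id : str
        Unique identifier of the recording.
    spike_times : ndarray of float
        Strictly increasing spike times in seconds, all within
        ``[0, duration]``.  Simultaneous spikes are a format error.
    duration : float
        Recording length in seconds, > 0.
    condition : {"anesthetized", "awake"}
    anesthetic : {"ketamine_xylazine", "isoflurane", "none"}
    session_id : str, optional
        Links the neuron to a motion-energy trace, when one exists.
    """

    neuron_id: str
    spike_times: np.ndarray
    duration: float
    condition: str = "anesthetized"
    anesthetic: str = "none"
    session_id: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if self.duration <= 0:
            raise ValueError(f"{self.neuron_id}: duration must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"{self.neuron_id}: unknown condition {self.condition!r}")
        if self.anesthetic not in ANESTHETICS:
            raise ValueError(f"{self.neuron_id}: unknown anesthetic {self.anesthetic!r}")
        if times.size:
            if not np.all(np.isfinite(times)):
                raise ValueError(f"{self.neuron_id}: non-finite spike times")
            if times[0] < 0 or times[-1] > self.duration:
                raise ValueError(
                    f"{self.neuron_id}: spike times outside [0, {self.duration}]"
                )
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"{self.neuron_id}: spike times not strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals in seconds (length ``n_spikes - 1``)."""
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class TrialSet:
    """Stimulus trials for one neuron (e.g., foot-shock onsets).

    Onsets are ascending and spaced at least ``stim_duration`` apart.
    """

    neuron_id: str
    onsets: np.ndarray
    stim_duration: float = 0.5

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.stim_duration <= 0:
            raise ValueError(f"{self.neuron_id}: stim_duration must be > 0")
        if onsets.size > 1 and np.any(np.diff(onsets) < self.stim_duration):
            raise ValueError(
                f"{self.neuron_id}: trial onsets closer than stim_duration"
            )

    @property
    def n_trials(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class MotionTrace:
    """Regularly sampled, nonnegative motion-energy series for a session."""

    session_id: str
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_rate <= 0:
            raise ValueError(f"{self.session_id}: sample_rate must be > 0")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"{self.session_id}: non-finite motion samples")
        if np.any(samples < 0):
            raise ValueError(f"{self.session_id}: negative motion samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass
class Dataset:
    """A collection of spike trains with optional trials and motion traces."""

    trains: list[SpikeTrain]
    trials: dict[str, TrialSet] = field(default_factory=dict)
    motion: dict[str, MotionTrace] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trains)

    def by_id(self, neuron_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.neuron_id == neuron_id:
                return t
        raise KeyError(neuron_id)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with the published defaults.

    Defaults reproduce the analysis constants where they are stated
    (burst threshold 25 ms, ISI range 0-0.5 s, ACG range +/-0.1 s, eight
    sparse components per histogram bank, 100 mixture restarts,
    similarity threshold 0.6, 80th/20th motion percentiles, alpha 0.05,
    PSTH window -0.2..+1.3 s at 20 ms); the remaining knobs (bin widths,
    sparsity penalty, epoching minima) are this package's documented
    choices.
    """

    seed: int = 0
    # feature extraction
    isi_bin_width: float = 0.005
    isi_max: float = 0.5
    acg_bin_width: float = 0.002
    acg_max: float = 0.1
    burst_threshold: float = 0.025
    min_spikes: int = 10
    # embedding + clustering
    n_components: int = 8
    spca_penalty: float = 1.0
    k_min: int = 1
    k_max: int = 8
    n_restarts: int = 100
    covariance_type: str = "full"
    reg_covar: float = 1e-6
    saturation_frac: float = 0.1
    standardize_features: bool = True
    # matching
    similarity_threshold: float = 0.6
    # foot-shock modulation
    psth_start: float = -0.2
    psth_stop: float = 1.3
    psth_bin_width: float = 0.02
    fsmi_baseline_window: float = 1.0
    fsmi_min_rate: float = 1.0
    auc_window: float = 0.3
    # behavioral state
    active_percentile: float = 80.0
    quiet_percentile: float = 20.0
    motion_smooth: float = 0.5
    min_epoch: float = 0.5
    min_state_time: float = 10.0
    min_epochs: int = 3
    # statistics
    alpha: float = 0.05

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DatasetFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# Dataset reading / writing
# ---------------------------------------------------------------------------

_SPIKES_FILE = "spikes.csv"
_NEURONS_FILE = "neurons.csv"
_TRIALS_FILE = "trials.csv"
_MOTION_FILE = "motion.csv"
_MOTION_META_FILE = "motion_meta.csv"
_LABELS_FILE = "labels.csv"


def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{fname}: missing columns {missing}")


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory into validated domain objects.

    Expected layout (all CSV)::

        neurons.csv      neuron_id, duration_s, condition, anesthetic[, session_id]
        spikes.csv       neuron_id, spike_time_s        (one row per spike)
        trials.csv       neuron_id, onset_s, stim_duration_s     (optional)
        motion.csv       session_id, motion_energy               (optional)
        motion_meta.csv  session_id, sample_rate_hz              (optional)

    Malformed rows raise :class:`DatasetFormatError` naming the file and
    the offending neuron or line.
    """
    root = Path(path)
    meta_path = root / _NEURONS_FILE
    if not meta_path.exists():
        raise DatasetFormatError(f"{meta_path} not found")
    meta = pd.read_csv(meta_path, dtype={"neuron_id": str})
    _require_columns(meta, ["neuron_id", "duration_s", "condition", "anesthetic"], _NEURONS_FILE)
    if meta["neuron_id"].duplicated().any():
        dupes = meta.loc[meta["neuron_id"].duplicated(), "neuron_id"].tolist()
        raise DatasetFormatError(f"{_NEURONS_FILE}: duplicate neuron ids {dupes}")
    if meta["duration_s"].isna().any():
        bad = meta.loc[meta["duration_s"].isna(), "neuron_id"].tolist()
        raise DatasetFormatError(f"{_NEURONS_FILE}: missing duration for {bad}")

    spikes_path = root / _SPIKES_FILE
    if spikes_path.exists():
        spikes = pd.read_csv(spikes_path, dtype={"neuron_id": str})
        _require_columns(spikes, ["neuron_id", "spike_time_s"], _SPIKES_FILE)
        grouped = {k: g["spike_time_s"].to_numpy() for k, g in spikes.groupby("neuron_id")}
    else:
        grouped = {}

    trains: list[SpikeTrain] = []
    for row in meta.itertuples(index=False):
        times = grouped.pop(row.neuron_id, np.empty(0))
        session = getattr(row, "session_id", None)
        if session is not None and (pd.isna(session) or session == ""):
            session = None
        try:
            trains.append(
                SpikeTrain(
                    neuron_id=row.neuron_id,
                    spike_times=times,
                    duration=float(row.duration_s),
                    condition=str(row.condition),
                    anesthetic=str(row.anesthetic),
                    session_id=session,
                )
            )
        except ValueError as exc:
            raise DatasetFormatError(str(exc)) from exc
    if grouped:
        raise DatasetFormatError(
            f"{_SPIKES_FILE}: spikes for unknown neurons {sorted(grouped)}"
        )

    trials: dict[str, TrialSet] = {}
    trials_path = root / _TRIALS_FILE
    if trials_path.exists():
        tdf = pd.read_csv(trials_path, dtype={"neuron_id": str})
        _require_columns(tdf, ["neuron_id", "onset_s", "stim_duration_s"], _TRIALS_FILE)
        for nid, g in tdf.groupby("neuron_id"):
            stim = g["stim_duration_s"].unique()
            if len(stim) != 1:
                raise DatasetFormatError(f"{_TRIALS_FILE}: mixed stim_duration for {nid}")
            try:
                trials[str(nid)] = TrialSet(
                    neuron_id=str(nid),
                    onsets=np.sort(g["onset_s"].to_numpy()),
                    stim_duration=float(stim[0]),
                )
            except ValueError as exc:
                raise DatasetFormatError(str(exc)) from exc

    motion: dict[str, MotionTrace] = {}
    motion_path = root / _MOTION_FILE
    if motion_path.exists():
        mdf = pd.read_csv(motion_path, dtype={"session_id": str})
        _require_columns(mdf, ["session_id", "motion_energy"], _MOTION_FILE)
        meta_m = pd.read_csv(root / _MOTION_META_FILE, dtype={"session_id": str})
        _require_columns(meta_m, ["session_id", "sample_rate_hz"], _MOTION_META_FILE)
        rates = dict(zip(meta_m["session_id"], meta_m["sample_rate_hz"]))
        for sid, g in mdf.groupby("session_id"):
            if sid not in rates:
                raise DatasetFormatError(f"{_MOTION_META_FILE}: no sample rate for {sid}")
            motion[str(sid)] = MotionTrace(
                session_id=str(sid),
                samples=g["motion_energy"].to_numpy(),
                sample_rate=float(rates[sid]),
            )

    ds = Dataset(trains=trains, trials=trials, motion=motion)
    logger.info(
        "read_dataset: %d neurons, %d trial sets, %d motion traces from %s",
        len(ds), len(trials), len(motion), root,
    )
    return ds


def write_dataset(
    dataset: Dataset,
    path: str | Path,
    labels: Sequence[int] | None = None,
) -> None:
    """Write a dataset to the documented CSV layout (see :func:`read_dataset`).

    ``labels``, when given, are ground-truth type labels written to a
    separate ``labels.csv`` so they never leak into the analysis inputs.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    meta = pd.DataFrame(
        {
            "neuron_id": [t.neuron_id for t in dataset.trains],
            "duration_s": [t.duration for t in dataset.trains],
            "condition": [t.condition for t in dataset.trains],
            "anesthetic": [t.anesthetic for t in dataset.trains],
            "session_id": [t.session_id or "" for t in dataset.trains],
        }
    )
    meta.to_csv(root / _NEURONS_FILE, index=False)
    spike_rows = [
        pd.DataFrame({"neuron_id": t.neuron_id, "spike_time_s": t.spike_times})
        for t in dataset.trains
        if t.n_spikes
    ]
    spikes = (
        pd.concat(spike_rows, ignore_index=True)
        if spike_rows
        else pd.DataFrame(columns=["neuron_id", "spike_time_s"])
    )
    spikes.to_csv(root / _SPIKES_FILE, index=False)
    if dataset.trials:
        rows = [
            pd.DataFrame(
                {
                    "neuron_id": ts.neuron_id,
                    "onset_s": ts.onsets,
                    "stim_duration_s": ts.stim_duration,
                }
            )
            for ts in dataset.trials.values()
        ]
        pd.concat(rows, ignore_index=True).to_csv(root / _TRIALS_FILE, index=False)
    if dataset.motion:
        rows = [
            pd.DataFrame({"session_id": m.session_id, "motion_energy": m.samples})
            for m in dataset.motion.values()
        ]
        pd.concat(rows, ignore_index=True).to_csv(root / _MOTION_FILE, index=False)
        pd.DataFrame(
            {
                "session_id": [m.session_id for m in dataset.motion.values()],
                "sample_rate_hz": [m.sample_rate for m in dataset.motion.values()],
            }
        ).to_csv(root / _MOTION_META_FILE, index=False)
    if labels is not None:
        if len(labels) != len(dataset.trains):
            raise ValueError("labels length does not match number of trains")
        pd.DataFrame(
            {
                "neuron_id": [t.neuron_id for t in dataset.trains],
                "label": list(labels),
            }
        ).to_csv(root / _LABELS_FILE, index=False)


def read_labels(path: str | Path) -> pd.Series:
    """Read a ground-truth labels file written by :func:`write_dataset`."""
    df = pd.read_csv(Path(path) / _LABELS_FILE, dtype={"neuron_id": str})
    _require_columns(df, ["neuron_id", "label"], _LABELS_FILE)
    return df.set_index("neuron_id")["label"]


# ---------------------------------------------------------------------------
# Result writing (CSV + JSON); each result type is re-readable
# ---------------------------------------------------------------------------


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV; an empty collection yields a header-only file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


class _ArrayEncoder(json.JSONEncoder):
    def default(self, obj):  # noqa: D102
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_json(payload: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, cls=_ArrayEncoder, indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
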