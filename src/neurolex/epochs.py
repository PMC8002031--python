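"""Epoch containers, trial exclusion, segmentation and ERP averaging.

The pipeline consumes clean (preprocessed) epochs: trials x channels x
samples in µV, -200..+1000 ms around stimulus onset.  Trial exclusion
follows the study convention: response times beyond ±2.5 SD of the
participant x session x lexicality cell mean are removed first (statistics
computed once, on all trials of the cell), then incorrect trials.
Within-session analyses divide a session's retained trials into 10
chronological segments of near-equal size, extras going to the earliest
segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "ErpWaveform",
    "average_erp",
    "exclude_incorrect",
    "exclude_rt_outliers",
    "load_epochs",
    "partition_segments",
    "save_epochs",
    "segment_sizes",
]


@dataclass
class EpochSet:
    """Trials x channels x samples voltage tensor with aligned metadata."""

    data: np.ndarray                  # (n_trials, n_channels, n_samples), µV
    times_ms: np.ndarray              # (n_samples,), relative to stimulus onset
    channel_labels: tuple[str, ...]
    trial_meta: pd.DataFrame          # one row per trial
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_tr, n_ch, n_sa = self.data.shape
        if len(self.channel_labels) != n_ch:
            raise ValueError("channel_labels length mismatch")
        if len(self.times_ms) != n_sa:
            raise ValueError("times_ms length mismatch")
        if len(self.trial_meta) != n_tr:
            raise ValueError("trial_meta must have one row per trial")
        dt = np.diff(self.times_ms)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times_ms must be strictly increasing and uniform")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, trial_mask) -> "EpochSet":
        """Subset trials by boolean mask or integer index, keeping metadata aligned."""
        idx = np.asarray(trial_mask)
        return EpochSet(
            data=self.data[idx],
            times_ms=self.times_ms,
            channel_labels=self.channel_labels,
            trial_meta=self.trial_meta.iloc[idx].reset_index(drop=True),
            sampling_rate=self.sampling_rate,
        )


@dataclass
class ErpWaveform:
    """Per-condition average voltage, baseline-corrected."""

    mean: np.ndarray                  # (n_channels, n_samples), µV
    times_ms: np.ndarray
    channel_labels: tuple[str, ...]
    n_trials: int
    condition: str = ""


DEFAULT_GROUPING = ("participant", "session", "lexicality")


def exclude_rt_outliers(trials: pd.DataFrame,
                        grouping=DEFAULT_GROUPING,
                        n_sd: float = 2.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove trials whose RT lies beyond ±n_sd SD of its cell mean.

    Cell statistics (mean, sample SD) are computed once on all trials of
    the cell, before any removal — the rule is a single pass, not
    iterative.  Cells with fewer than two trials have an undefined SD and
    are retained with a warning.

    Returns (retained trials, per-cell exclusion report).
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("rt_ms must be finite and positive")
    grouping = list(grouping)
    keep = np.ones(len(trials), dtype=bool)
    records = []
    for key, idx in trials.groupby(grouping, sort=True).indices.items():
        vals = rt[idx]
        if len(vals) < 2:
            warnings.warn(f"cell {key}: fewer than 2 trials, SD undefined; retained")
            records.append((*np.atleast_1d(key), len(vals), 0))
            continue
        mean, sd = vals.mean(), vals.std(ddof=1)
        out = np.abs(vals - mean) > n_sd * sd
        keep[idx[out]] = False
        records.append((*np.atleast_1d(key), len(vals), int(out.sum())))
    report = pd.DataFrame(records, columns=grouping + ["n_trials", "n_excluded"])
    return trials[keep].copy(), report


def exclude_incorrect(trials: pd.DataFrame) -> pd.DataFrame:
    """Keep only correct-response trials (applied after RT-outlier removal)."""
    return trials[trials["correct"] == 1].copy()


def partition_segments(n_trials: int, k: int = 10) -> np.ndarray:
    """Segment index (1..k) per trial, chronological order preserved.

    Base size floor(n/k); the first n mod k segments receive one extra
    trial each (e.g. 950 trials -> ten segments of 95, segment 1 holding
    trials 1–95; 1003 trials -> sizes 101,101,101,100,...).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_trials < k:
        raise ValueError(f"cannot partition {n_trials} trials into {k} segments")
    base, rem = divmod(n_trials, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    return np.repeat(np.arange(1, k + 1), sizes)


def segment_sizes(n_trials: int, k: int = 10) -> np.ndarray:
    """Sizes of the k chronological segments."""
    part = partition_segments(n_trials, k)
    return np.bincount(part)[1:]


def _baseline_mask(times_ms: np.ndarray, baseline: tuple[float, float]) -> np.ndarray:
    # half-open [start, stop): the t=0 sample belongs to post-stimulus
    lo, hi = baseline
    mask = (times_ms >= lo) & (times_ms < hi)
    if not mask.any():
        raise ValueError(f"baseline {baseline} ms contains no samples")
    return mask


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)
                     ) -> EpochSet:
    """Subtract each trial's per-channel baseline mean."""
    mask = _baseline_mask(epochs.times_ms, baseline)
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data, epochs.times_ms, epochs.channel_labels,
                    epochs.trial_meta.copy(), epochs.sampling_rate)


def average_erp(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0),
                condition: str = "") -> ErpWaveform:
    """Baseline-correct each trial, then average over trials."""
    if epochs.n_trials == 0:
        raise ValueError("cannot average an empty trial set")
    corrected = baseline_correct(epochs, baseline)
    return ErpWaveform(
        mean=corrected.data.mean(axis=0),
        times_ms=epochs.times_ms,
        channel_labels=epochs.channel_labels,
        n_trials=epochs.n_trials,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# container I/O

def save_epochs(path, epochs: dict[tuple[int, int], EpochSet]) -> None:
    """Write a {(participant, session): EpochSet} mapping to HDF5.

    Layout: group ``sub-<p>/ses-<s>`` with float32 dataset ``data``
    (trials x channels x samples, µV), attrs ``sampling_rate``,
    ``times_ms``, ``channel_labels`` and trial metadata columns under
    ``trials/``.
    """
    with h5py.File(path, "w") as f:
        for (p, s), ep in epochs.items():
            g = f.create_group(f"sub-{p:02d}/ses-{s}")
            g.create_dataset("data", data=ep.data.astype(np.float32),
                             compression="gzip", compression_opts=1)
            g.attrs["sampling_rate"] = ep.sampling_rate
            g.attrs["times_ms"] = ep.times_ms
            g.attrs["channel_labels"] = list(ep.channel_labels)
            tg = g.create_group("trials")
            for col in ep.trial_meta.columns:
                vals = ep.trial_meta[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                tg.create_dataset(col, data=vals)


def load_epochs(path) -> dict[tuple[int, int], EpochSet]:
    """Read the HDF5 epochs container written by save_epochs."""
    out: dict[tuple[int, int], EpochSet] = {}
    with h5py.File(path, "r") as f:
        for sub in f:
            p = int(sub.split("-")[1])
            for ses in f[sub]:
                s = int(ses.split("-")[1])
                g = f[sub][ses]
                meta = {}
                for col in g["trials"]:
                    vals = g["trials"][col][()]
                    if vals.dtype.kind == "S":
                        vals = vals.astype(str)
                    meta[col] = vals
                out[(p, s)] = EpochSet(
                    data=g["data"][()].astype(float),
                    times_ms=np.asarray(g.attrs["times_ms"], dtype=float),
                    channel_labels=tuple(str(c) for c in g.attrs["channel_labels"]),
                    trial_meta=pd.DataFrame(meta),
                    sampling_rate=float(g.attrs["sampling_rate"]),
                )
    return out


def read_brainvision_epochs(vhdr_path, events, tmin_s: float = -0.2,
                            tmax_s: float = 0.998) -> EpochSet:
    """Optional BrainVision (.vhdr/.vmrk/.eeg) reader; requires ``mne``.

    ``events`` is an MNE-style (n, 3) event array.  Provided as a
    convenience for real recordings; the rest of the package is
    format-agnostic and consumes EpochSet directly.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "read_brainvision_epochs requires the optional 'mne' dependency "
            "(pip install neurolex[brainvision])") from exc
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    ep = mne.Epochs(raw, np.asarray(events), tmin=tmin_s, tmax=tmax_s,
                    baseline=None, preload=True, verbose="error")
    data = ep.get_data() * 1e6  # volts -> µV
    meta = pd.DataFrame({"event_sample": ep.events[:, 0],
                         "event_id": ep.events[:, 2]})
    return EpochSet(data=data, times_ms=ep.times * 1000.0,
                    channel_labels=tuple(ep.ch_names), trial_meta=meta,
                    sampling_rate=float(ep.info["sfreq"]))
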