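"""Multiscale entropy: coarse-graining plus sample entropy on single trials.

Follows the classic multiscale-entropy recipe: the signal is averaged
within non-overlapping windows of length tau (scale tau; at 500 Hz scale 1
is a 2 ms window, scale 22 a 44 ms window), and sample entropy is computed
at each scale with pattern length m and tolerance r.  r is fixed once per
trial and channel as ``r_fraction x SD of the original (scale-1) series``
and is NOT recomputed at coarser scales — coarse-graining therefore lowers
the variance relative to r, which is part of the measure.

Sample entropy is -ln(A/B) where B counts ordered template pairs (i < j,
self-matches excluded) matching for m points within Chebyshev distance r,
and A counts pairs matching for m+1 points, both over the first N-m
template start positions.  Entropy is undefined (NaN) when no template
pair matches; undefined trials are excluded from condition averages with
counts recorded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .epochs import EpochSet

__all__ = [
    "MseMatrix",
    "MseParams",
    "coarse_grain",
    "mse_condition",
    "mse_trial",
    "mse_trials",
    "sample_entropy",
    "sampen_counts",
]


@dataclass(frozen=True)
class MseParams:
    """m: pattern length; r_fraction: tolerance as a fraction of the
    scale-1 SD; n_scales: number of coarse-graining scales."""

    m: int = 2
    r_fraction: float = 0.50
    n_scales: int = 22

    def validate(self, n_samples: int | None = None) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_fraction <= 0:
            raise ValueError("r_fraction must be > 0")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if n_samples is not None and n_samples // self.n_scales < self.m + 2:
            warnings.warn(
                f"coarse-grained length {n_samples // self.n_scales} at scale "
                f"{self.n_scales} is shorter than m+2; entropy will often be undefined")

    def scale_window_ms(self, sampling_rate: float) -> np.ndarray:
        """Window length per scale: tau x (1000 / sampling_rate) ms."""
        return np.arange(1, self.n_scales + 1) * 1000.0 / sampling_rate


@dataclass
class MseMatrix:
    """Trial-averaged channels x scales sample entropy for one condition."""

    entropy: np.ndarray          # (n_channels, n_scales), nats; NaN if undefined
    n_valid_trials: np.ndarray   # (n_channels, n_scales) count of defined trials
    scale_window_ms: np.ndarray  # (n_scales,)
    channel_labels: tuple[str, ...]
    n_trials: int

    def to_frame(self, **ids) -> pd.DataFrame:
        """Long-format export: one row per channel x scale."""
        n_ch, n_sc = self.entropy.shape
        df = pd.DataFrame({
            "channel": np.repeat(self.channel_labels, n_sc),
            "scale": np.tile(np.arange(1, n_sc + 1), n_ch),
            "window_ms": np.tile(self.scale_window_ms, n_ch),
            "entropy": self.entropy.ravel(),
            "n_valid_trials": self.n_valid_trials.ravel(),
        })
        for k, v in ids.items():
            df.insert(0, k, v)
        return df


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Average within non-overlapping windows of length tau.

    Output length floor(N/tau); trailing remainder samples are discarded.
    tau=1 returns the series unchanged.
    """
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = x.shape[0]
    if tau > n:
        raise ValueError(f"tau={tau} exceeds series length {n}")
    L = n // tau
    return x[: L * tau].reshape(L, tau).mean(axis=1)


@njit(cache=True)
def _sampen_counts_kernel(x, m, r):  # pragma: no cover - compiled
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


@njit(cache=True)
def _mse_scales_kernel(x, m, r, n_scales):  # pragma: no cover - compiled
    out = np.empty(n_scales)
    for tau in range(1, n_scales + 1):
        L = x.shape[0] // tau
        y = np.empty(L)
        for j in range(L):
            s = 0.0
            for k in range(j * tau, (j + 1) * tau):
                s += x[k]
            y[j] = s / tau
        if L <= m + 1:
            out[tau - 1] = np.nan
            continue
        a, b = _sampen_counts_kernel(y, m, r)
        if a > 0 and b > 0:
            out[tau - 1] = -np.log(a / b)
        else:
            out[tau - 1] = np.nan
    return out


def sampen_counts(series: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Template-match counts (A, B) for sample entropy.

    B: ordered pairs of m-length templates within Chebyshev distance r;
    A: the same for m+1; both over start positions 0..N-m-1.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if x.shape[0] <= m + 1:
        raise ValueError(f"series length {x.shape[0]} too short for m={m}")
    if r <= 0:
        raise ValueError("r must be > 0")
    a, b = _sampen_counts_kernel(x, m, r)
    return int(a), int(b)


def sample_entropy(series: np.ndarray, m: int = 2, r: float = 1.0) -> float:
    """Sample entropy -ln(A/B) in nats; NaN when A or B is zero."""
    a, b = sampen_counts(series, m, r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_trial(series: np.ndarray, params: MseParams = MseParams(),
              sd_ddof: int = 1) -> np.ndarray:
    """Per-scale sample entropy of one trial/channel series.

    The tolerance r = r_fraction x SD(series) is computed on the original
    series and held fixed across scales.  A zero-SD series yields NaN at
    every scale.
    """
    x = np.ascontiguousarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    params.validate(x.shape[0])
    sd = x.std(ddof=sd_ddof)
    if sd == 0:
        warnings.warn("zero-SD series: entropy undefined at all scales")
        return np.full(params.n_scales, np.nan)
    return _mse_scales_kernel(x, params.m, params.r_fraction * sd, params.n_scales)


def mse_trials(epochs: EpochSet, params: MseParams = MseParams(),
               window: str = "full") -> np.ndarray:
    """Trial-level entropy tensor (n_trials, n_channels, n_scales).

    ``window`` selects the samples entering the computation: "full" uses
    the whole epoch (default; maximises coarse-scale series length),
    "post" restricts to t >= 0 ms.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty condition: no trials")
    if window == "full":
        data = epochs.data
    elif window == "post":
        data = epochs.data[:, :, epochs.times_ms >= 0.0]
    else:
        raise ValueError("window must be 'full' or 'post'")
    n_tr, n_ch, n_sa = data.shape
    params.validate(n_sa)
    out = np.empty((n_tr, n_ch, params.n_scales))
    for t in range(n_tr):
        for c in range(n_ch):
            x = np.ascontiguousarray(data[t, c])
            sd = x.std(ddof=1)
            if sd == 0:
                out[t, c] = np.nan
                continue
            out[t, c] = _mse_scales_kernel(x, params.m,
                                           params.r_fraction * sd, params.n_scales)
    return out


def mse_condition(epochs: EpochSet, params: MseParams = MseParams(),
                  window: str = "full",
                  trial_entropy: np.ndarray | None = None) -> MseMatrix:
    """Condition-level MSE: single-trial entropy averaged over trials.

    Cells where a trial's entropy is undefined are excluded from that
    cell's average; ``n_valid_trials`` records how many trials contributed.
    ``trial_entropy`` may pass a precomputed mse_trials tensor to avoid
    recomputation when the same trials enter several condition splits.
    """
    ent = mse_trials(epochs, params, window) if trial_entropy is None else trial_entropy
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        mean = np.nanmean(ent, axis=0)
    return MseMatrix(
        entropy=mean,
        n_valid_trials=np.sum(np.isfinite(ent), axis=0),
        scale_window_ms=params.scale_window_ms(epochs.sampling_rate),
        channel_labels=epochs.channel_labels,
        n_trials=ent.shape[0],
    )
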