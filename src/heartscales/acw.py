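"""Autocorrelation window (ACW) estimation, heartbeat-locked.

The intrinsic neural timescale of a channel is summarised by the ACW-50:
the first time lag at which the signal's autocorrelation function (ACF)
drops below 0.5.  Fast, noise-like dynamics give an ACW-50 near one sample;
slower dynamics give longer windows.  Estimation is heartbeat-locked: a
3-second window is extracted from each R-wave onset, the ACF and ACW-50 are
computed per window (epoch), and epochs are averaged to one value per
electrode, which feeds the spatial cluster statistics.

The ACF estimator is the biased (normalise-by-N) sample autocorrelation on a
1-sample lag grid; the ACW-50 is the first crossing at sample resolution with
no sub-sample interpolation.  Epochs whose ACF never reaches 0.5 within the
window are flagged missing (NaN) rather than censored at the maximum lag.

For heartbeat-locked epochs the mean subtracted before correlation is the
channel's whole-recording mean, not the epoch mean: a 3-s window spans only
~15 timescales of a slow (tau ~ 0.2 s) channel, and subtracting the window's
own mean shrinks its ACF by roughly 2*tau*fs/N - enough to bias the ACW-50
of slow channels downward by a third.  The band-passed signal is zero-mean
to begin with, so recording-level demeaning costs nothing for fast channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .io import ConfigError, EventTrain, Recording

__all__ = [
    "ACFCurve",
    "ChannelScalarMap",
    "acf",
    "acf_batch",
    "acw50",
    "heartbeat_acw",
    "sliding_acw",
    "group_acf_summary",
    "maps_to_matrix",
]


@dataclass
class ACFCurve:
    """Sample autocorrelation at lags 0..max_lag (ACF(0) = 1)."""

    lags: np.ndarray
    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.lags = np.asarray(self.lags)
        self.values = np.asarray(self.values, float)
        if self.values[0] != 1.0:
            raise ValueError("ACF must be 1 at lag 0")


@dataclass
class ChannelScalarMap:
    """One scalar per electrode for one subject x condition.

    ``values`` holds ACW-50 in seconds (NaN = missing on that channel);
    ``n_epochs`` counts the usable (non-flagged) epochs per channel.
    """

    labels: list[str]
    values: np.ndarray
    subject: str = ""
    condition: str = ""
    n_epochs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("values must align with labels")
        if self.n_epochs is not None:
            self.n_epochs = np.asarray(self.n_epochs, int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject": self.subject,
            "condition": self.condition,
            "channel": self.labels,
            "acw50_s": self.values,
            "n_epochs": (np.zeros(len(self.labels), int)
                         if self.n_epochs is None else self.n_epochs),
        })

    @staticmethod
    def concat_frames(maps: list["ChannelScalarMap"]) -> pd.DataFrame:
        return pd.concat([m.to_frame() for m in maps], ignore_index=True)


def acf_batch(epochs: np.ndarray, max_lag: int,
              mean: float | np.ndarray | None = None) -> np.ndarray:
    """Biased sample ACF of each row, lags 0..max_lag, via FFT.

    ``mean`` is the value subtracted before correlation; by default each
    row's own mean (appropriate for standalone segments).  Pass the
    channel's recording-level mean for short heartbeat-locked epochs (see
    module docstring).  Rows with zero variance get all-NaN ACF (flagged,
    not an error, so a batch can carry occasional degenerate epochs).
    """
    x = np.asarray(epochs, float)
    if x.ndim == 1:
        x = x[None, :]
    n = x.shape[1]
    if not 1 <= max_lag < n:
        raise ConfigError("need segment length > max_lag >= 1")
    if not np.all(np.isfinite(x)):
        raise ConfigError("ACF input must be finite")
    xc = x - (x.mean(axis=1, keepdims=True) if mean is None else mean)
    nfft = sp_fft.next_fast_len(2 * n)
    spec = sp_fft.rfft(xc, nfft, axis=1)
    acov = sp_fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :max_lag + 1]
    acov /= n  # biased estimator
    var = acov[:, :1].copy()
    bad = var[:, 0] <= 0
    var[bad] = 1.0
    rho = acov / var
    rho[bad] = np.nan
    rho[~bad, 0] = 1.0  # exact, despite rounding
    return rho


def acf(segment: np.ndarray, max_lag: int, fs: float = 1.0) -> ACFCurve:
    """Sample ACF of a single segment (mean-removed, biased, normalised)."""
    rho = acf_batch(np.asarray(segment, float).ravel(), max_lag)[0]
    if np.any(np.isnan(rho)):
        raise ConfigError("ACF undefined for a zero-variance segment")
    return ACFCurve(lags=np.arange(max_lag + 1), values=rho, fs=fs)


def _first_crossing(rho: np.ndarray, threshold: float) -> float:
    """First lag k >= 1 with rho[k] < threshold; NaN if none."""
    below = rho[1:] < threshold
    idx = np.argmax(below)
    if not below[idx]:
        return np.nan
    return float(idx + 1)


def acw50(curve: ACFCurve | np.ndarray, fs: float | None = None,
          threshold: float = 0.5) -> float:
    """ACW-50 in seconds: first lag where the ACF drops below ``threshold``.

    Returns NaN (flagged missing) when the ACF never crosses within the
    available lags - never silently the maximum lag.
    """
    if isinstance(curve, ACFCurve):
        rho, fs = curve.values, curve.fs
    else:
        rho = np.asarray(curve, float)
        if fs is None:
            raise ConfigError("fs required for array input")
    k = _first_crossing(rho, threshold)
    return k / fs if np.isfinite(k) else np.nan


def _epoch_starts(rec: Recording, rpeaks: EventTrain, window: float,
                  exclude_cross_block: bool) -> np.ndarray:
    wlen = int(round(window * rec.fs))
    starts = np.round(rpeaks.times * rec.fs).astype(int)
    ok = (starts >= 0) & (starts + wlen <= rec.n_samples)
    if exclude_cross_block and len(rec.block_bounds) > 1:
        bounds = np.asarray(sorted(rec.block_bounds) + [rec.duration])
        t0 = starts / rec.fs
        t1 = (starts + wlen) / rec.fs
        blk0 = np.searchsorted(bounds, t0, side="right")
        blk1 = np.searchsorted(bounds, t1 - 0.5 / rec.fs, side="right")
        ok &= blk0 == blk1
    return starts[ok]


def heartbeat_acw(rec: Recording, rpeaks: EventTrain, window: float = 3.0,
                  exclude_cross_block: bool = True,
                  exclude_channels: set[str] | None = None
                  ) -> ChannelScalarMap:
    """Heartbeat-locked ACW-50 map: one value per electrode.

    For every R-peak ``t0`` whose window ``[t0, t0 + window)`` lies inside
    the recording (and, by default, inside one task block), the per-channel
    ACF and ACW-50 are computed on that epoch; epochs are then averaged per
    channel, ignoring flagged-missing epochs.  Overlapping windows are
    permitted (inherent whenever the heart rate exceeds 20 bpm at the
    default 3-s window).
    """
    exclude = set(exclude_channels or ())
    wlen = int(round(window * rec.fs))
    if wlen < 2:
        raise ConfigError("window too short")
    starts = _epoch_starts(rec, rpeaks, window, exclude_cross_block)
    if starts.size == 0:
        raise ConfigError("no R-peak has a full window inside the recording")
    max_lag = wlen - 1
    idx = starts[:, None] + np.arange(wlen)[None, :]
    values = np.full(rec.n_channels, np.nan)
    n_ep = np.zeros(rec.n_channels, int)
    for c, lab in enumerate(rec.labels):
        if lab in exclude:
            continue
        rho = acf_batch(rec.data[c][idx], max_lag,
                        mean=float(rec.data[c].mean()))
        per_epoch = np.array([_first_crossing(r, 0.5) for r in rho]) / rec.fs
        good = np.isfinite(per_epoch)
        n_ep[c] = int(good.sum())
        if n_ep[c]:
            values[c] = per_epoch[good].mean()
    if not np.any(np.isfinite(values)):
        raise ConfigError("zero usable epochs on every channel")
    return ChannelScalarMap(
        labels=list(rec.labels), values=values, subject=rec.subject,
        condition=rec.condition, n_epochs=n_ep,
        meta={"window_s": window, "n_rpeaks_used": int(starts.size)})


def sliding_acw(x: np.ndarray, fs: float, window: float = 3.0,
                step: float | None = None) -> float:
    """Continuous sliding-window ACW-50 (epoch placement ignores heartbeats).

    Reference estimate for stationary signals: for such signals the
    heartbeat-locked estimate should agree with this one.
    """
    x = np.asarray(x, float).ravel()
    wlen = int(round(window * fs))
    hop = wlen if step is None else max(1, int(round(step * fs)))
    starts = np.arange(0, x.size - wlen + 1, hop)
    if starts.size == 0:
        raise ConfigError("signal shorter than one window")
    idx = starts[:, None] + np.arange(wlen)[None, :]
    rho = acf_batch(x[idx], wlen - 1, mean=float(x.mean()))
    vals = np.array([_first_crossing(r, 0.5) for r in rho]) / fs
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ConfigError("no epoch ACF crossed 0.5")
    return float(vals.mean())


def group_acf_summary(curves: dict[str, np.ndarray], groups: dict[str, str]
                      ) -> dict[str, np.ndarray]:
    """Pointwise mean ACF across subjects, per group (QC of the 0.5 reach).

    Parameters
    ----------
    curves : subject id -> ACF array (common lag grid)
    groups : subject id -> group label
    """
    out: dict[str, list[np.ndarray]] = {}
    for sub, curve in curves.items():
        out.setdefault(groups[sub], []).append(np.asarray(curve, float))
    if not out:
        raise ConfigError("no subjects")
    return {g: np.mean(np.vstack(v), axis=0) for g, v in out.items()}


def maps_to_matrix(maps: list[ChannelScalarMap], labels: list[str] | None = None
                   ) -> tuple[np.ndarray, list[str]]:
    """Stack scalar maps into a (n_subjects, n_channels) matrix."""
    if not maps:
        raise ConfigError("no maps")
    if labels is None:
        labels = list(maps[0].labels)
    rows = []
    for m in maps:
        if list(m.labels) == list(labels):
            rows.append(m.values)
        else:
            lut = {lab: i for i, lab in enumerate(m.labels)}
            try:
                rows.append(m.values[[lut[lab] for lab in labels]])
            except KeyError as e:
                raise ConfigError(f"map missing channel {e}") from None
    return np.vstack(rows), list(labels)
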