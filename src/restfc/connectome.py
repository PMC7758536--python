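"""Static and dynamic functional connectivity matrices.

Static connectivity (``sfc_z``) is the Fisher-z transformed Pearson
correlation of every ROI pair over the full time series.  Dynamic
connectivity (``dfc_sd``) slides correlation windows along the series in
steps of one TR and summarizes each edge by the standard deviation of its
windowed correlations — a temporal-variability index where larger values
mean a less stable connection.  Windowed correlations are kept on the raw
``r`` scale (no Fisher transform).

Two window policies are provided: ``fixed`` (constant length, default
targeting ~34 s) and ``adaptive`` (per-edge, per-start length set by the
mean instantaneous frequency of the two band-limited signals around the
start frame; an approximation to single-scale time-dependent windowing).
Windows are rectangular, left-aligned, and partial end windows are
discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from .core import ConnectivityMatrix, RoiTimeSeries, edge_index_pairs

__all__ = ["WindowScheme", "static_fc", "window_lengths", "dynamic_fc"]

log = logging.getLogger(__name__)

DEFAULT_TARGET_SECONDS = 34.0
DEFAULT_MIN_LEN = 10
DEFAULT_MAX_LEN = 20
_BAND = (0.008, 0.1)  # Hz, passband for the adaptive policy


@dataclass
class WindowScheme:
    """Sliding-window layout for one time series.

    ``lengths`` is a scalar (fixed policy) or an ``n_edges x n_frames``
    integer array of the window length starting at each frame (adaptive
    policy, edges in the shared i<j order).  ``step`` is in frames.
    """

    policy: str
    lengths: int | np.ndarray
    step: int = 1
    n_frames: int = 0
    min_len: int = DEFAULT_MIN_LEN
    meta: dict = field(default_factory=dict)

    def mean_length(self) -> float:
        """Mean window length in frames over all usable placements."""
        if np.isscalar(self.lengths):
            return float(self.lengths)
        L = np.asarray(self.lengths)
        starts = np.arange(L.shape[1])
        usable = (starts[None, :] + L) <= self.n_frames
        return float(L[usable].mean())


def static_fc(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Fisher-z Pearson correlation matrix over the full series."""
    if ts.n_frames < 3:
        raise ValueError("static connectivity needs at least 3 frames")
    sd = ts.data.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance ROI: {ts.roi_labels[bad[0]]}")
    r = np.corrcoef(ts.data.T)
    iu, ju = edge_index_pairs(ts.n_roi)
    sat = np.nonzero(np.abs(r[iu, ju]) >= 1.0 - 1e-15)[0]
    if sat.size:
        i, j = iu[sat[0]], ju[sat[0]]
        raise ValueError(
            f"|r| = 1 between {ts.roi_labels[i]} and {ts.roi_labels[j]}: Fisher z undefined"
        )
    np.fill_diagonal(r, 0.0)  # keep arctanh finite; diagonal is undefined anyway
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return ConnectivityMatrix(z, "sfc_z", list(ts.roi_labels), ts.subject_id)


def _instantaneous_frequency(ts: RoiTimeSeries) -> np.ndarray:
    """Per-ROI instantaneous frequency (Hz) of the band-limited signal."""
    n, tr = ts.n_frames, ts.tr_seconds
    freqs = np.fft.rfftfreq(n, tr)
    keep = (freqs >= _BAND[0]) & (freqs <= _BAND[1])
    spec = np.fft.rfft(ts.data - ts.data.mean(axis=0), axis=0)
    spec[~keep] = 0.0
    band = np.fft.irfft(spec, n=n, axis=0)
    phase = np.unwrap(np.angle(hilbert(band, axis=0)), axis=0)
    ifreq = np.gradient(phase, axis=0) / (2 * np.pi * tr)
    # light smoothing: a pure tone should map to its own frequency
    kernel = np.ones(5) / 5.0
    sm = np.apply_along_axis(lambda c: np.convolve(c, kernel, mode="same"), 0, ifreq)
    return np.clip(sm, _BAND[0], _BAND[1])


def window_lengths(
    ts: RoiTimeSeries,
    policy: str = "fixed",
    target_seconds: float = DEFAULT_TARGET_SECONDS,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    step: int = 1,
) -> WindowScheme:
    """Build the window scheme for a series under the given policy."""
    if policy not in ("fixed", "adaptive"):
        raise ValueError(f"unknown window policy {policy!r}")
    if policy == "fixed":
        L = int(round(target_seconds / ts.tr_seconds))
        if L < 3:
            raise ValueError("fixed window shorter than 3 frames")
        if L > ts.n_frames:
            raise ValueError(f"window of {L} frames exceeds series length {ts.n_frames}")
        return WindowScheme("fixed", L, step, ts.n_frames, min_len=min_len,
                            meta={"target_seconds": target_seconds})
    if max_len > ts.n_frames:
        raise ValueError(f"max window {max_len} exceeds series length {ts.n_frames}")
    ifreq = _instantaneous_frequency(ts)
    iu, ju = edge_index_pairs(ts.n_roi)
    f_edge = 0.5 * (ifreq[:, iu] + ifreq[:, ju])  # frames x edges
    L = np.clip(np.round(1.0 / (f_edge * ts.tr_seconds)), min_len, max_len).astype(int)
    return WindowScheme("adaptive", L.T.copy(), step, ts.n_frames, min_len=min_len,
                        meta={"band_hz": _BAND, "min_len": min_len, "max_len": max_len})


def _windowed_correlations(data: np.ndarray, length: int, step: int) -> np.ndarray:
    """Correlation of every ROI pair in every window: (n_windows, n_edges).

    Windows with a zero-variance ROI produce NaN for that ROI's edges.
    """
    W = sliding_window_view(data, length, axis=0)[::step]  # (n_win, n_roi, L)
    Wc = W - W.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(Wc, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Wn = np.where(norm > 0, Wc / norm, np.nan)
    C = Wn @ Wn.transpose(0, 2, 1)
    iu, ju = edge_index_pairs(data.shape[1])
    return np.clip(C[:, iu, ju], -1.0, 1.0)


def dynamic_fc(ts: RoiTimeSeries, scheme: WindowScheme) -> ConnectivityMatrix:
    """Temporal-variability index: SD of windowed correlations per edge."""
    n_roi = ts.n_roi
    iu, ju = edge_index_pairs(n_roi)
    n_edge = iu.size

    if np.isscalar(scheme.lengths):
        rs = _windowed_correlations(ts.data, int(scheme.lengths), scheme.step)
    else:
        L = np.asarray(scheme.lengths)
        if L.shape != (n_edge, ts.n_frames):
            raise ValueError("adaptive lengths must be n_edges x n_frames")
        starts = np.arange(0, ts.n_frames, scheme.step)
        rs = np.full((starts.size, n_edge), np.nan)
        for length in np.unique(L):
            C = _windowed_correlations(ts.data, int(length), 1)  # all starts
            for w, s in enumerate(starts):
                if s + length > ts.n_frames:
                    continue
                sel = L[:, s] == length
                rs[w, sel] = C[s, sel]

    usable = np.isfinite(rs)
    n_usable = usable.sum(axis=0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.warning("skipped %d zero-variance or out-of-range windows", n_skipped)
    if np.any(n_usable < 3):
        k = int(np.argmin(n_usable))
        raise ValueError(
            f"edge ({iu[k]}, {ju[k]}) has only {int(n_usable[k])} usable windows (< 3): "
            "series too short for a stable variability index"
        )
    sd = np.nanstd(rs, axis=0, ddof=1)
    mat = np.full((n_roi, n_roi), np.nan)
    mat[iu, ju] = sd
    mat[ju, iu] = sd
    meta = {"policy": scheme.policy, "step": scheme.step,
            "mean_window_frames": scheme.mean_length(),
            "mean_window_seconds": scheme.mean_length() * ts.tr_seconds}
    return ConnectivityMatrix(mat, "dfc_sd", list(ts.roi_labels), ts.subject_id, meta=meta)
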