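"""Behavioral event detection and aligned-window extraction.

Movement onsets are found per trial as the first upward crossing of 70% of
the trial's peak speed, searching from 250 ms after trial start; trials whose
first (forward scan) and last (backward scan) crossings disagree — multiple
speed peaks, corrective movements — are rejected. Speech onset/offset come
from peaks of the differentiated microphone envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .session import BinnedFeatures, ValidationError, validate_trials


@dataclass
class AlignmentSpec:
    search_offset_ms: float = 250.0  # skipped after trial start
    peak_frac: float = 0.70
    window_pre_ms: float = 250.0
    window_post_ms: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.peak_frac < 1):
            raise ValidationError(f"AlignmentSpec.peak_frac: need 0 < f < 1, got {self.peak_frac}")
        if self.window_pre_ms <= 0 or self.window_post_ms <= 0:
            raise ValidationError("AlignmentSpec: window bounds must be positive")


def _crossings(seg: np.ndarray, thr: float) -> np.ndarray:
    """Indices i with seg[i] >= thr and seg[i-1] < thr (upward crossings)."""
    above = seg >= thr
    up = above[1:] & ~above[:-1]
    return np.nonzero(up)[0] + 1


def movement_onsets(
    speed: np.ndarray,
    trials: pd.DataFrame,
    spec: AlignmentSpec = AlignmentSpec(),
    bin_ms: float = 20.0,
    t0_ms: float = 0.0,
) -> pd.DataFrame:
    """Fill align_ms and accepted for each trial from the speed series.

    Within [start + 250 ms, stop]: threshold = peak_frac * max speed; the
    alignment point is the first upward crossing. A trial is accepted only
    when the first crossing scanning forward equals the last crossing
    scanning backward (single dominant speed peak). Trials whose speed starts
    at or above threshold have no defined crossing and are rejected.
    """
    validate_trials(trials)
    out = trials.copy()
    speed = np.asarray(speed, dtype=float)
    n = speed.shape[0]
    for idx, tr in out.iterrows():
        i0 = int(np.ceil((tr.start_ms + spec.search_offset_ms - t0_ms) / bin_ms))
        i1 = int(np.floor((tr.stop_ms - t0_ms) / bin_ms))
        i0, i1 = max(i0, 0), min(i1, n)
        seg = speed[i0:i1]
        if seg.size < 2:
            out.at[idx, "accepted"] = False
            continue
        thr = spec.peak_frac * seg.max()
        ups = _crossings(seg, thr)
        if ups.size == 0:
            out.at[idx, "accepted"] = False
            continue
        first, last = ups[0], ups[-1]
        if first != last:
            out.at[idx, "accepted"] = False
            continue
        out.at[idx, "align_ms"] = t0_ms + (i0 + first) * bin_ms
        out.at[idx, "accepted"] = True
    return out


def extract_aligned(
    x: BinnedFeatures,
    trials: pd.DataFrame,
    pre_ms: float = 250.0,
    post_ms: float = 500.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut aligned windows around each accepted trial's align_ms.

    Returns ``(tensor, labels)`` with tensor of shape
    ``trials x channels x bins``. The window spans ``floor(pre/bin)`` bins
    before the alignment bin through ``floor(post/bin)`` bins after it, with
    the alignment bin included: ``floor((pre + post)/bin)`` bins in total
    (37 for 250/500 ms at 20 ms). Trials whose window leaves the session are
    dropped.
    """
    n_pre = int(np.floor(pre_ms / x.bin_ms))
    n_post = int(np.floor(post_ms / x.bin_ms))
    n_bins = n_pre + n_post
    wins, labels = [], []
    for _, tr in trials.iterrows():
        if not tr.accepted or np.isnan(tr.align_ms):
            continue
        a = x.time_to_bin(tr.align_ms)
        lo, hi = a - n_pre, a + n_post
        if lo < 0 or hi > x.n_bins:
            continue
        wins.append(x.values[:, lo:hi])
        labels.append(tr.condition_label)
    if not wins:
        return np.zeros((0, x.n_channels, n_bins)), np.array([])
    return np.stack(wins), np.asarray(labels)


def audio_envelope(
    mic: np.ndarray,
    fs_hz: float,
    hp_hz: float = 65.0,
    lp_hz: float = 10.0,
    out_fs_hz: float = 50.0,
    order: int = 4,
) -> np.ndarray:
    """Microphone waveform -> low-rate speech envelope.

    Mean-center, causal high-pass at ``hp_hz``, rectify, causal low-pass at
    ``lp_hz``, downsample to ``out_fs_hz`` (the 20 ms clock).
    """
    if fs_hz <= 2 * hp_hz:
        raise ValidationError(f"audio_envelope: fs {fs_hz} too low for high-pass at {hp_hz}")
    x = np.asarray(mic, dtype=float)
    x = x - x.mean()
    b, a = signal.butter(order, hp_hz, btype="highpass", fs=fs_hz)
    x = signal.lfilter(b, a, x)
    x = np.abs(x)
    b, a = signal.butter(order, lp_hz, btype="lowpass", fs=fs_hz)
    x = signal.lfilter(b, a, x)
    step = fs_hz / out_fs_hz
    idx = np.floor(np.arange(0, x.shape[0], step)).astype(int)
    return x[idx[idx < x.shape[0]]]


def speech_onset_offset(
    envelope: np.ndarray,
    go_ms: float,
    stop_ms: float,
    peak_min: float = 3.5,
    fs_hz: float = 50.0,
    min_sep_ms: float = 60.0,
) -> tuple[float | None, float | None]:
    """Speech onset/offset from peaks of the differentiated envelope.

    The envelope is differentiated (first difference / dt); within
    [go_ms, stop_ms] the onset is the first local maximum of the derivative
    with magnitude >= ``peak_min`` and the offset the last local maximum of
    the negated derivative with magnitude >= ``peak_min``. Returns (None,
    None) when no qualifying positive peak exists; the caller decides trial
    rejection.
    """
    env = np.asarray(envelope, dtype=float)
    dt_s = 1.0 / fs_hz
    d = np.diff(env) / dt_s
    t_ms = (np.arange(d.shape[0]) + 0.5) / fs_hz * 1000.0
    sel = (t_ms >= go_ms) & (t_ms <= stop_ms)
    if not np.any(sel):
        return None, None
    lo = np.nonzero(sel)[0][0]
    dseg = d[sel]
    dist = max(int(round(min_sep_ms / 1000.0 * fs_hz)), 1)
    pos, _ = signal.find_peaks(dseg, height=peak_min, distance=dist)
    neg, _ = signal.find_peaks(-dseg, height=peak_min, distance=dist)
    onset = t_ms[lo + pos[0]] if pos.size else None
    offset = t_ms[lo + neg[-1]] if neg.size else None
    if onset is None:
        return None, None
    return onset, offset
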