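"""Signal preprocessing: broadband -> model-ready binned features.

Covers LFP extraction (band-pass/low-pass, resampling, powerline notches),
threshold-crossing detection, short-time-Fourier-transform band power in
20 ms bins, channel quality control, log + causal z-scoring against a 3 min
rolling window, Gaussian smoothing, per-channel min-max quantization,
band-limited downsampling, and coincident/correlated spike cleaning with
20 ms rebinning.

Conventions
-----------
* The STFT uses a rectangular window of ``fs / freq_res_hz`` samples and a hop
  of ``shift_frac`` times the window, which must equal one 20 ms output bin.
  A frequency component belongs to a band if its center frequency f satisfies
  ``lo <= f < hi`` (one-sided spectrum, no doubling; the absolute scale
  cancels in the log + z-score).
* Causal operations never read future samples; this is covered by
  prefix-invariance tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .session import (
    BinnedFeatures,
    BroadbandRecording,
    FeatureFlags,
    FrequencyBand,
    ValidationError,
)

EPS = 1e-8  # zero-variance / log-clamp guard


# ---------------------------------------------------------------------------
# LFP extraction from broadband voltage
# ---------------------------------------------------------------------------


def _notch_harmonics(x: np.ndarray, fs: float, base_hz: float = 60.0, q: float = 35.0) -> np.ndarray:
    """Causal 2nd-order IIR notches at harmonics of base_hz below Nyquist."""
    f = base_hz
    while f < fs / 2:
        b, a = signal.iirnotch(f, q, fs=fs)
        x = signal.lfilter(b, a, x, axis=-1)
        f += base_hz
    return x


def _resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase FIR anti-aliased resampling (cutoff 0.9x the new Nyquist)."""
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    # resample_poly's default kaiser filter cuts at the new Nyquist; tighten to 0.9x
    max_rate = max(up, down)
    half_len = 25 * max_rate  # long kaiser FIR: narrow transition at 0.9x Nyquist
    cutoff = 0.9 / max_rate
    win = signal.firwin(2 * half_len + 1, cutoff, window=("kaiser", 5.0))
    return signal.resample_poly(x, up, down, axis=-1, window=win)


def extract_lfp(broadband: BroadbandRecording, pipeline: str = "monkey") -> BroadbandRecording:
    """Broadband voltage -> 2 kHz LFP.

    ``monkey``: causal 1st-order band-pass 0.3-500 Hz, resample to 2 kHz,
    notch at 60 Hz harmonics. ``human``: 5th-order Butterworth low-pass at
    1000 Hz, downsample to 2 kHz, notch at 60 Hz harmonics.
    """
    fs = broadband.fs_hz
    fs_out = 2000.0
    if pipeline == "monkey":
        if fs < 2 * 500.0:
            raise ValidationError(f"extract_lfp: fs {fs} too low for a 500 Hz band edge")
        b, a = signal.butter(1, [0.3, 500.0], btype="bandpass", fs=fs)
        x = signal.lfilter(b, a, broadband.samples, axis=-1)
    elif pipeline == "human":
        if fs < 2 * 1000.0:
            raise ValidationError(f"extract_lfp: fs {fs} too low for a 1000 Hz cutoff")
        b, a = signal.butter(5, 1000.0, btype="lowpass", fs=fs)
        x = signal.lfilter(b, a, broadband.samples, axis=-1)
    else:
        raise ValidationError(f"extract_lfp: unknown pipeline {pipeline!r}")
    if fs != fs_out:
        x = _resample_to(x, fs, fs_out)
    x = _notch_harmonics(x, fs_out)
    return BroadbandRecording(samples=x, fs_hz=fs_out, channel_ids=list(broadband.channel_ids))


def detect_threshold_crossings(
    broadband: BroadbandRecording,
    threshold_rms: float = -4.5,
    band: FrequencyBand = FrequencyBand(250.0, 5000.0),
    filter_order: int = 4,
    refractory_ms: float = 1.0,
) -> BinnedFeatures:
    """Unsorted multiunit events from broadband voltage, on a 1 ms raster.

    Band-pass filter, per-channel threshold at ``threshold_rms`` times the RMS
    of the filtered trace, count downward crossings with a refractory period.
    """
    fs = broadband.fs_hz
    if fs < 2 * band.hi_hz:
        raise ValidationError(f"detect_threshold_crossings: fs {fs} < 2x band.hi {band.hi_hz}")
    b, a = signal.butter(filter_order, [band.lo_hz, band.hi_hz], btype="bandpass", fs=fs)
    x = signal.lfilter(b, a, broadband.samples, axis=-1)
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    thr = threshold_rms * rms  # negative multiplier -> negative threshold
    below = x < thr
    crossings = below & ~np.roll(below, 1, axis=-1)
    crossings[:, 0] = False  # a crossing needs a predecessor above threshold
    n_ms = int(np.floor(broadband.n_samples / fs * 1000.0))
    counts = np.zeros((broadband.n_channels, n_ms), dtype=np.int64)
    refr = refractory_ms / 1000.0
    for c in range(broadband.n_channels):
        idx = np.nonzero(crossings[c])[0]
        if idx.size == 0:
            continue
        times = idx / fs
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refr:
                kept.append(t)
        bins = np.floor(np.asarray(kept) * 1000.0).astype(int)
        bins = bins[bins < n_ms]
        np.add.at(counts[c], bins, 1)
    return BinnedFeatures(
        values=counts,
        bin_ms=1.0,
        t0_ms=0.0,
        kind="spike_counts",
        channel_ids=list(broadband.channel_ids),
    )


# ---------------------------------------------------------------------------
# STFT band power
# ---------------------------------------------------------------------------


@dataclass
class PowerSpec:
    """STFT band-power settings: window = 1/freq_res, hop = one output bin."""

    band: FrequencyBand
    freq_res_hz: float = 5.0
    shift_frac: float = 0.10
    bin_ms: float = 20.0

    def __post_init__(self) -> None:
        hop_s = self.shift_frac / self.freq_res_hz
        if not np.isclose(hop_s, self.bin_ms / 1000.0):
            raise ValidationError(
                f"PowerSpec: hop (1/freq_res)*shift_frac = {hop_s*1000:.3f} ms "
                f"must equal bin_ms = {self.bin_ms} ms"
            )


def compute_lfp_power(lfp: BroadbandRecording, spec: PowerSpec) -> BinnedFeatures:
    """Band power per channel per 20 ms bin from a rectangular-window STFT.

    Window length is ``fs / freq_res_hz`` samples; each hop advances one
    output bin; power is the sum of squared STFT magnitudes whose center
    frequency lies in ``[band.lo, band.hi)``. The first full window defines
    the output time origin.
    """
    fs = lfp.fs_hz
    if spec.band.hi_hz > fs / 2:
        raise ValidationError(f"compute_lfp_power: band.hi {spec.band.hi_hz} above Nyquist {fs/2}")
    win = int(round(fs / spec.freq_res_hz))
    hop = int(round(spec.shift_frac * win))
    n = lfp.n_samples
    if n < win:
        raise ValidationError(f"compute_lfp_power: signal ({n} samples) shorter than one window ({win})")
    n_frames = (n - win) // hop + 1
    freqs = np.fft.rfftfreq(win, d=1 / fs)
    sel = (freqs >= spec.band.lo_hz) & (freqs < spec.band.hi_hz)
    out = np.empty((lfp.n_channels, n_frames))
    starts = hop * np.arange(n_frames)
    frames_idx = starts[:, None] + np.arange(win)[None, :]
    for c in range(lfp.n_channels):
        frames = lfp.samples[c, frames_idx]
        spec_mag = np.abs(np.fft.rfft(frames, axis=-1))
        out[c] = np.sum(spec_mag[:, sel] ** 2, axis=-1)
    t0_ms = (win / fs) * 1000.0 - spec.bin_ms  # bin k ends where window k ends
    return BinnedFeatures(
        values=out,
        bin_ms=spec.bin_ms,
        t0_ms=t0_ms,
        kind="lfp_power",
        band=spec.band,
        channel_ids=list(lfp.channel_ids),
    )


# ---------------------------------------------------------------------------
# channel quality control
# ---------------------------------------------------------------------------


@dataclass
class ChannelQCReport:
    """Per-channel mean band power with disconnect/over-activity flags."""

    mean_power: np.ndarray
    flags: list[str]  # per channel: keep | disconnected | overactive
    median_of_means: float
    q99_of_means: float

    def keep_mask(self) -> np.ndarray:
        return np.array([f == "keep" for f in self.flags])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean_power": self.mean_power, "flag": self.flags})


def channel_qc(power: BinnedFeatures) -> ChannelQCReport:
    """Flag disconnected (< 50% of median mean power) and overly active
    (>= 2x the 99th quantile of per-channel means) channels."""
    if power.kind != "lfp_power":
        raise ValidationError("channel_qc: expects kind='lfp_power'")
    if power.flags.log_transformed or power.flags.zscored:
        raise ValidationError("channel_qc: expects un-normalized power")
    if power.n_channels < 2:
        raise ValidationError("channel_qc: needs at least 2 channels")
    means = power.values.mean(axis=1)
    med = float(np.median(means))
    q99 = float(np.quantile(means, 0.99))
    flags = []
    for m in means:
        if m < 0.5 * med:
            flags.append("disconnected")
        elif m >= 2.0 * q99:
            flags.append("overactive")
        else:
            flags.append("keep")
    return ChannelQCReport(mean_power=means, flags=flags, median_of_means=med, q99_of_means=q99)


# ---------------------------------------------------------------------------
# log + causal z-score
# ---------------------------------------------------------------------------


def log_and_causal_zscore(
    power: BinnedFeatures, window_min: float = 3.0, eps: float = EPS, min_bins: int = 10
) -> BinnedFeatures:
    """log-transform, then z-score each bin against a trailing rolling window.

    At bin t the mean and standard deviation are computed over bins in
    ``(t - window, t]`` only — never over the future. Before ``min_bins`` of
    history have accumulated the output is 0.
    """
    if power.kind != "lfp_power":
        raise ValidationError("log_and_causal_zscore: expects kind='lfp_power'")
    x = np.log(np.maximum(power.values, eps))
    n = x.shape[1]
    w = int(round(window_min * 60.0 * 1000.0 / power.bin_ms))
    # trailing-window mean/var via cumulative sums; window (t-w, t] inclusive of t
    c1 = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((x.shape[0], 1)), np.cumsum(x**2, axis=1)], axis=1)
    t = np.arange(n)
    lo = np.maximum(t + 1 - w, 0)
    cnt = (t + 1 - lo).astype(float)
    s1 = c1[:, t + 1] - c1[:, lo]
    s2 = c2[:, t + 1] - c2[:, lo]
    mean = s1 / cnt
    var = np.maximum(s2 / cnt - mean**2, 0.0)
    sd = np.sqrt(var)
    z = (x - mean) / np.maximum(sd, eps)
    z[:, : max(min_bins - 1, 0)] = 0.0  # fewer than min_bins of history -> 0
    flags = FeatureFlags(
        log_transformed=True,
        zscored=True,
        smoothed_sd_ms=power.flags.smoothed_sd_ms,
        quantized_bits=power.flags.quantized_bits,
    )
    return power.copy_with(values=z, flags=flags)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------


def quantize(power: BinnedFeatures, bits: int) -> BinnedFeatures:
    """Per-channel min-max scale to [0, 2^b) and floor to integers.

    ``q = floor((x - min)/(max - min) * 2^b)`` clamped to ``2^b - 1``;
    constant channels map to 0. Mimics compressed transmission of LFP power
    from a wireless recording front end.
    """
    if not np.all(np.isfinite(power.values)):
        raise ValidationError("quantize: non-finite input")
    x = power.values
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    levels = float(2**bits)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.floor((x - lo) / span * levels)
    q = np.where(span > 0, q, 0.0)
    q = np.clip(q, 0, levels - 1)
    flags = FeatureFlags(
        log_transformed=power.flags.log_transformed,
        zscored=power.flags.zscored,
        smoothed_sd_ms=power.flags.smoothed_sd_ms,
        quantized_bits=bits,
    )
    return power.copy_with(values=q, flags=flags)


def dequantize_scale(power: BinnedFeatures, quantized: BinnedFeatures) -> BinnedFeatures:
    """Map quantized levels back onto each channel's original [min, max] range."""
    bits = quantized.flags.quantized_bits
    if bits is None:
        raise ValidationError("dequantize_scale: input is not quantized")
    lo = power.values.min(axis=1, keepdims=True)
    hi = power.values.max(axis=1, keepdims=True)
    x = quantized.values / float(2**bits) * (hi - lo) + lo
    flags = FeatureFlags(
        log_transformed=power.flags.log_transformed,
        zscored=power.flags.zscored,
        smoothed_sd_ms=power.flags.smoothed_sd_ms,
        quantized_bits=None,
    )
    return quantized.copy_with(values=x, flags=flags)


# ---------------------------------------------------------------------------
# band-limited downsampling
# ---------------------------------------------------------------------------


def downsample_for_band(lfp: BroadbandRecording, band: FrequencyBand) -> BroadbandRecording:
    """Resample to the Nyquist rate of the band's upper edge (min 50 Hz).

    Target sampling rate is ``2 * band.hi_hz``, except never below 50 Hz (the
    lowest rate that still supports 20 ms feature bins).
    """
    if band.hi_hz > lfp.fs_hz / 2:
        raise ValidationError(
            f"downsample_for_band: band.hi {band.hi_hz} above input Nyquist {lfp.fs_hz/2}"
        )
    fs_out = max(2.0 * band.hi_hz, 50.0)
    x = _resample_to(lfp.samples, lfp.fs_hz, fs_out)
    return BroadbandRecording(samples=x, fs_hz=fs_out, channel_ids=list(lfp.channel_ids))


# ---------------------------------------------------------------------------
# spike cleaning and binning
# ---------------------------------------------------------------------------


def clean_and_bin_spikes(
    raster: BinnedFeatures,
    coincident_frac: float = 0.30,
    corr_thresh: float = 0.2,
    bin_ms: float = 20.0,
) -> tuple[BinnedFeatures, list[int]]:
    """Remove coincident artifacts and correlated channels, then bin to 20 ms.

    1. Any 1 ms step on which strictly more than ``coincident_frac`` of the
       channels spiked is zeroed across all channels.
    2. Channels are removed greedily — at each pass the channel in the most
       above-threshold Pearson pairs (ties broken toward the lower index) is
       dropped and correlations recomputed — until no pair exceeds
       ``corr_thresh`` on the 1 ms raster.
    3. Surviving counts are summed into half-open ``bin_ms`` bins.

    Returns the binned features and the indices (in the original ordering) of
    the removed channels.
    """
    if raster.kind != "spike_counts":
        raise ValidationError("clean_and_bin_spikes: expects kind='spike_counts'")
    x = raster.values.astype(np.int64).copy()
    n_ch = x.shape[0]
    spiking = (x > 0).sum(axis=0)
    bad = spiking / n_ch > coincident_frac
    x[:, bad] = 0

    alive = list(range(n_ch))
    removed: list[int] = []
    while len(alive) > 1:
        sub = x[alive].astype(float)
        sd = sub.std(axis=1)
        # zero-variance channels cannot correlate; keep them out of the matrix
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 0.0)
        over = np.abs(corr) > corr_thresh
        counts = over.sum(axis=1)
        if counts.max() == 0:
            break
        worst = int(np.argmax(counts))  # argmax ties -> lowest index
        removed.append(alive.pop(worst))
    if not alive:
        raise ValidationError("clean_and_bin_spikes: all channels removed")

    kept = x[alive]
    steps_per_bin = int(round(bin_ms / raster.bin_ms))
    n_bins = kept.shape[1] // steps_per_bin
    binned = kept[:, : n_bins * steps_per_bin].reshape(len(alive), n_bins, steps_per_bin).sum(axis=2)
    ch_ids = None
    if raster.channel_ids is not None:
        ch_ids = [raster.channel_ids[i] for i in alive]
    out = BinnedFeatures(
        values=binned,
        bin_ms=bin_ms,
        t0_ms=raster.t0_ms,
        kind="spike_counts",
        channel_ids=ch_ids,
    )
    return out, sorted(removed)


# ---------------------------------------------------------------------------
# Gaussian smoothing
# ---------------------------------------------------------------------------


def gaussian_smooth(x: BinnedFeatures, sd_ms: float = 30.0, causal: bool = False) -> BinnedFeatures:
    """Gaussian-kernel smoothing along time (kernel truncated at ±4 SD).

    The kernel is renormalized at the edges so constant inputs are preserved
    exactly. The default is the symmetric (acausal) kernel used for offline
    analysis; ``causal=True`` uses the half-kernel over past bins only.
    """
    if sd_ms <= 0:
        raise ValidationError(f"gaussian_smooth: sd_ms must be > 0, got {sd_ms}")
    sd_bins = sd_ms / x.bin_ms
    half = int(np.ceil(4 * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    if causal:
        k[: half] = 0.0
    k = k / k.sum()
    v = x.values.astype(float)
    # convolve-'same' index m maps to lag j = m - half, so k as laid out
    # weights x[t - j]: symmetric when untruncated, past-only when causal
    num = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, v)
    den = np.convolve(np.ones(v.shape[1]), k, mode="same")
    out = num / den
    flags = FeatureFlags(
        log_transformed=x.flags.log_transformed,
        zscored=x.flags.zscored,
        smoothed_sd_ms=sd_ms,
        quantized_bits=x.flags.quantized_bits,
    )
    kind = "rates" if x.kind == "spike_counts" else x.kind
    if kind == "rates":
        out = np.maximum(out, EPS)  # rates are strictly positive
    return BinnedFeatures(
        values=out,
        bin_ms=x.bin_ms,
        t0_ms=x.t0_ms,
        kind=kind,
        band=x.band,
        flags=flags,
        channel_ids=x.channel_ids,
    )
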