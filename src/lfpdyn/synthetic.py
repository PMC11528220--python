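"""Synthetic sessions with the statistical structure the method assumes.

The generator emulates an eight-target center-out reaching session recorded
with an intracortical array: a low-dimensional latent state drives both
Poisson spiking (through an exponential readout) and LFP band power (through
a softplus readout with multiplicative lognormal noise and slow drift), and
is read out linearly into 2-D cursor velocity with bell-shaped speed
profiles. Spikes are generated on a 1 ms raster so that the coincident-spike
and correlated-channel quality-control rules downstream have real work to do:
a configurable fraction of raster steps carries a coincident artifact, and
one channel is a perfect duplicate of another.

Latent dynamics are rotational-linear: two 2-D planes rotating with distinct
periods, excited at movement onset by a condition-dependent state on a circle
of target angles and gated by a smooth onset/offset envelope. A Lorenz system
is available for nonlinearity stress tests.

Everything is a pure function of the configuration (including the seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .session import (
    BinnedFeatures,
    BroadbandRecording,
    FrequencyBand,
    SessionBundle,
    ValidationError,
    make_trial_table,
)


@dataclass
class GeneratorConfig:
    n_channels_spk: int = 40
    n_channels_lfp: int = 16
    latent_dim: int = 4
    dynamics: str = "rotational-linear"  # or "lorenz"
    n_trials: int = 300
    n_conditions: int = 8
    bin_ms: float = 20.0
    raster_dt_ms: float = 1.0
    base_rate_hz: float = 10.0
    tuning_depth: float = 1.5  # log-rate modulation amplitude at |z| = 1
    coupling_snr: float = 4.0  # latent-driven vs noise variance in LFP power
    noise_latent_frac: float = 0.8  # noise budget entering at the latent level
    noise_tau_ms: float = 150.0  # correlation time of the latent-level LFP noise
    noise_shared_frac: float = 0.5  # of the channel-level noise, fraction shared
    lfp_plane2_gain: float = 0.35  # LFP expression of the second latent plane
    velocity_plane2_gain: float = 0.6  # contribution of plane 2 to velocity
    drift_amp: float = 0.2  # relative multiplicative slow drift
    drift_period_s: float = 360.0
    coincident_frac: float = 0.002  # fraction of 1 ms steps carrying an artifact
    duplicate_channel: bool = True  # append a perfectly correlated channel
    hold_ms: float = 400.0
    reach_ms: float = 900.0
    iti_ms: float = 300.0
    peak_speed_cms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_channels_spk", "n_channels_lfp", "latent_dim", "n_trials", "n_conditions"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"GeneratorConfig.{name}: must be positive")
        if self.coupling_snr <= 0:
            raise ValidationError("GeneratorConfig.coupling_snr: must be > 0")
        if self.base_rate_hz * self.bin_ms <= 0:
            raise ValidationError("GeneratorConfig.base_rate_hz: must be > 0")
        if self.dynamics not in ("rotational-linear", "lorenz"):
            raise ValidationError(f"GeneratorConfig.dynamics: unknown {self.dynamics!r}")


@dataclass
class GroundTruth:
    """Latents, rates and onsets underlying a generated session."""

    latents: np.ndarray  # latent_dim x bins
    rates: np.ndarray  # channels x bins, spikes/bin (pre-QC channel set)
    true_onset_ms: np.ndarray  # per trial: 70%-of-peak crossing of clean speed
    duplicated_channel: Optional[int]  # index of the appended duplicate
    clean_speed: np.ndarray  # noiseless speed series, cm/s
    readout_velocity: np.ndarray  # W_v z (noiseless behavior)
    clean_lfp_power: np.ndarray  # softplus readout before noise/drift


def _onset_envelope(t_ms: np.ndarray, on_ms: float, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Smooth gate: sigmoid rise at on_ms, exponential decay, unit peak."""
    x = np.clip((t_ms - on_ms) / rise_ms, -20.0, 20.0)
    rise = 1.0 / (1.0 + np.exp(-4.0 * (x - 1.0)))
    env = rise * np.exp(-np.maximum(t_ms - on_ms, 0.0) / decay_ms)
    # normalize the peak on a dense grid so |z| reaches the intended amplitude
    tg = np.arange(on_ms, on_ms + 1500.0, 1.0)
    xg = np.clip((tg - on_ms) / rise_ms, -20.0, 20.0)
    peak = np.max(1.0 / (1.0 + np.exp(-4.0 * (xg - 1.0))) * np.exp(-(tg - on_ms) / decay_ms))
    return env / peak


def _rotational_latents(cfg: GeneratorConfig, rng, n_bins, trial_starts_ms, conditions):
    """Two rotation planes excited per trial; returns latent_dim x bins."""
    d = cfg.latent_dim
    z = np.zeros((d, n_bins))
    t_ms = cfg.bin_ms * np.arange(n_bins)
    # rotation periods in the 150-400 ms range stated for desk-scale dynamics
    periods_ms = np.linspace(400.0, 150.0, max(d // 2, 1))
    for k, (t_start, cond) in enumerate(zip(trial_starts_ms, conditions)):
        on = t_start + cfg.hold_ms
        env = _onset_envelope(t_ms, on, rise_ms=120.0, decay_ms=320.0)
        theta = 2 * np.pi * cond / cfg.n_conditions
        for p in range(max(d // 2, 1)):
            if 2 * p + 1 >= d:
                break
            w = 2 * np.pi / periods_ms[p]
            phase = w * (t_ms - on) + (p + 1) * theta
            amp = env * (1.0 if p == 0 else 0.6)
            z[2 * p] += amp * np.cos(phase)
            z[2 * p + 1] += amp * np.sin(phase)
    z += 0.02 * rng.standard_normal(z.shape)  # small state noise
    return z


def _lorenz_latents(cfg: GeneratorConfig, rng, n_bins, trial_starts_ms, conditions):
    """Standard Lorenz system integrated at the bin step, standardized."""
    d = cfg.latent_dim
    state = np.array([1.0, 1.0, 25.0])
    dt = 0.01
    out = np.zeros((3, n_bins))
    for i in range(n_bins):
        x, y, zz = state
        state = state + dt * np.array([10.0 * (y - x), x * (28.0 - zz) - y, x * y - 8.0 / 3.0 * zz])
        out[:, i] = state
    out = (out - out.mean(axis=1, keepdims=True)) / out.std(axis=1, keepdims=True)
    z = np.zeros((d, n_bins))
    z[: min(3, d)] = out[: min(3, d)]
    return z


def generate_session(cfg: GeneratorConfig) -> tuple[SessionBundle, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Returns (bundle, truth). The bundle carries 1 ms spike-count rasters
    (pre-QC, including artifacts and the duplicated channel), 20 ms LFP band
    power, 2-D cursor velocity and a trial table; the truth carries latents,
    noiseless rates, and the movement-onset times implied by the clean speed
    profiles.
    """
    rng = np.random.default_rng(cfg.seed)
    trial_len = cfg.hold_ms + cfg.reach_ms
    trial_starts = cfg.iti_ms + np.arange(cfg.n_trials) * (trial_len + cfg.iti_ms)
    session_ms = trial_starts[-1] + trial_len + cfg.iti_ms
    n_bins = int(np.floor(session_ms / cfg.bin_ms))
    t_ms = cfg.bin_ms * np.arange(n_bins)
    conditions = np.arange(cfg.n_trials) % cfg.n_conditions
    rng.shuffle(conditions)

    if cfg.dynamics == "rotational-linear":
        z = _rotational_latents(cfg, rng, n_bins, trial_starts, conditions)
    else:
        z = _lorenz_latents(cfg, rng, n_bins, trial_starts, conditions)

    # --- rates: r = exp(W_r z + b_r), scaled to the target mean rate -------
    # channels tuned to random latent directions; modulation depth matches
    # motor-cortical reach data (rates swinging several-fold around baseline)
    n_spk = cfg.n_channels_spk
    w_r = rng.standard_normal((n_spk, cfg.latent_dim))
    w_r = w_r / np.linalg.norm(w_r, axis=1, keepdims=True) * cfg.tuning_depth
    b0 = np.log(cfg.base_rate_hz * cfg.bin_ms / 1000.0)
    log_r = w_r @ z + b0
    # per-channel offset so each channel's mean rate is base_rate (E[e^x] correction)
    per_bin_target = cfg.base_rate_hz * cfg.bin_ms / 1000.0
    log_r += np.log(per_bin_target) - np.log(np.exp(log_r).mean(axis=1, keepdims=True))
    rates = np.exp(log_r)  # spikes per 20 ms bin

    # --- spikes on the 1 ms raster ----------------------------------------
    steps_per_bin = int(round(cfg.bin_ms / cfg.raster_dt_ms))
    n_steps = n_bins * steps_per_bin
    lam_step = np.repeat(rates / steps_per_bin, steps_per_bin, axis=1)
    raster = rng.poisson(lam_step)

    # coincident artifacts: spike on ~half the channels at selected steps
    n_art = int(round(cfg.coincident_frac * n_steps))
    artifact_steps = rng.choice(n_steps, size=n_art, replace=False) if n_art else np.array([], int)
    for s in artifact_steps:
        hit = rng.random(n_spk) < 0.5
        raster[hit, s] += 1

    dup_idx = None
    if cfg.duplicate_channel:
        raster = np.vstack([raster, raster[0:1]])
        dup_idx = raster.shape[0] - 1

    spikes_1ms = BinnedFeatures(
        values=raster,
        bin_ms=cfg.raster_dt_ms,
        t0_ms=0.0,
        kind="spike_counts",
        channel_ids=[f"spk{i}" for i in range(raster.shape[0])],
    )

    # --- LFP band power at the 20 ms feature level ------------------------
    n_lfp = cfg.n_channels_lfp
    # band power is rectified energy: offsets near zero leave many channels
    # pinned at their floor during quiescence and driven only by activity.
    # LFP is an aggregate signal and expresses only part of the population
    # state: the second latent plane appears with reduced gain, while spiking
    # (above) expresses all latent dimensions fully.
    w_p = rng.standard_normal((n_lfp, cfg.latent_dim)) * 0.7
    b_p = rng.uniform(-0.5, 1.0, size=(n_lfp, 1))
    gain = np.ones((cfg.latent_dim, 1))
    if cfg.latent_dim > 2:
        gain[2:] = cfg.lfp_plane2_gain
    z_lfp = gain * z  # the latent state as expressed in the LFP
    clean = np.log1p(np.exp(w_p @ z_lfp + b_p))  # softplus of the noiseless latents
    # the LFP sees the latents through a noisy field: global fluctuations
    # (movement artifacts, common-mode potentials) that do not drive spiking
    # enter at the latent level with AR(1) temporal correlation, so neither
    # channel averaging nor smoothing can reject them; the remainder of the
    # 1/coupling_snr noise budget is channel-level multiplicative lognormal
    # noise, partly shared across the array (volume conduction)
    if np.isfinite(cfg.coupling_snr):
        rho = np.exp(-cfg.bin_ms / cfg.noise_tau_ms)
        eta = np.empty_like(z)
        innov = rng.standard_normal(z.shape)
        eta[:, 0] = innov[:, 0]
        for t in range(1, z.shape[1]):
            eta[:, t] = rho * eta[:, t - 1] + np.sqrt(1 - rho**2) * innov[:, t]
        # a common noise floor referenced to the dominant plane: weakly
        # expressed latent dimensions therefore have low SNR in the LFP
        floor_sd = z[: min(2, z.shape[0])].std(axis=1).mean()
        eta *= floor_sd * np.sqrt(cfg.noise_latent_frac / cfg.coupling_snr)
        noisy = np.log1p(np.exp(w_p @ (z_lfp + eta) + b_p))
        var_s = clean.var(axis=1, keepdims=True)
        mean_s2 = (clean**2).mean(axis=1, keepdims=True)
        sigma2 = np.log1p(var_s * (1 - cfg.noise_latent_frac) / (mean_s2 * cfg.coupling_snr))
        sigma = np.sqrt(sigma2)
        f = cfg.noise_shared_frac
        eps = np.sqrt(f) * rng.standard_normal((1, clean.shape[1])) + np.sqrt(1 - f) * rng.standard_normal(clean.shape)
        mult = np.exp(sigma * eps - sigma2 / 2)
    else:
        noisy = clean
        mult = 1.0
    drift = 1.0 + cfg.drift_amp * np.sin(2 * np.pi * t_ms / 1000.0 / cfg.drift_period_s)
    power = noisy * drift * mult
    lfp_power = BinnedFeatures(
        values=power,
        bin_ms=cfg.bin_ms,
        t0_ms=0.0,
        kind="lfp_power",
        band=FrequencyBand(150.0, 450.0),
        channel_ids=[f"lfp{i}" for i in range(n_lfp)],
    )

    # --- behavior: velocity = W_v z + noise -------------------------------
    w_v = np.zeros((2, cfg.latent_dim))
    w_v[0, 0] = cfg.peak_speed_cms
    w_v[1, 1] = cfg.peak_speed_cms
    if cfg.latent_dim >= 4:
        w_v[0, 2] = cfg.velocity_plane2_gain * cfg.peak_speed_cms
        w_v[1, 3] = cfg.velocity_plane2_gain * cfg.peak_speed_cms
    v_clean = w_v @ z
    velocity = v_clean + 0.3 * rng.standard_normal(v_clean.shape)
    clean_speed = np.linalg.norm(v_clean, axis=0)

    # --- trial table and true onsets --------------------------------------
    trial_stops = trial_starts + trial_len
    trials = make_trial_table(
        start_ms=trial_starts,
        stop_ms=trial_stops,
        condition_label=conditions,
        go_cue_ms=trial_starts + cfg.hold_ms,
    )
    true_onsets = np.full(cfg.n_trials, np.nan)
    search_skip = 250.0
    for k in range(cfg.n_trials):
        i0 = int(np.floor((trial_starts[k] + search_skip) / cfg.bin_ms))
        i1 = int(np.floor(trial_stops[k] / cfg.bin_ms))
        seg = clean_speed[i0:i1]
        if seg.size == 0:
            continue
        thr = 0.7 * seg.max()
        above = np.nonzero(seg >= thr)[0]
        if above.size:
            true_onsets[k] = (i0 + above[0]) * cfg.bin_ms

    bundle = SessionBundle(
        features={"spikes_1ms": spikes_1ms, "lfp_power": lfp_power},
        behavior=velocity.T,
        behavior_bin_ms=cfg.bin_ms,
        behavior_t0_ms=0.0,
        trials=trials,
        meta={"generator_seed": cfg.seed, "generator": "lfpdyn.synthetic", "dynamics": cfg.dynamics},
    )
    bundle.validate()
    truth = GroundTruth(
        latents=z,
        rates=rates,
        true_onset_ms=true_onsets,
        duplicated_channel=dup_idx,
        clean_speed=clean_speed,
        readout_velocity=v_clean,
        clean_lfp_power=clean,
    )
    return bundle, truth


def generate_broadband_tone(
    freqs_hz,
    amps,
    fs_hz: float = 2000.0,
    duration_s: float = 10.0,
    noise_sd: float = 0.0,
    n_channels: int = 1,
    seed: int = 0,
) -> BroadbandRecording:
    """Sinusoid-mixture fixture for exercising the STFT/filtering path."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(fs_hz * duration_s))) / fs_hz
    sig = np.zeros_like(t)
    for f, a in zip(np.atleast_1d(freqs_hz), np.atleast_1d(amps)):
        sig = sig + a * np.sin(2 * np.pi * f * t)
    samples = np.tile(sig, (n_channels, 1))
    if noise_sd > 0:
        samples = samples + noise_sd * rng.standard_normal(samples.shape)
    return BroadbandRecording(
        samples=samples, fs_hz=fs_hz, channel_ids=[f"ch{i}" for i in range(n_channels)]
    )
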