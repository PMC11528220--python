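"""Closed-form front-end power model for a wireless iBCI recording device.

Amplifier power per channel follows the noise-efficiency-factor (NEF)
relation

    P_amp = V_source * (NEF / V_RMS)^2 * (pi * U_T * 4 k T * BW) / 2

and ADC power per channel follows the Schreier figure of merit

    P_ADC = BW / 10^((FoM_s - SNDR) / 10)

with BW the amplifier signal bandwidth (band width, hi - lo) and the ADC
sampling bandwidth (half the sampling rate) respectively. Feature extraction
is treated as free — it is orders of magnitude below the analog front end —
and wireless transmission power is matched across scenarios via the
transmission rate, so scenario comparisons isolate the analog front end.

Default scenario set: high-bandwidth spikes (5–10000 Hz), low-bandwidth
spikes (500–3000 Hz), raw LFP (0–1000 Hz at 2 kHz), spike-band power
(300–1000 Hz at 2 kHz), and the LFP power bands 150–450, 100–200, 50–100,
25–50 and 0–25 Hz sampled at the Nyquist rate of their upper edge (minimum
50 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import FrequencyBand, ValidationError


@dataclass(frozen=True)
class AmplifierSpec:
    """Electrical parameters of the analog amplifier (per channel)."""

    bandwidth_hz: float
    v_source: float = 3.3  # V
    nef: float = 4.0
    v_rms: float = 2e-6  # input-referred noise, V
    u_t: float = 0.0267  # thermal voltage, V
    temperature: float = 310.0  # K
    k_boltzmann: float = 1.38e-23  # J/K

    def __post_init__(self) -> None:
        for name in ("v_source", "nef", "v_rms", "u_t", "temperature", "k_boltzmann"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"AmplifierSpec.{name}: must be positive")
        if self.bandwidth_hz < 0:
            raise ValidationError("AmplifierSpec.bandwidth_hz: must be >= 0")


@dataclass(frozen=True)
class AdcSpec:
    """ADC parameters: Schreier figure of merit, SNDR, sampling bandwidth."""

    sampling_bandwidth_hz: float  # half the sampling rate
    fom_s_db: float = 185.0
    sndr_db: float = 96.0

    def __post_init__(self) -> None:
        if self.fom_s_db <= self.sndr_db:
            raise ValidationError("AdcSpec: fom_s_db must exceed sndr_db")
        if self.sampling_bandwidth_hz <= 0:
            raise ValidationError("AdcSpec.sampling_bandwidth_hz: must be > 0")


@dataclass(frozen=True)
class FrontEndConfig:
    """One acquisition scenario: a named amplifier + ADC pair."""

    label: str
    amplifier: AmplifierSpec
    adc: AdcSpec


def amplifier_power(spec: AmplifierSpec) -> float:
    """Per-channel amplifier power from the NEF formula, in mW."""
    watts = (
        spec.v_source
        * (spec.nef / spec.v_rms) ** 2
        * (np.pi * spec.u_t * 4.0 * spec.k_boltzmann * spec.temperature * spec.bandwidth_hz)
        / 2.0
    )
    return watts * 1e3


def adc_power(spec: AdcSpec) -> float:
    """Per-channel ADC power from the Schreier figure of merit, in mW."""
    watts = spec.sampling_bandwidth_hz / 10.0 ** ((spec.fom_s_db - spec.sndr_db) / 10.0)
    return watts * 1e3


def transmission_rate(n_channels: int, bits_per_sample: int, bin_s: float) -> float:
    """Wireless transmission rate in Kbps (1 Kbps = 1000 bps)."""
    if n_channels <= 0 or bits_per_sample <= 0 or bin_s <= 0:
        raise ValidationError("transmission_rate: all arguments must be positive")
    return n_channels * bits_per_sample / bin_s / 1000.0


def front_end_comparison(a: FrontEndConfig, b: FrontEndConfig) -> dict:
    """Per-channel front-end totals for two scenarios and the saving of a vs b.

    Returns totals in µW, the absolute saving ``total_b - total_a`` in µW,
    and the percent saving relative to b.
    """
    total_a = (amplifier_power(a.amplifier) + adc_power(a.adc)) * 1e3  # µW
    total_b = (amplifier_power(b.amplifier) + adc_power(b.adc)) * 1e3
    saving = total_b - total_a
    return {
        "label_a": a.label,
        "label_b": b.label,
        "total_uw_a": total_a,
        "total_uw_b": total_b,
        "saving_uw": saving,
        "saving_percent": saving / total_b * 100.0,
    }


# the nine scenarios compared in this work: (label, band, amplifier BW, ADC sampling BW)
DEFAULT_SCENARIOS: list[tuple[str, FrequencyBand, float, float]] = [
    ("high-bandwidth spikes", FrequencyBand(5, 10000), 9995.0, 10000.0),
    ("low-bandwidth spikes", FrequencyBand(500, 3000), 2500.0, 3000.0),
    ("raw LFP", FrequencyBand(0, 1000), 1000.0, 1000.0),  # acquired at 2 kHz
    ("SBP", FrequencyBand(300, 1000), 700.0, 1000.0),  # acquired at 2 kHz
    ("LFP 150-450", FrequencyBand(150, 450), 300.0, 450.0),
    ("LFP 100-200", FrequencyBand(100, 200), 100.0, 200.0),
    ("LFP 50-100", FrequencyBand(50, 100), 50.0, 100.0),
    ("LFP 25-50", FrequencyBand(25, 50), 25.0, 50.0),
    ("LFP 0-25", FrequencyBand(0, 25), 25.0, 25.0),  # sampled at 50 Hz
]


def make_front_end(label: str) -> FrontEndConfig:
    """Look up one of the default scenarios by label."""
    for lab, _, amp_bw, adc_bw in DEFAULT_SCENARIOS:
        if lab == label:
            return FrontEndConfig(
                label=lab,
                amplifier=AmplifierSpec(bandwidth_hz=amp_bw),
                adc=AdcSpec(sampling_bandwidth_hz=adc_bw),
            )
    raise ValidationError(f"make_front_end: unknown scenario {label!r}")


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(x, precision=sig, unique=False, fractional=False))


def scenario_table(scenarios=None) -> pd.DataFrame:
    """Amplifier and ADC power per channel for each scenario, in mW.

    Display columns are rounded to 2 significant figures; the ``*_exact``
    columns keep full precision. Feature-extraction power is treated as zero
    (negligible relative to the analog front end).
    """
    if scenarios is None:
        scenarios = DEFAULT_SCENARIOS
    rows = []
    for label, band, amp_bw, adc_bw in scenarios:
        p_amp = amplifier_power(AmplifierSpec(bandwidth_hz=amp_bw))
        p_adc = adc_power(AdcSpec(sampling_bandwidth_hz=adc_bw))
        rows.append(
            {
                "label": label,
                "band_lo_hz": band.lo_hz,
                "band_hi_hz": band.hi_hz,
                "amp_bw_hz": amp_bw,
                "adc_sampling_bw_hz": adc_bw,
                "amp_mw": _round_sig(p_amp),
                "adc_mw": _round_sig(p_adc),
                "amp_mw_exact": p_amp,
                "adc_mw_exact": p_adc,
            }
        )
    return pd.DataFrame(rows)
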