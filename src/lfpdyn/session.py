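"""Core domain types and the on-disk session container.

A recording session is the unit of analysis: broadband voltage and/or binned
features (LFP band power, spike counts, inferred firing rates), continuous
behavior on the same 20 ms clock, a trial table, and free-form provenance
metadata. Sessions round-trip through a single HDF5 file whose schema is
documented in ``docs/methods.md``.

Binned data use a 0-based, half-open bin convention: bin ``k`` covers
``[t0_ms + k * bin_ms, t0_ms + (k + 1) * bin_ms)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

#: feature kinds a BinnedFeatures matrix may carry
FEATURE_KINDS = ("lfp_power", "spike_counts", "rates", "factors")

TRIAL_COLUMNS = [
    "trial_id",
    "start_ms",
    "stop_ms",
    "go_cue_ms",
    "condition_label",
    "align_ms",
    "accepted",
]


class ValidationError(ValueError):
    """An invariant of a domain type was violated; the message names the field."""


class SchemaError(IOError):
    """A session file does not match the expected container schema/version."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency band ``[lo_hz, hi_hz)`` in Hz."""

    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ValidationError(
                f"FrequencyBand: need 0 <= lo_hz < hi_hz, got ({self.lo_hz}, {self.hi_hz})"
            )

    def bandwidth(self) -> float:
        return self.hi_hz - self.lo_hz


@dataclass
class BroadbandRecording:
    """Multichannel continuous voltage, channels x samples, in microvolts."""

    samples: np.ndarray
    fs_hz: float
    channel_ids: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValidationError("BroadbandRecording.samples: expected 2-D channels x time")
        if self.fs_hz <= 0:
            raise ValidationError(f"BroadbandRecording.fs_hz: must be > 0, got {self.fs_hz}")
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError(
                "BroadbandRecording.channel_ids: length "
                f"{len(self.channel_ids)} != channel count {self.samples.shape[0]}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("BroadbandRecording.samples: non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class FeatureFlags:
    """Provenance of the transforms applied to a BinnedFeatures matrix."""

    log_transformed: bool = False
    zscored: bool = False
    smoothed_sd_ms: Optional[float] = None
    quantized_bits: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "log_transformed": self.log_transformed,
                "zscored": self.zscored,
                "smoothed_sd_ms": self.smoothed_sd_ms,
                "quantized_bits": self.quantized_bits,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "FeatureFlags":
        d = json.loads(s)
        return cls(**d)


@dataclass
class BinnedFeatures:
    """Channels x bins matrix on a common bin clock.

    ``kind`` fixes the units: spike counts per bin, band power in µV², or
    inferred rates in spikes/bin. ``flags`` records every transform applied.
    """

    values: np.ndarray
    bin_ms: float
    t0_ms: float = 0.0
    kind: str = "lfp_power"
    band: Optional[FrequencyBand] = None
    flags: FeatureFlags = field(default_factory=FeatureFlags)
    channel_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("BinnedFeatures.values: expected 2-D channels x bins")
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"BinnedFeatures.kind: unknown kind {self.kind!r}")
        if self.bin_ms <= 0:
            raise ValidationError(f"BinnedFeatures.bin_ms: must be > 0, got {self.bin_ms}")
        if self.kind == "spike_counts":
            v = self.values
            if np.any(v < 0) or not np.allclose(v, np.round(v)):
                raise ValidationError("BinnedFeatures.values: spike_counts must be non-negative integers")
            self.values = np.asarray(np.round(v), dtype=np.int64)
        else:
            self.values = np.asarray(self.values, dtype=np.float64)
        if self.channel_ids is not None and len(self.channel_ids) != self.values.shape[0]:
            raise ValidationError("BinnedFeatures.channel_ids: length mismatch with values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_times_ms(self) -> np.ndarray:
        """Start time of each bin, ms."""
        return self.t0_ms + self.bin_ms * np.arange(self.n_bins)

    def time_to_bin(self, t_ms: float) -> int:
        """Index of the bin containing time ``t_ms`` (half-open convention)."""
        return int(np.floor((t_ms - self.t0_ms) / self.bin_ms))

    def copy_with(self, **kw) -> "BinnedFeatures":
        out = replace(self, **kw)
        return out


def make_trial_table(
    start_ms,
    stop_ms,
    condition_label,
    go_cue_ms=None,
    trial_id=None,
) -> pd.DataFrame:
    """Build a trial table with the canonical columns."""
    start_ms = np.asarray(start_ms, dtype=float)
    stop_ms = np.asarray(stop_ms, dtype=float)
    n = len(start_ms)
    if np.any(start_ms >= stop_ms):
        raise ValidationError("TrialTable: start_ms must be < stop_ms for every trial")
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n) if trial_id is None else np.asarray(trial_id),
            "start_ms": start_ms,
            "stop_ms": stop_ms,
            "go_cue_ms": np.full(n, np.nan) if go_cue_ms is None else np.asarray(go_cue_ms, dtype=float),
            "condition_label": np.asarray([str(c) for c in condition_label]),
            "align_ms": np.full(n, np.nan),
            "accepted": np.zeros(n, dtype=bool),
        }
    )
    return df


def validate_trials(trials: pd.DataFrame) -> None:
    for col in TRIAL_COLUMNS:
        if col not in trials.columns:
            raise ValidationError(f"TrialTable: missing column {col!r}")
    if np.any(trials["start_ms"].to_numpy() >= trials["stop_ms"].to_numpy()):
        raise ValidationError("TrialTable.start_ms: must be < stop_ms")
    al = trials["align_ms"].to_numpy(dtype=float)
    ok = np.isnan(al) | (
        (al >= trials["start_ms"].to_numpy()) & (al <= trials["stop_ms"].to_numpy())
    )
    if not np.all(ok):
        raise ValidationError("TrialTable.align_ms: must lie within [start_ms, stop_ms]")


@dataclass
class SessionBundle:
    """One recording session: signals, behavior, trials, provenance.

    All binned members (features, behavior) share ``bin_ms`` and a consistent
    time origin; the provenance map ``meta`` records the generator seed or the
    source file plus any stage configuration hashes.
    """

    features: dict[str, BinnedFeatures] = field(default_factory=dict)
    behavior: Optional[np.ndarray] = None  # time x dims, cursor velocity cm/s
    behavior_bin_ms: float = 20.0
    behavior_t0_ms: float = 0.0
    trials: Optional[pd.DataFrame] = None
    broadband: Optional[BroadbandRecording] = None
    lfp: Optional[BroadbandRecording] = None
    audio_envelope: Optional[np.ndarray] = None
    audio_fs_hz: float = 50.0
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        # features may live on different bin widths (e.g. a 1 ms raster next
        # to 20 ms power) but must share one clock: bin ratios integral and
        # origins offset by whole fine bins
        fine = None
        for name, f in self.features.items():
            if fine is None or f.bin_ms < fine.bin_ms:
                fine = f
        for name, f in self.features.items():
            ratio = f.bin_ms / fine.bin_ms
            off = (f.t0_ms - fine.t0_ms) / fine.bin_ms
            if not (np.isclose(ratio, round(ratio)) and np.isclose(off, round(off))):
                raise ValidationError(
                    f"SessionBundle.features[{name!r}]: bin clock ({f.bin_ms}, {f.t0_ms}) "
                    f"inconsistent with ({fine.bin_ms}, {fine.t0_ms})"
                )
        if self.behavior is not None:
            self.behavior = np.asarray(self.behavior, dtype=np.float64)
            if self.behavior.ndim != 2:
                raise ValidationError("SessionBundle.behavior: expected time x dims")
            if fine is not None:
                ratio = self.behavior_bin_ms / fine.bin_ms
                if not np.isclose(ratio, round(ratio)):
                    raise ValidationError("SessionBundle.behavior_bin_ms: inconsistent with features")
        if self.trials is not None:
            validate_trials(self.trials)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------


def _write_recording(g: h5py.Group, rec: BroadbandRecording) -> None:
    g.create_dataset("samples", data=rec.samples)
    g.attrs["fs_hz"] = rec.fs_hz
    g.create_dataset(
        "channel_ids", data=np.array([str(c) for c in rec.channel_ids], dtype="S64")
    )


def _read_recording(g: h5py.Group) -> BroadbandRecording:
    return BroadbandRecording(
        samples=g["samples"][()],
        fs_hz=float(g.attrs["fs_hz"]),
        channel_ids=[c.decode() for c in g["channel_ids"][()]],
    )


def write_session(bundle: SessionBundle, path) -> None:
    """Write a validated session bundle to one HDF5 file.

    Round-trips bit-exactly for integer data and to machine precision for
    floats (everything is stored as float64/int64).
    """
    bundle.validate()
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta"] = json.dumps(bundle.meta)
        if bundle.broadband is not None:
            _write_recording(f.create_group("broadband"), bundle.broadband)
        if bundle.lfp is not None:
            _write_recording(f.create_group("lfp"), bundle.lfp)
        feats = f.create_group("features")
        for name, feat in bundle.features.items():
            g = feats.create_group(name)
            g.create_dataset("values", data=feat.values)
            g.attrs["bin_ms"] = feat.bin_ms
            g.attrs["t0_ms"] = feat.t0_ms
            g.attrs["kind"] = feat.kind
            g.attrs["flags"] = feat.flags.to_json()
            if feat.band is not None:
                g.attrs["band_lo_hz"] = feat.band.lo_hz
                g.attrs["band_hi_hz"] = feat.band.hi_hz
            if feat.channel_ids is not None:
                g.create_dataset(
                    "channel_ids",
                    data=np.array([str(c) for c in feat.channel_ids], dtype="S64"),
                )
        if bundle.behavior is not None:
            g = f.create_group("behavior")
            g.create_dataset("values", data=bundle.behavior)
            g.attrs["bin_ms"] = bundle.behavior_bin_ms
            g.attrs["t0_ms"] = bundle.behavior_t0_ms
        if bundle.audio_envelope is not None:
            g = f.create_group("audio")
            g.create_dataset("envelope", data=np.asarray(bundle.audio_envelope, dtype=np.float64))
            g.attrs["fs_hz"] = bundle.audio_fs_hz
        if bundle.trials is not None:
            g = f.create_group("trials")
            for col in TRIAL_COLUMNS:
                v = bundle.trials[col].to_numpy()
                if col == "condition_label":
                    g.create_dataset(col, data=np.array([str(x) for x in v], dtype="S64"))
                elif col == "accepted":
                    g.create_dataset(col, data=v.astype(np.int8))
                else:
                    g.create_dataset(col, data=v.astype(np.float64))


def read_session(path) -> SessionBundle:
    """Read and validate a session bundle written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("schema_version") != SCHEMA_VERSION:
            raise SchemaError(
                f"session file {path}: schema_version "
                f"{f.attrs.get('schema_version')!r} != {SCHEMA_VERSION!r}"
            )
        if "features" not in f:
            raise SchemaError(f"session file {path}: missing required group /features")
        bundle = SessionBundle(meta=json.loads(f.attrs["meta"]))
        if "broadband" in f:
            bundle.broadband = _read_recording(f["broadband"])
        if "lfp" in f:
            bundle.lfp = _read_recording(f["lfp"])
        for name, g in f["features"].items():
            band = None
            if "band_lo_hz" in g.attrs:
                band = FrequencyBand(float(g.attrs["band_lo_hz"]), float(g.attrs["band_hi_hz"]))
            ch = None
            if "channel_ids" in g:
                ch = [c.decode() for c in g["channel_ids"][()]]
            bundle.features[name] = BinnedFeatures(
                values=g["values"][()],
                bin_ms=float(g.attrs["bin_ms"]),
                t0_ms=float(g.attrs["t0_ms"]),
                kind=str(g.attrs["kind"]),
                band=band,
                flags=FeatureFlags.from_json(g.attrs["flags"]),
                channel_ids=ch,
            )
        if "behavior" in f:
            g = f["behavior"]
            bundle.behavior = g["values"][()]
            bundle.behavior_bin_ms = float(g.attrs["bin_ms"])
            bundle.behavior_t0_ms = float(g.attrs["t0_ms"])
        if "audio" in f:
            bundle.audio_envelope = f["audio"]["envelope"][()]
            bundle.audio_fs_hz = float(f["audio"].attrs["fs_hz"])
        if "trials" in f:
            g = f["trials"]
            df = pd.DataFrame(
                {
                    "trial_id": g["trial_id"][()].astype(int),
                    "start_ms": g["start_ms"][()],
                    "stop_ms": g["stop_ms"][()],
                    "go_cue_ms": g["go_cue_ms"][()],
                    "condition_label": [c.decode() for c in g["condition_label"][()]],
                    "align_ms": g["align_ms"][()],
                    "accepted": g["accepted"][()].astype(bool),
                }
            )
            bundle.trials = df
    bundle.validate()
    return bundle
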