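"""Sequential variational autoencoder for latent neural dynamics.

The model is an LFADS-style encoder/controller/generator stack of gated
recurrent units. Its input is either binned spike counts or LFP band power;
its objective is always Poisson reconstruction of the spike counts, so an
LFP-power-driven model learns to estimate the firing rates underlying
simultaneously recorded spiking. After training, inference needs only the
low-power LFP signal.

Architecture (per 1000 ms / 50-bin window):

* a bidirectional GRU encoder reads the whole input window and parameterizes
  a Gaussian posterior over the generator initial condition;
* an optional controller GRU, conditioned on the encoder's per-step features
  and the previous factors, parameterizes a Gaussian posterior over a
  per-step inferred input u(t);
* the generator GRU evolves from the initial condition driven by u(t);
  factors are a linear readout of the generator state and per-channel rates
  are the exponential of a linear readout of the factors;
* loss = Poisson NLL + kl_ic * KL(q(x0)||N(0,I)) + kl_co * KL(q(u)||N(0,I)),
  with linear KL warm-up and L2 penalties on the recurrent weights.

Everything runs on a small reverse-mode autodiff tape over numpy arrays
(checked against finite differences in the test suite); a tape-free numpy
forward path is used for inference and is checked against the tape path.
Causal inference slides a trailing window over the stream and emits only the
final bin of each window, using posterior means, so output at bin t depends
only on bins <= t.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import gammaln

from .session import BinnedFeatures, ValidationError

# ---------------------------------------------------------------------------
# reverse-mode autodiff tape
# ---------------------------------------------------------------------------

_TAPE: Optional[list] = None


class Var:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("v", "g", "bk")

    def __init__(self, v, bk=None):
        self.v = np.asarray(v, dtype=np.float64)
        self.g = None
        self.bk = bk
        if _TAPE is not None and bk is not None:
            _TAPE.append(self)


@contextmanager
def tape():
    global _TAPE
    old = _TAPE
    _TAPE = []
    try:
        yield _TAPE
    finally:
        _TAPE = old


def backward(loss: "Var", tp: list) -> None:
    loss.g = np.ones_like(loss.v)
    for node in reversed(tp):
        if node.g is not None and node.bk is not None:
            node.bk(node.g)


def _val(x):
    return x.v if isinstance(x, Var) else np.asarray(x, dtype=np.float64)


def _acc(p, g):
    if isinstance(p, Var):
        p.g = g if p.g is None else p.g + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def vadd(a, b) -> Var:
    av, bv = _val(a), _val(b)
    out = Var(av + bv, bk=lambda g: (_acc(a, _unbroadcast(g, av.shape)), _acc(b, _unbroadcast(g, bv.shape))))
    return out


def vmul(a, b) -> Var:
    av, bv = _val(a), _val(b)
    return Var(
        av * bv,
        bk=lambda g: (_acc(a, _unbroadcast(g * bv, av.shape)), _acc(b, _unbroadcast(g * av, bv.shape))),
    )


def vscale(a, c: float) -> Var:
    av = _val(a)
    return Var(av * c, bk=lambda g: _acc(a, g * c))


def vmatmul(a, b) -> Var:
    av, bv = _val(a), _val(b)
    return Var(av @ bv, bk=lambda g: (_acc(a, g @ bv.T), _acc(b, av.T @ g)))


def vsigmoid(a) -> Var:
    s = 1.0 / (1.0 + np.exp(-_val(a)))
    return Var(s, bk=lambda g: _acc(a, g * s * (1 - s)))


def vtanh(a) -> Var:
    t = np.tanh(_val(a))
    return Var(t, bk=lambda g: _acc(a, g * (1 - t**2)))


def vexp(a) -> Var:
    e = np.exp(_val(a))
    return Var(e, bk=lambda g: _acc(a, g * e))


def vconcat(parts: list, axis: int = 1) -> Var:
    vals = [_val(p) for p in parts]
    sizes = [v.shape[axis] for v in vals]
    splits = np.cumsum(sizes)[:-1]

    def bk(g):
        for p, gs in zip(parts, np.split(g, splits, axis=axis)):
            _acc(p, gs)

    return Var(np.concatenate(vals, axis=axis), bk=bk)


def vslice_cols(a, lo: int, hi: int) -> Var:
    av = _val(a)

    def bk(g):
        full = np.zeros_like(av)
        full[:, lo:hi] = g
        _acc(a, full)

    return Var(av[:, lo:hi], bk=bk)


def vsum(a) -> Var:
    av = _val(a)
    return Var(av.sum(), bk=lambda g: _acc(a, np.broadcast_to(g, av.shape).copy()))


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    input_kind: str  # "lfp_power" | "spikes"
    n_in: int
    n_out: int
    encoder_dim: int = 64
    generator_dim: int = 64
    controller_dim: int = 64
    ic_dim: int = 32
    co_dim: int = 8  # 0 disables the controller
    factor_dim: int = 12
    kl_weight_ic: float = 1e-3
    kl_weight_co: float = 3e-3
    kl_warmup_steps: int = 100
    l2_gen: float = 1e-2
    l2_con: float = 1e-2
    dropout: float = 0.05
    learning_rate: float = 1e-2
    lr_decay: float = 0.996
    batch_size: int = 64
    max_epochs: int = 100
    val_frac: float = 0.2
    jitter_bins: int = 2  # spikes input only
    cell: str = "gru"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_kind not in ("lfp_power", "spikes"):
            raise ValidationError(f"ModelConfig.input_kind: unknown {self.input_kind!r}")
        for name in ("n_in", "n_out", "encoder_dim", "generator_dim", "ic_dim", "factor_dim"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ModelConfig.{name}: must be positive")
        if self.co_dim < 0:
            raise ValidationError("ModelConfig.co_dim: must be >= 0")
        if self.co_dim > 0 and self.controller_dim <= 0:
            raise ValidationError("ModelConfig.controller_dim: must be positive when co_dim > 0")
        if self.factor_dim > self.generator_dim:
            raise ValidationError("ModelConfig.factor_dim: must be <= generator_dim")
        if self.cell != "gru":
            raise ValidationError(f"ModelConfig.cell: only 'gru' is implemented, got {self.cell!r}")


@dataclass
class SegmentSet:
    """Overlapping fixed-length windows cut from a continuous session."""

    inputs: np.ndarray  # segments x bins x n_in
    targets: Optional[np.ndarray]  # segments x bins x n_out (spike counts)
    starts_ms: np.ndarray
    window_ms: float
    overlap_ms: float
    bin_ms: float
    t0_ms: float = 0.0

    @property
    def n_segments(self) -> int:
        return self.inputs.shape[0]

    @property
    def window_bins(self) -> int:
        return self.inputs.shape[1]


@dataclass
class PosteriorOutput:
    """Inference result on a bin clock: rates, factors, inferred inputs."""

    rates: np.ndarray  # channels x bins, spikes/bin, > 0
    factors: np.ndarray  # factor_dim x bins
    inferred_inputs: Optional[np.ndarray]  # co_dim x bins
    ic_mean: Optional[np.ndarray]
    ic_var: Optional[np.ndarray]
    bin_ms: float
    t0_ms: float

    def rates_features(self) -> BinnedFeatures:
        return BinnedFeatures(values=self.rates, bin_ms=self.bin_ms, t0_ms=self.t0_ms, kind="rates")


# ---------------------------------------------------------------------------
# segmentation, augmentation, Poisson NLL
# ---------------------------------------------------------------------------


def segment_continuous(
    x: BinnedFeatures,
    target: Optional[BinnedFeatures] = None,
    window_ms: float = 1000.0,
    overlap_ms: float = 200.0,
) -> SegmentSet:
    """Cut a session into overlapping windows (final partial window dropped).

    Starts at 0 and advances by ``window_ms - overlap_ms``; input and target
    are segmented identically on their shared bin clock.
    """
    if overlap_ms >= window_ms:
        raise ValidationError("segment_continuous: overlap must be < window")
    wb = int(round(window_ms / x.bin_ms))
    step = int(round((window_ms - overlap_ms) / x.bin_ms))
    n = x.n_bins
    if target is not None:
        if not np.isclose(target.bin_ms, x.bin_ms) or not np.isclose(target.t0_ms, x.t0_ms):
            raise ValidationError("segment_continuous: input/target bin clocks differ")
        n = min(n, target.n_bins)
    if n < wb:
        raise ValidationError(f"segment_continuous: session ({n} bins) shorter than window ({wb})")
    starts = np.arange(0, n - wb + 1, step)
    inputs = np.stack([x.values[:, s : s + wb].T for s in starts])
    targets = None
    if target is not None:
        targets = np.stack([target.values[:, s : s + wb].T for s in starts])
    return SegmentSet(
        inputs=inputs,
        targets=targets,
        starts_ms=x.t0_ms + starts * x.bin_ms,
        window_ms=window_ms,
        overlap_ms=overlap_ms,
        bin_ms=x.bin_ms,
        t0_ms=x.t0_ms,
    )


def jitter_spikes(batch: np.ndarray, jitter_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Displace each spike by an independent uniform offset in [-j, +j] bins.

    Offsets are clipped at the window edges, so the total count per segment
    and channel is conserved. Applied to the model *input* only.
    """
    if jitter_bins == 0:
        return batch
    out = np.zeros_like(batch)
    S, T, C = batch.shape
    seg, t, ch = np.nonzero(batch)
    counts = batch[seg, t, ch].astype(int)
    seg = np.repeat(seg, counts)
    t = np.repeat(t, counts)
    ch = np.repeat(ch, counts)
    off = rng.integers(-jitter_bins, jitter_bins + 1, size=t.shape[0])
    t_new = np.clip(t + off, 0, T - 1)
    np.add.at(out, (seg, t_new, ch), 1)
    return out


def poisson_nll(rates: np.ndarray, counts: np.ndarray) -> float:
    """Exact Poisson negative log likelihood: sum of lam - s*log(lam) + log(s!)."""
    lam = np.asarray(rates, dtype=float)
    s = np.asarray(counts)
    if lam.shape != s.shape:
        raise ValidationError("poisson_nll: shapes must match")
    if np.any(lam <= 0):
        raise ValidationError("poisson_nll: rates must be strictly positive")
    if np.any(s < 0) or not np.allclose(s, np.round(s)):
        raise ValidationError("poisson_nll: counts must be non-negative integers")
    return float(np.sum(lam - s * np.log(lam) + gammaln(np.asarray(s, dtype=float) + 1)))


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


def _init_gru(rng, n_in, n_h, params, prefix):
    sc_x = 1.0 / np.sqrt(n_in)
    sc_h = 1.0 / np.sqrt(n_h)
    params[prefix + ".Wx"] = Var(rng.uniform(-sc_x, sc_x, (n_in, 3 * n_h)))
    params[prefix + ".Wh"] = Var(rng.uniform(-sc_h, sc_h, (n_h, 3 * n_h)))
    params[prefix + ".b"] = Var(np.zeros((1, 3 * n_h)))


def _init_linear(rng, n_in, n_out, params, prefix, bias=True):
    sc = 1.0 / np.sqrt(n_in)
    params[prefix + ".W"] = Var(rng.uniform(-sc, sc, (n_in, n_out)))
    if bias:
        params[prefix + ".b"] = Var(np.zeros((1, n_out)))


class DynamicsModel:
    """Encoder/controller/generator recurrent variational model."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        p: dict[str, Var] = {}
        _init_gru(rng, cfg.n_in, cfg.encoder_dim, p, "enc_f")
        _init_gru(rng, cfg.n_in, cfg.encoder_dim, p, "enc_b")
        _init_linear(rng, 2 * cfg.encoder_dim, 2 * cfg.ic_dim, p, "ic")
        _init_linear(rng, cfg.ic_dim, cfg.generator_dim, p, "ic2gen")
        if cfg.co_dim > 0:
            _init_gru(rng, 2 * cfg.encoder_dim + cfg.factor_dim, cfg.controller_dim, p, "con")
            _init_linear(rng, cfg.controller_dim, 2 * cfg.co_dim, p, "co")
        _init_gru(rng, max(cfg.co_dim, 1), cfg.generator_dim, p, "gen")
        _init_linear(rng, cfg.generator_dim, cfg.factor_dim, p, "fac", bias=False)
        _init_linear(rng, cfg.factor_dim, cfg.n_out, p, "rate")
        self.params = p
        self.train_log: dict = {}

    # -- tape forward (training) -------------------------------------------

    def _gru_step(self, prefix, x, h):
        p = self.params
        nh = _val(h).shape[1]
        xg = vadd(vmatmul(x, p[prefix + ".Wx"]), p[prefix + ".b"])
        hg = vmatmul(h, p[prefix + ".Wh"])
        r = vsigmoid(vadd(vslice_cols(xg, 0, nh), vslice_cols(hg, 0, nh)))
        z = vsigmoid(vadd(vslice_cols(xg, nh, 2 * nh), vslice_cols(hg, nh, 2 * nh)))
        n = vtanh(vadd(vslice_cols(xg, 2 * nh, 3 * nh), vmul(r, vslice_cols(hg, 2 * nh, 3 * nh))))
        # h' = (1 - z) * n + z * h
        return vadd(vmul(vadd(vscale(z, -1.0), 1.0), n), vmul(z, h))

    def _linear(self, prefix, x):
        p = self.params
        out = vmatmul(x, p[prefix + ".W"])
        if prefix + ".b" in self.params:
            out = vadd(out, p[prefix + ".b"])
        return out

    def _forward_tape(self, x_np: np.ndarray, rng: Optional[np.random.Generator]):
        """Graph forward over a batch (B x T x n_in). rng=None -> posterior means.

        Returns (logrates per step list, kl_ic Var, kl_co Var).
        """
        cfg = self.cfg
        B, T, _ = x_np.shape
        h_f = Var(np.zeros((B, cfg.encoder_dim)))
        h_b = Var(np.zeros((B, cfg.encoder_dim)))
        fs, bs = [], []
        for t in range(T):
            h_f = self._gru_step("enc_f", x_np[:, t], h_f)
            fs.append(h_f)
        for t in range(T - 1, -1, -1):
            h_b = self._gru_step("enc_b", x_np[:, t], h_b)
            bs.append(h_b)
        bs = bs[::-1]  # bs[t] has context from t..T-1

        ic_stats = self._linear("ic", vconcat([fs[-1], bs[0]], axis=1))
        ic_mean = vslice_cols(ic_stats, 0, cfg.ic_dim)
        ic_logvar = vslice_cols(ic_stats, cfg.ic_dim, 2 * cfg.ic_dim)
        kl_ic = self._kl(ic_mean, ic_logvar)
        ic = self._sample(ic_mean, ic_logvar, rng)
        g = vtanh(self._linear("ic2gen", ic))

        f = Var(np.zeros((B, cfg.factor_dim)))
        c = Var(np.zeros((B, cfg.controller_dim))) if cfg.co_dim > 0 else None
        kl_co_terms = []
        logrates = []
        u_means = []
        for t in range(T):
            if cfg.co_dim > 0:
                c = self._gru_step("con", vconcat([fs[t], bs[t], f], axis=1), c)
                u_stats = self._linear("co", c)
                u_mean = vslice_cols(u_stats, 0, cfg.co_dim)
                u_logvar = vslice_cols(u_stats, cfg.co_dim, 2 * cfg.co_dim)
                kl_co_terms.append(self._kl(u_mean, u_logvar))
                u = self._sample(u_mean, u_logvar, rng)
                u_means.append(u_mean)
            else:
                u = Var(np.zeros((B, 1)))
            g = self._gru_step("gen", u, g)
            f = self._linear("fac", g)
            logrates.append(self._linear("rate", f))
        if kl_co_terms:
            kl_co = kl_co_terms[0]
            for k in kl_co_terms[1:]:
                kl_co = vadd(kl_co, k)
        else:
            kl_co = Var(0.0)
        return logrates, kl_ic, kl_co, u_means

    @staticmethod
    def _kl(mean: Var, logvar: Var) -> Var:
        # KL(N(mu, sigma^2) || N(0, I)) = 0.5 sum(mu^2 + sigma^2 - logvar - 1)
        term = vadd(vadd(vmul(mean, mean), vexp(logvar)), vscale(vadd(logvar, 1.0), -1.0))
        return vscale(vsum(term), 0.5)

    @staticmethod
    def _sample(mean: Var, logvar: Var, rng) -> Var:
        if rng is None:
            return mean
        eps = rng.standard_normal(mean.v.shape)
        return vadd(mean, vmul(vexp(vscale(logvar, 0.5)), eps))

    def loss_graph(self, x_np, s_np, rng, kl_scale: float = 1.0):
        """Training loss (per-element) on a batch; returns (loss, parts)."""
        cfg = self.cfg
        B, T, n_out = s_np.shape
        logrates, kl_ic, kl_co, _ = self._forward_tape(x_np, rng)
        nll_terms = []
        for t in range(T):
            lr = logrates[t]
            # lam - s*log(lam); log s! added outside the graph (constant)
            nll_terms.append(vadd(vsum(vexp(lr)), vscale(vsum(vmul(lr, s_np[:, t])), -1.0)))
        nll = nll_terms[0]
        for term in nll_terms[1:]:
            nll = vadd(nll, term)
        count = float(B * T * n_out)
        loss = vscale(nll, 1.0 / count)
        loss = vadd(loss, vscale(kl_ic, kl_scale * cfg.kl_weight_ic / count))
        loss = vadd(loss, vscale(kl_co, kl_scale * cfg.kl_weight_co / count))
        for prefix, lam in (("gen", cfg.l2_gen), ("con", cfg.l2_con)):
            key = prefix + ".Wh"
            if lam > 0 and key in self.params:
                w = self.params[key]
                loss = vadd(loss, vscale(vsum(vmul(w, w)), lam / w.v.size))
        parts = {"nll_sum": float(nll.v), "kl_ic": float(kl_ic.v), "kl_co": float(kl_co.v)}
        return loss, parts

    # -- numpy forward (inference) -----------------------------------------

    def _np_gru_step(self, prefix, x, h):
        p = self.params
        nh = h.shape[1]
        xg = x @ p[prefix + ".Wx"].v + p[prefix + ".b"].v
        hg = h @ p[prefix + ".Wh"].v
        r = 1 / (1 + np.exp(-(xg[:, :nh] + hg[:, :nh])))
        z = 1 / (1 + np.exp(-(xg[:, nh : 2 * nh] + hg[:, nh : 2 * nh])))
        n = np.tanh(xg[:, 2 * nh :] + r * hg[:, 2 * nh :])
        return (1 - z) * n + z * h

    def _np_linear(self, prefix, x):
        p = self.params
        out = x @ p[prefix + ".W"].v
        if prefix + ".b" in p:
            out = out + p[prefix + ".b"].v
        return out

    def forward_np(self, x_np: np.ndarray, rng: Optional[np.random.Generator] = None):
        """Tape-free forward over a batch; rng=None uses posterior means.

        Returns dict with rates (B,T,n_out), factors, u (co means or samples),
        ic_mean, ic_var.
        """
        cfg = self.cfg
        B, T, _ = x_np.shape
        h_f = np.zeros((B, cfg.encoder_dim))
        h_b = np.zeros((B, cfg.encoder_dim))
        fs = np.empty((T, B, cfg.encoder_dim))
        bs = np.empty((T, B, cfg.encoder_dim))
        for t in range(T):
            h_f = self._np_gru_step("enc_f", x_np[:, t], h_f)
            fs[t] = h_f
        for t in range(T - 1, -1, -1):
            h_b = self._np_gru_step("enc_b", x_np[:, t], h_b)
            bs[t] = h_b
        ic_stats = self._np_linear("ic", np.concatenate([fs[-1], bs[0]], axis=1))
        ic_mean = ic_stats[:, : cfg.ic_dim]
        ic_logvar = ic_stats[:, cfg.ic_dim :]
        ic = ic_mean if rng is None else ic_mean + np.exp(0.5 * ic_logvar) * rng.standard_normal(ic_mean.shape)
        g = np.tanh(self._np_linear("ic2gen", ic))
        f = np.zeros((B, cfg.factor_dim))
        c = np.zeros((B, cfg.controller_dim)) if cfg.co_dim > 0 else None
        rates = np.empty((B, T, cfg.n_out))
        factors = np.empty((B, T, cfg.factor_dim))
        us = np.zeros((B, T, max(cfg.co_dim, 1)))
        for t in range(T):
            if cfg.co_dim > 0:
                c = self._np_gru_step("con", np.concatenate([fs[t], bs[t], f], axis=1), c)
                u_stats = self._np_linear("co", c)
                u_mean = u_stats[:, : cfg.co_dim]
                u_logvar = u_stats[:, cfg.co_dim :]
                u = u_mean if rng is None else u_mean + np.exp(0.5 * u_logvar) * rng.standard_normal(u_mean.shape)
            else:
                u = np.zeros((B, 1))
            g = self._np_gru_step("gen", u, g)
            f = self._np_linear("fac", g)
            rates[:, t] = np.exp(self._np_linear("rate", f))
            factors[:, t] = f
            us[:, t] = u
        return {
            "rates": rates,
            "factors": factors,
            "u": us if cfg.co_dim > 0 else None,
            "ic_mean": ic_mean,
            "ic_var": np.exp(ic_logvar),
        }


def build_model(cfg: ModelConfig) -> DynamicsModel:
    """Construct and initialize the model for a validated configuration."""
    return DynamicsModel(cfg)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.params = params
        self.lr = lr
        self.m = {k: np.zeros_like(v.v) for k, v in params.items()}
        self.s = {k: np.zeros_like(v.v) for k, v in params.items()}
        self.t = 0

    def step(self, lr: float, clip: float = 10.0) -> None:
        self.t += 1
        norm = np.sqrt(sum(float((p.g**2).sum()) for p in self.params.values() if p.g is not None))
        scale = min(1.0, clip / (norm + 1e-12))
        for k, p in self.params.items():
            if p.g is None:
                continue
            g = p.g * scale
            self.m[k] = 0.9 * self.m[k] + 0.1 * g
            self.s[k] = 0.999 * self.s[k] + 0.001 * g**2
            mhat = self.m[k] / (1 - 0.9**self.t)
            shat = self.s[k] / (1 - 0.999**self.t)
            p.v -= lr * mhat / (np.sqrt(shat) + 1e-8)
            p.g = None


def train(model: DynamicsModel, segments: SegmentSet, verbose: bool = False) -> DynamicsModel:
    """Stochastic-gradient training with KL warm-up and a validation split.

    20% of segments (seeded shuffle) are held out; the model state with the
    best validation Poisson NLL (at posterior means) is restored at the end.
    When the input is spiking activity, each training step independently
    re-jitters the input spikes. Aborts on divergence (non-finite loss).
    """
    cfg = model.cfg
    if segments.targets is None:
        raise ValidationError("train: segments must carry spike-count targets")
    rng = np.random.default_rng(cfg.seed)
    n = segments.n_segments
    order = rng.permutation(n)
    n_val = max(int(round(cfg.val_frac * n)), 1)
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_all, s_all = segments.inputs, segments.targets
    opt = _Adam(model.params, cfg.learning_rate)
    curves = {"train_loss": [], "val_nll": []}
    best_val = np.inf
    best_params = None
    step = 0
    for epoch in range(cfg.max_epochs):
        rng.shuffle(train_idx)
        losses = []
        for lo in range(0, train_idx.size, cfg.batch_size):
            idx = train_idx[lo : lo + cfg.batch_size]
            xb = x_all[idx]
            sb = s_all[idx]
            if cfg.input_kind == "spikes" and cfg.jitter_bins > 0:
                xb = jitter_spikes(xb, cfg.jitter_bins, rng)
            if cfg.dropout > 0:
                xb = xb * (rng.random(xb.shape) >= cfg.dropout)
            kl_scale = min(1.0, (step + 1) / max(cfg.kl_warmup_steps, 1))
            with tape() as tp:
                loss, _ = model.loss_graph(xb, sb, rng, kl_scale)
                if not np.isfinite(loss.v):
                    raise RuntimeError(
                        f"train: non-finite loss at epoch {epoch}, step {step} - diverged"
                    )
                backward(loss, tp)
            opt.step(cfg.learning_rate * cfg.lr_decay**epoch)
            losses.append(float(loss.v))
            step += 1
        out = model.forward_np(x_all[val_idx])
        val_nll = poisson_nll(out["rates"], s_all[val_idx]) / s_all[val_idx].size
        curves["train_loss"].append(float(np.mean(losses)))
        curves["val_nll"].append(val_nll)
        if val_nll < best_val:
            best_val = val_nll
            best_params = {k: v.v.copy() for k, v in model.params.items()}
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch}: train {curves['train_loss'][-1]:.4f} val {val_nll:.4f}")
    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].v = v
    model.train_log = {"curves": curves, "best_val_nll": best_val, "n_train": train_idx.size, "n_val": n_val}
    return model


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: DynamicsModel, path) -> None:
    """Store config and weights in one .npz file."""
    import json
    from dataclasses import asdict

    arrays = {k.replace(".", "__"): p.v for k, p in model.params.items()}
    np.savez(path, __config__=json.dumps(asdict(model.cfg)), **arrays)


def load_checkpoint(path) -> DynamicsModel:
    import json

    data = np.load(path, allow_pickle=False)
    cfg = ModelConfig(**json.loads(str(data["__config__"])))
    model = DynamicsModel(cfg)
    for k in model.params:
        model.params[k].v = data[k.replace(".", "__")]
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def infer_causal(
    model: DynamicsModel,
    stream: BinnedFeatures,
    window_ms: float = 1000.0,
    chunk: int = 256,
) -> PosteriorOutput:
    """Sliding trailing-window inference: one new output bin per input bin.

    For each bin t >= window_bins - 1 the model runs on the window ending at
    t using posterior means (no sampling), and only the final bin's rates and
    factors are emitted; outputs at bin t therefore depend only on bins <= t.
    The first emitted bin has index window_bins - 1.
    """
    wb = int(round(window_ms / stream.bin_ms))
    n = stream.n_bins
    if n < wb:
        raise ValidationError(f"infer_causal: stream ({n} bins) shorter than one window ({wb})")
    x = stream.values.T  # bins x channels
    n_out = n - wb + 1
    rates = np.empty((model.cfg.n_out, n_out))
    factors = np.empty((model.cfg.factor_dim, n_out))
    us = np.empty((max(model.cfg.co_dim, 1), n_out))
    for lo in range(0, n_out, chunk):
        hi = min(lo + chunk, n_out)
        batch = np.stack([x[s : s + wb] for s in range(lo, hi)])
        out = model.forward_np(batch)
        rates[:, lo:hi] = out["rates"][:, -1].T
        factors[:, lo:hi] = out["factors"][:, -1].T
        us[:, lo:hi] = out["u"][:, -1].T if out["u"] is not None else 0.0
    return PosteriorOutput(
        rates=rates,
        factors=factors,
        inferred_inputs=us if model.cfg.co_dim > 0 else None,
        ic_mean=None,
        ic_var=None,
        bin_ms=stream.bin_ms,
        t0_ms=stream.t0_ms + (wb - 1) * stream.bin_ms,
    )


def infer_acausal(
    model: DynamicsModel,
    segments: SegmentSet,
    n_samples: int = 1,
    seed: int = 0,
) -> PosteriorOutput:
    """Full-window inference over a SegmentSet, merged back onto the session.

    ``n_samples=1`` uses posterior means; otherwise rates are averaged over
    posterior samples. Overlapping windows are merged by keeping, for each
    session bin, the value from the window in which the bin is deepest (most
    left-context), i.e. the earliest window covering it.
    """
    cfg = model.cfg
    wb = segments.window_bins
    step = int(round((segments.window_ms - segments.overlap_ms) / segments.bin_ms))
    if n_samples <= 1:
        outs = [model.forward_np(segments.inputs)]
    else:
        rng = np.random.default_rng(seed)
        outs = [model.forward_np(segments.inputs, rng) for _ in range(n_samples)]
    rates_seg = np.mean([o["rates"] for o in outs], axis=0)
    fac_seg = np.mean([o["factors"] for o in outs], axis=0)
    u_seg = np.mean([o["u"] for o in outs], axis=0) if outs[0]["u"] is not None else None
    starts = np.round((segments.starts_ms - segments.t0_ms) / segments.bin_ms).astype(int)
    n_bins = starts[-1] + wb
    rates = np.empty((cfg.n_out, n_bins))
    factors = np.empty((cfg.factor_dim, n_bins))
    us = np.empty((max(cfg.co_dim, 1), n_bins)) if u_seg is not None else None
    for b in range(n_bins):
        # earliest window covering bin b: start <= b < start + wb
        i = int(np.searchsorted(starts, b - wb, side="right"))
        i = min(i, len(starts) - 1)
        off = b - starts[i]
        if off < 0:  # only possible before the first window; cannot happen with start 0
            i, off = 0, b
        rates[:, b] = rates_seg[i, off]
        factors[:, b] = fac_seg[i, off]
        if us is not None:
            us[:, b] = u_seg[i, off]
    ic0 = outs[0]
    return PosteriorOutput(
        rates=rates,
        factors=factors,
        inferred_inputs=us,
        ic_mean=ic0["ic_mean"],
        ic_var=ic0["ic_var"],
        bin_ms=segments.bin_ms,
        t0_ms=segments.t0_ms,
    )
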