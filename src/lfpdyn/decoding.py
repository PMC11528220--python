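"""Kinematic decoding and evaluation metrics.

A ridge-regularized Wiener filter with spike-history bins maps lagged neural
features to 2-D cursor velocity; the regularization constant is chosen by
10-fold cross-validation over a log-spaced grid, with contiguous time-block
folds to avoid leakage through overlapping history. Reconstruction quality is
summarized by variance-weighted R² (pooled over output dimensions), PSTH R²
(per-channel R² on concatenated condition averages), and phoneme error rate
(edit distance over true length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import linalg

from .events import extract_aligned
from .preprocess import gaussian_smooth
from .session import BinnedFeatures, ValidationError


# ---------------------------------------------------------------------------
# Wiener filter
# ---------------------------------------------------------------------------


@dataclass
class WienerDecoder:
    """Linear filter y_t = [x_t, x_{t-1}, ..., x_{t-h}, 1] @ W."""

    W: np.ndarray  # (n_features*(history+1) + 1) x out_dims
    history_bins: int = 4
    lam: float = 0.0
    feature_names: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.W


def build_design(features: np.ndarray, history_bins: int = 4) -> np.ndarray:
    """Lagged design matrix with a trailing bias column.

    ``features`` is time x channels; row t of the output concatenates feature
    bins t, t-1, ..., t-history plus a constant 1. The first ``history`` rows
    (which lack full history) are dropped, so targets must be aligned with
    ``y[history:]``.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValidationError("build_design: features must be time x channels")
    n, d = x.shape
    if n <= history_bins:
        raise ValidationError(f"build_design: {n} bins <= history {history_bins}")
    cols = [x[history_bins - k : n - k] for k in range(history_bins + 1)]
    X = np.concatenate(cols, axis=1)
    return np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)


def fit_wiener(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 0.0,
    history_bins: int = 4,
    squared_penalty: bool = False,
) -> WienerDecoder:
    """Solve ``(XᵀX + P) W = Xᵀ y`` with the bias unregularized.

    P is diagonal with ``lam`` on every entry except 0 at the bias column
    (with ``squared_penalty=True`` the literal RᵀR reading, penalty lam²).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValidationError("fit_wiener: X and y must be row-aligned")
    p = X.shape[1]
    pen = np.full(p, lam**2 if squared_penalty else lam)
    pen[-1] = 0.0  # bias
    A = X.T @ X + np.diag(pen)
    if lam == 0.0 and np.linalg.matrix_rank(A) < p:
        raise np.linalg.LinAlgError("fit_wiener: singular normal equations with lam=0")
    W = linalg.solve(A, X.T @ y, assume_a="pos")
    return WienerDecoder(W=W, history_bins=history_bins, lam=lam)


def variance_weighted_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Pooled R²: 1 - Σ_d Σ_i (ŷ-y)² / Σ_d Σ_i (y-ȳ_d)².

    A single pooled ratio (dimensions with larger variance weigh more), not a
    per-dimension average. May be negative on held-out data.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    yhat = np.atleast_2d(np.asarray(yhat, dtype=float).T).T
    if y.shape != yhat.shape or y.shape[0] < 2:
        raise ValidationError("variance_weighted_r2: shapes must match with N >= 2")
    ss_res = np.sum((yhat - y) ** 2)
    ss_tot = np.sum((y - y.mean(axis=0, keepdims=True)) ** 2)
    if ss_tot <= 0:
        raise ValidationError("variance_weighted_r2: zero total variance")
    return float(1.0 - ss_res / ss_tot)


def cv_decode(
    features: np.ndarray,
    targets: np.ndarray,
    lam_grid: np.ndarray | None = None,
    k_folds: int = 10,
    history_bins: int = 4,
    holdout_frac: float = 0.2,
) -> dict:
    """Sweep the ridge constant by blocked cross-validation, then evaluate.

    The last ``holdout_frac`` of rows is held out entirely; the remainder is
    split into ``k_folds`` contiguous time blocks. For each lambda the mean
    validation variance-weighted R² across folds picks the winner; the final
    decoder is refit on all CV rows and scored on the untouched holdout.
    Rows whose history spans a fold boundary are dropped from validation.
    """
    if lam_grid is None:
        lam_grid = np.logspace(np.log10(100.0), np.log10(1000.0), 20)
    lam_grid = np.asarray(lam_grid, dtype=float)
    X_all = build_design(features, history_bins)
    y_all = np.asarray(targets, dtype=float)
    if y_all.ndim == 1:
        y_all = y_all[:, None]
    y_all = y_all[history_bins:]
    n = X_all.shape[0]
    n_hold = int(round(holdout_frac * n))
    n_cv = n - n_hold
    if k_folds > n_cv:
        raise ValidationError(f"cv_decode: k_folds {k_folds} > {n_cv} CV rows")
    bounds = np.linspace(0, n_cv, k_folds + 1).astype(int)
    scores = np.zeros((lam_grid.size, k_folds))
    for f in range(k_folds):
        lo, hi = bounds[f], bounds[f + 1]
        val = np.arange(lo, hi)
        train = np.concatenate([np.arange(0, max(lo - history_bins, 0)), np.arange(hi, n_cv)])
        # rows at the start of the val block share history with train rows; drop them
        val = val[val >= lo + history_bins] if lo > 0 else val
        if val.size < 2 or train.size < X_all.shape[1] // 2:
            scores[:, f] = np.nan
            continue
        for i, lam in enumerate(lam_grid):
            dec = fit_wiener(X_all[train], y_all[train], lam, history_bins)
            scores[i, f] = variance_weighted_r2(y_all[val], dec.predict(X_all[val]))
    mean_scores = np.nanmean(scores, axis=1)
    best = int(np.argmax(mean_scores))
    dec = fit_wiener(X_all[:n_cv], y_all[:n_cv], lam_grid[best], history_bins)
    if n_hold >= 2:
        r2 = variance_weighted_r2(y_all[n_cv:], dec.predict(X_all[n_cv:]))
    else:
        r2 = float(mean_scores[best])
    return {
        "best_lam": float(lam_grid[best]),
        "holdout_r2": r2,
        "cv_r2": float(mean_scores[best]),
        "decoder": dec,
        "lam_grid": lam_grid,
        "mean_scores": mean_scores,
    }


# ---------------------------------------------------------------------------
# PSTH R²
# ---------------------------------------------------------------------------


def psth_r2(
    rates: BinnedFeatures,
    reference: BinnedFeatures,
    trials: pd.DataFrame,
    smooth_sd_ms: float = 30.0,
    pre_ms: float = 250.0,
    post_ms: float = 500.0,
) -> tuple[float, np.ndarray]:
    """PSTH R² between inferred rates and (smoothed) reference activity.

    Reference spike counts are Gaussian-smoothed with ``smooth_sd_ms``;
    reference rates are used as-is. Both signals are windowed around each
    accepted trial's alignment time, averaged within condition, and the
    condition averages are concatenated along time; the per-channel
    coefficient of determination is computed on the concatenation and
    averaged uniformly over channels.
    """
    if reference.kind == "spike_counts":
        reference = gaussian_smooth(reference, smooth_sd_ms)
    ten_r, lab_r = extract_aligned(rates, trials, pre_ms, post_ms)
    ten_s, lab_s = extract_aligned(reference, trials, pre_ms, post_ms)
    if ten_r.shape[0] < 2:
        raise ValidationError("psth_r2: need at least 2 accepted trials")
    conds = [c for c in pd.unique(lab_s) if np.sum(lab_s == c) >= 2]
    if len(conds) < 2:
        raise ValidationError("psth_r2: need >= 2 conditions with >= 2 accepted trials")
    avg_r = np.concatenate([ten_r[lab_r == c].mean(axis=0) for c in conds], axis=1)
    avg_s = np.concatenate([ten_s[lab_s == c].mean(axis=0) for c in conds], axis=1)
    per_channel = np.empty(avg_r.shape[0])
    for ch in range(avg_r.shape[0]):
        y, yh = avg_s[ch], avg_r[ch]
        ss_tot = np.sum((y - y.mean()) ** 2)
        per_channel[ch] = 1.0 - np.sum((yh - y) ** 2) / ss_tot if ss_tot > 0 else np.nan
    return float(np.nanmean(per_channel)), per_channel


# ---------------------------------------------------------------------------
# phoneme error rate
# ---------------------------------------------------------------------------


def phoneme_error_rate(decoded, truth) -> float:
    """Levenshtein distance (unit-cost sub/ins/del) over the true length."""
    truth = list(truth)
    decoded = list(decoded)
    if len(truth) == 0:
        raise ValidationError("phoneme_error_rate: empty truth sequence")
    symbols = {s: chr(0x100 + i) for i, s in enumerate(dict.fromkeys(truth + decoded))}
    d = edlib.align("".join(symbols[s] for s in decoded), "".join(symbols[s] for s in truth))
    return d["editDistance"] / len(truth)
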