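"""Empirical-Bayes location/scale batch-effect correction.

Per-chemical model: after removing covariate effects, each batch shifts the
standardized data by an additive term (gamma) and rescales it by a
multiplicative term (delta).  Per-batch, per-chemical estimates are shrunk
toward across-chemical parametric priors (normal for gamma, inverse-gamma
for delta, both moment-matched), then the data are adjusted and the
covariate effects restored.  A single batch is returned unchanged, and
covariate columns perfectly confounded with batch are dropped with a
warning (the correction cannot separate them).
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError


def _drop_confounded(Z: np.ndarray, X: np.ndarray, names) -> tuple:
    """Remove covariate columns lying in the span of the batch indicators."""
    keep, dropped = [], []
    for j in range(X.shape[1]):
        coef, *_ = np.linalg.lstsq(Z, X[:, j], rcond=None)
        resid = X[:, j] - Z @ coef
        scale = max(np.linalg.norm(X[:, j]), 1.0)
        if np.linalg.norm(resid) < 1e-8 * scale:
            dropped.append(names[j] if names is not None else j)
        else:
            keep.append(j)
    if dropped:
        warnings.warn(
            f"covariate column(s) confounded with batch dropped: {dropped}",
            stacklevel=3,
        )
    return X[:, keep], keep


def correct_batch_effects(
    log_abundance: pd.DataFrame,
    batch: pd.Series,
    design: Optional[pd.DataFrame] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Remove additive and multiplicative batch effects from log abundances.

    Parameters
    ----------
    log_abundance
        Chemicals x samples matrix of log-transformed abundances.
    batch
        Batch label per sample (index must cover the columns).
    design
        Optional samples x covariates indicator matrix (no intercept); the
        fitted covariate effects are preserved by the correction.
    """
    Y = log_abundance.to_numpy(dtype=float)  # G x n
    cols = list(log_abundance.columns)
    b = batch.reindex(cols)
    if b.isna().any():
        raise ValidationError("batch label missing for some samples")
    levels = sorted(b.unique())
    if len(levels) == 1:
        return log_abundance.copy()
    counts = b.value_counts()
    if (counts < 2).any():
        raise ValidationError("every batch needs at least 2 samples")
    n = len(cols)
    G = Y.shape[0]
    Z = np.column_stack([(b == lv).to_numpy(dtype=float) for lv in levels])
    n_b = Z.sum(axis=0)

    if design is not None and design.shape[1] > 0:
        X = design.reindex(cols).to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValidationError("design matrix missing rows for some samples")
        X, kept = _drop_confounded(Z, X, list(design.columns))
    else:
        X = np.empty((n, 0))

    D = np.hstack([Z, X])
    B_hat, *_ = np.linalg.lstsq(D, Y.T, rcond=None)  # (B+p) x G
    grand = (n_b / n) @ B_hat[: len(levels)]  # G
    stand_mean = np.outer(np.ones(n), grand)
    if X.shape[1]:
        stand_mean = stand_mean + X @ B_hat[len(levels):]
    resid = Y.T - D @ B_hat
    var_pooled = (resid**2).mean(axis=0)
    var_pooled = np.maximum(var_pooled, 1e-12)
    s = (Y.T - stand_mean) / np.sqrt(var_pooled)  # n x G

    adjusted = s.copy()
    for i, lv in enumerate(levels):
        idx = Z[:, i].astype(bool)
        sb = s[idx]
        nb = int(n_b[i])
        gamma_hat = sb.mean(axis=0)
        delta_hat = sb.var(axis=0, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        if tau2 <= 0 or s2 <= 0 or G < 2:
            gamma_star, delta_star = gamma_hat, np.maximum(delta_hat, 1e-12)
        else:
            a_prior = (2.0 * s2 + m**2) / s2
            b_prior = (m * s2 + m**3) / s2
            gamma_star = gamma_hat.copy()
            delta_star = delta_hat.copy()
            for _ in range(max_iter):
                g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                    nb * tau2 + delta_star
                )
                ss = ((sb - g_new[None, :]) ** 2).sum(axis=0)
                d_new = (b_prior + 0.5 * ss) / (nb / 2.0 + a_prior - 1.0)
                change = max(
                    np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
                )
                gamma_star, delta_star = g_new, d_new
                if change < tol:
                    break
            delta_star = np.maximum(delta_star, 1e-12)
        adjusted[idx] = (sb - gamma_star[None, :]) / np.sqrt(delta_star[None, :])

    out = adjusted * np.sqrt(var_pooled) + stand_mean
    return pd.DataFrame(out.T, index=log_abundance.index, columns=cols)
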