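"""Shrinkage estimation of a gene set covariance matrix.

When a set holds more genes than there are samples, the sample covariance is
singular; multivariate statistics that invert it need regularisation.  The
estimator here shrinks the sample correlation matrix toward the identity
with a data-driven intensity (Schafer-Strimmer style) while leaving the
sample variances untouched:

    s*_ij = s_ii                      if i == j
    s*_ij = r_ij (1 - lambda*) sqrt(s_ii s_jj)   otherwise,

    lambda* = sum_{i!=j} Var^(r_ij) / sum_{i!=j} r_ij^2,

clipped to [0, 1].  For lambda* in (0, 1) the shrunk correlation matrix
(1 - lambda*) R + lambda* I is positive definite, so the estimate is always
invertible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShrinkageEstimate",
    "shrinkage_intensity",
    "shrink_covariance",
    "within_group_residuals",
]


@dataclass
class ShrinkageEstimate:
    covariance: np.ndarray        # (m, m), diagonal = sample variances
    intensity: float              # clipped to [0, 1]
    raw_intensity: float          # pre-clipping value (may be inf)
    sample_correlation: np.ndarray
    sample_variances: np.ndarray


def _moments(X: np.ndarray, n_groups: int):
    """Centered data, df-denominator variances and correlations.

    ``n_groups`` is the number of groups the residuals in ``X`` were pooled
    over (1 for plain observations); variances and correlations use the
    denominator n - n_groups.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n < 3:
        raise ValueError("insufficient samples for shrinkage (need n >= 3)")
    if m < 2:
        raise ValueError("shrinkage needs at least 2 variables")
    df = n - n_groups
    if df < 2:
        raise ValueError("insufficient residual degrees of freedom for shrinkage")
    Xc = X - X.mean(axis=0)
    variances = (Xc**2).sum(axis=0) / df
    if np.any(variances <= 0):
        raise ValueError("zero-variance column passed to shrinkage (filter genes first)")
    sd = np.sqrt(variances)
    Xs = Xc / sd  # df-denominator standardized data
    corr = (Xs.T @ Xs) / df
    np.fill_diagonal(corr, 1.0)
    return Xs, corr, variances, n, df


def shrinkage_intensity(X: np.ndarray, n_groups: int = 1) -> float:
    """Pre-clipping optimal intensity lambda* for observations ``X`` (n x m).

    Computed as sum Var^(r_ij) / sum r_ij^2 over off-diagonal pairs, with
    the empirical variance estimator
    Var^(r_ij) = n / df^3 * sum_k (w_kij - w_bar_ij)^2 on standardized
    products w_kij.  Returns ``inf`` when all off-diagonal correlations are
    exactly zero (forcing full shrinkage to a diagonal matrix).
    """
    Xs, corr, _, n, df = _moments(X, n_groups)
    m = Xs.shape[1]
    offdiag = ~np.eye(m, dtype=bool)
    denom = float((corr[offdiag] ** 2).sum())
    if denom == 0.0:
        return np.inf
    # Var^(r_ij) via sums of w and w^2: w_kij = x~_ki x~_kj
    s_w = Xs.T @ Xs                       # sum_k w_kij
    s_w2 = (Xs**2).T @ (Xs**2)            # sum_k w_kij^2
    var_r = n / df**3 * (s_w2 - s_w**2 / n)
    num = float(var_r[offdiag].sum())
    return num / denom


def shrink_covariance(X: np.ndarray, n_groups: int = 1) -> ShrinkageEstimate:
    """Shrunk covariance of observations (or pooled residuals) ``X`` (n x m)."""
    lam_raw = shrinkage_intensity(X, n_groups)
    _, corr, variances, _, _ = _moments(X, n_groups)
    lam = min(1.0, max(0.0, lam_raw)) if np.isfinite(lam_raw) else 1.0
    shrunk_corr = corr * (1.0 - lam)
    np.fill_diagonal(shrunk_corr, 1.0)
    sd = np.sqrt(variances)
    cov = shrunk_corr * np.outer(sd, sd)
    np.fill_diagonal(cov, variances)
    return ShrinkageEstimate(
        covariance=cov,
        intensity=lam,
        raw_intensity=lam_raw,
        sample_correlation=corr,
        sample_variances=variances,
    )


def within_group_residuals(values: np.ndarray, group_indices: dict[str, np.ndarray]) -> np.ndarray:
    """Samples x genes residuals after removing each group's mean vector.

    ``values`` is genes x samples (the dataset orientation); the result is
    oriented samples x genes for the covariance routines.
    """
    values = np.asarray(values, dtype=float)
    resid = np.empty_like(values)
    for idx in group_indices.values():
        sub = values[:, idx]
        resid[:, idx] = sub - sub.mean(axis=1, keepdims=True)
    return resid.T
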