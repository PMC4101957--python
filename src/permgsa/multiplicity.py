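"""Across-set multiple-testing adjustment.

Two adjustments are attached to every family of set-level permutation tests:
the Benjamini-Hochberg FDR step-up and a single-step Westfall-Young
permutation FWER adjustment (min-P by default, max-T available).  BH accepts
an external family size ``m_total`` larger than the number of supplied
P-values, for the common reporting situation where only the k smallest
P-values of a large family are in hand.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust", "permutation_fwer"]


def bh_adjust(pvalues, m_total: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values.

    ``adjusted_(r) = min_{j >= r} p_(j) * m_total / j`` (capped at 1), mapped
    back to input order.  When ``m_total`` exceeds ``len(pvalues)``, the
    supplied values must be the smallest of the family; the suffix minimum
    then runs over the supplied ranks only.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    k = len(p)
    if m_total is None:
        m_total = k
    if m_total < k:
        raise ValueError("m_total cannot be smaller than the number of P-values")
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m_total / np.arange(1, k + 1)
    adjusted_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(k)
    out[order] = adjusted_sorted
    return out


def _raw_pvalues(observed: np.ndarray, null_matrix: np.ndarray, tail: str) -> np.ndarray:
    if tail == "upper":
        return (null_matrix >= observed).mean(axis=0)
    if tail == "lower":
        return (null_matrix <= observed).mean(axis=0)
    raise ValueError(f"unknown tail {tail!r}")


def permutation_fwer(
    observed,
    null_matrix,
    tail: str = "upper",
    method: str = "min_p",
) -> np.ndarray:
    """Single-step permutation FWER-adjusted P-values.

    ``null_matrix`` is nbPerm x n_sets of statistics drawn from one shared
    permutation stream, columns aligned with ``observed``.  The default
    ``min_p`` converts every permutation's row to per-set raw P-values
    against each set's own null column, takes the row minimum, and adjusts
    each set's raw P as the fraction of rows whose minimum P is <= it.
    ``max_t`` compares statistics directly on their common scale (row
    maximum for ``tail="upper"``, row minimum for ``"lower"``).

    Being rank-based, min-P is invariant under any strictly monotone
    transformation of the statistic.  Single-step (not step-down), so the
    adjusted values need not be monotone in the raw-P ordering.
    """
    observed = np.asarray(observed, dtype=float)
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.ndim != 2 or null_matrix.shape[1] != len(observed):
        raise ValueError("null_matrix must be nbPerm x n_sets, aligned with observed")
    nb_perm = null_matrix.shape[0]
    raw = _raw_pvalues(observed, null_matrix, tail)

    if method == "min_p":
        # per-column raw P of each permuted statistic against its own null
        null_p = np.empty_like(null_matrix)
        for j in range(null_matrix.shape[1]):
            col = np.sort(null_matrix[:, j])
            if tail == "upper":
                null_p[:, j] = nb_perm - np.searchsorted(col, null_matrix[:, j], side="left")
            else:
                null_p[:, j] = np.searchsorted(col, null_matrix[:, j], side="right")
        null_p /= nb_perm
        min_p = null_p.min(axis=1)
        adjusted = np.array([np.mean(min_p <= r) for r in raw])
    elif method == "max_t":
        if tail == "upper":
            extreme = null_matrix.max(axis=1)
            adjusted = np.array([np.mean(extreme >= o) for o in observed])
        else:
            extreme = null_matrix.min(axis=1)
            adjusted = np.array([np.mean(extreme <= o) for o in observed])
    else:
        raise ValueError(f"unknown FWER method {method!r}")
    return np.maximum(adjusted, raw)
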