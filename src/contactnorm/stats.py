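"""Shared statistics: pooled-variance Student t-test, fold changes, SEM.

The two-tailed Student t-test with pooled variance is the single test used
by every stage of the cascade and by the assay summaries, so it lives here
with an explicit implementation (degrees of freedom ``n_a + n_b - 2``).
The zero-pooled-variance corner is handled deterministically: equal means
give ``t = 0, p = 1``; unequal means give ``p = 0`` with a warning, a state
only reachable on noise-free synthetic data.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def pooled_t_arrays(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equal-variance two-sample t-test along the last axis.

    Parameters
    ----------
    a, b:
        Arrays of shape ``(..., n_a)`` and ``(..., n_b)`` with ``n >= 2``.

    Returns
    -------
    (t, p):
        t statistics (mean(a) - mean(b)) and two-tailed p-values.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[-1], b.shape[-1]
    if na < 2 or nb < 2:
        raise ValueError(f"each sample needs >= 2 values, got {na} and {nb}")
    df = na + nb - 2
    ma, mb = a.mean(axis=-1), b.mean(axis=-1)
    va, vb = a.var(axis=-1, ddof=1), b.var(axis=-1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    zero_se = se == 0
    if np.any(zero_se):
        equal = zero_se & (diff == 0)
        degenerate = zero_se & (diff != 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        if np.any(degenerate):
            warnings.warn(
                "zero pooled variance with unequal means: p set to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            t = np.where(degenerate, np.sign(diff) * np.inf, t)
            p = np.where(degenerate, 0.0, p)
    return t, p


def student_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed pooled-variance Student t-test between two replicate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("expected 1-D replicate vectors")
    t, p = pooled_t_arrays(a, b)
    return TTestResult(float(t), a.size + b.size - 2, float(p))


def fold_change(mean_num: float, mean_den: float, pseudocount: float = 1.0) -> float:
    """Pseudocount-stabilized ratio of group means.

    ``(mean_num + pseudocount) / (mean_den + pseudocount)``; the pseudocount
    bounds the ratio for near-zero genes. Rejected when numerator mean,
    denominator mean and pseudocount are all zero.
    """
    if mean_num < 0 or mean_den < 0:
        raise ValueError("group means must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    den = mean_den + pseudocount
    if den == 0:
        if mean_num + pseudocount == 0:
            raise ValueError("fold change undefined: both means and pseudocount are zero")
        return float("inf")
    return (mean_num + pseudocount) / den


def fold_change_arrays(
    mean_num: np.ndarray, mean_den: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """Vectorized :func:`fold_change`; zero/zero (with zero pseudocount) is NaN."""
    num = np.asarray(mean_num, dtype=float) + pseudocount
    den = np.asarray(mean_den, dtype=float) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / np.where(den > 0, den, 1.0),
                        np.where(num > 0, np.inf, np.nan))


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample standard deviation (n-1) / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size == 1:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default in the cascade)."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")
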