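"""Two-sample comparisons shared by the fly and zebrafish modules.

The Welch form is the default everywhere: behavioral groups routinely differ
in variance (knockout vs. control), and the Welch-Satterthwaite approximation
costs nothing when variances happen to be equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class StatResult:
    mean_difference: float
    se: float
    t_statistic: float
    df: float
    p_value: float
    method: str  # "welch" | "pooled"


def _prep(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return a, b


def welch_ttest(a, b) -> StatResult:
    """Two-sample t-test with Welch-Satterthwaite degrees of freedom.

    Reports mean(a) - mean(b), its standard error, t, non-integer df, and the
    two-sided p-value.
    """
    a, b = _prep(a, b)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    se = float(np.sqrt(se2))
    if se == 0.0:
        # identical constant samples: no evidence of a difference
        return StatResult(float(diff), 0.0, 0.0, float(na + nb - 2), 1.0, "welch")
    t = float(diff / se)
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(float(diff), se, t, df, p, "welch")


def pooled_ttest(a, b) -> StatResult:
    """Classic equal-variance two-sample t-test (df = nA + nB - 2)."""
    a, b = _prep(a, b)
    na, nb = a.size, b.size
    df = float(na + nb - 2)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    se = float(np.sqrt(sp2 * (1 / na + 1 / nb)))
    if se == 0.0:
        return StatResult(float(diff), 0.0, 0.0, df, 1.0, "pooled")
    t = float(diff / se)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(float(diff), se, t, df, p, "pooled")


def welch_pvalues_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized Welch p-values for replicate rows (reps x n per group).

    Used for Monte-Carlo calibration (type-I error at scale); row i compares
    A[i, :] with B[i, :].
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na, nb = A.shape[1], B.shape[1]
    va = A.var(axis=1, ddof=1)
    vb = B.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    t = (A.mean(axis=1) - B.mean(axis=1)) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * sps.t.sf(np.abs(t), df)
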