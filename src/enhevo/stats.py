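"""Exact tests on 2x2 contingency tables.

Fisher's exact test is evaluated by direct summation of the conditional
hypergeometric distribution over its full support, in log space, so it stays
numerically stable for tables with counts up to ~1e6 (the scale of
genome-wide polymorphism/divergence count tables).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

__all__ = ["fisher_exact_2x2"]

# Relative slack when comparing point probabilities to the observed one;
# tables tied with the observed probability must be included in the tail.
_TIE_SLACK = 1e-9


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    Parameters
    ----------
    table : 2x2 array-like of non-negative integers ``[[a, b], [c, d]]``.

    Returns
    -------
    (odds_ratio, p_value) where ``odds_ratio = a*d / (b*c)`` (sample odds
    ratio, ``inf`` when ``b*c == 0`` and ``a*d > 0``) and the p-value sums
    hypergeometric point probabilities not exceeding the observed table's.
    """
    tf = np.asarray(table, dtype=float)
    if tf.shape != (2, 2):
        raise ValueError("table must be 2x2")
    t = tf.astype(np.int64)
    if np.any(tf != t) or np.any(t < 0):
        raise ValueError("table entries must be non-negative integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])

    if a * d == 0 and b * c == 0:
        odds = np.nan
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)

    n = a + b + c + d
    if n == 0:
        return odds, 1.0
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = hypergeom.logpmf(support, n, r1, c1)
    log_obs = logpmf[a - lo]
    tail = logpmf <= log_obs + np.log1p(_TIE_SLACK)
    # log-sum-exp over the two-sided tail
    m = logpmf[tail].max()
    p = float(np.exp(m) * np.exp(logpmf[tail] - m).sum())
    return odds, min(1.0, p)
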