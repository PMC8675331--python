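"""Vectorized two-sided exact test on 2x2 count tables.

For a window with pooled counts (m1 methylated of t1) in group 1 and
(m2 of t2) in group 2, the null of equal methylation conditions on the
margins, so m1 follows a hypergeometric distribution.  The two-sided
p-value sums the probabilities of all outcomes no more likely than the
observed one — the same convention as ``scipy.stats.fisher_exact`` —
using the usual (1 + 1e-7) relative slack when comparing probability
masses, which absorbs floating-point ties.

The implementation evaluates log-probabilities with ``gammaln`` over the
full support of every table at once, so testing tens of thousands of
windows is a handful of array operations rather than per-table calls.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

_REL_SLACK = 1.0 + 1e-7


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def exact_test_2x2(
    m1: np.ndarray, t1: np.ndarray, m2: np.ndarray, t2: np.ndarray
) -> np.ndarray:
    """Two-sided exact p-values for arrays of 2x2 tables [[m1, t1-m1], [m2, t2-m2]].

    All arguments broadcast to a common shape; totals must be positive and
    0 <= m_i <= t_i.  Returns p-values in (0, 1].
    """
    m1, t1, m2, t2 = np.broadcast_arrays(
        np.atleast_1d(np.asarray(m1, dtype=np.int64)),
        np.atleast_1d(np.asarray(t1, dtype=np.int64)),
        np.atleast_1d(np.asarray(m2, dtype=np.int64)),
        np.atleast_1d(np.asarray(t2, dtype=np.int64)),
    )
    if (t1 <= 0).any() or (t2 <= 0).any():
        raise ValueError("group totals must be positive")
    if (m1 < 0).any() or (m1 > t1).any() or (m2 < 0).any() or (m2 > t2).any():
        raise ValueError("need 0 <= methylated <= total in each group")

    m = m1 + m2  # column margin (methylated)
    lo = np.maximum(0, m - t2)
    hi = np.minimum(t1, m)
    width = int((hi - lo).max()) + 1

    # support grid: k[i, j] = lo[i] + j, masked beyond hi
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    kc = np.where(valid, k, 0)

    logp = (
        _log_comb(t1[:, None], kc)
        + _log_comb(t2[:, None], (m[:, None] - kc))
        - _log_comb((t1 + t2)[:, None], m[:, None])
    )
    logp = np.where(valid, logp, -np.inf)
    pmf = np.exp(logp)

    obs = np.take_along_axis(pmf, (m1 - lo)[:, None], axis=1)
    p = np.where(pmf <= obs * _REL_SLACK, pmf, 0.0).sum(axis=1)
    # normalize by the summed mass so the full-support case is exactly 1
    return np.minimum(p / pmf.sum(axis=1), 1.0)


def exact_test_single(m1: int, t1: int, m2: int, t2: int) -> float:
    """Scalar convenience wrapper around :func:`exact_test_2x2`."""
    return float(exact_test_2x2(m1, t1, m2, t2)[0])
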