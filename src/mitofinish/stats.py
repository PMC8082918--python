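"""Contingency-table inference: Yates-corrected chi-square, Fisher's exact
test, and Monte-Carlo simulated p-values with fixed margins.

These mirror the default behaviour of the standard R primitives: the 2x2
chi-square applies a continuity correction capped at |O - E| (so a perfectly
null table scores 0), Fisher's two-sided p sums all tables at fixed margins
whose point probability does not exceed the observed one, and the simulated
p-value uses the add-one estimator over fixed-margin resamples of the
uncorrected Pearson statistic.
"""

from __future__ import annotations

from math import comb

import numpy as np

from .records import ContingencyTable2x2


def _expected_2x2(t: ContingencyTable2x2):
    r1, r2 = t.a + t.b, t.c + t.d
    c1, c2 = t.a + t.c, t.b + t.d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("degenerate table: zero row or column margin")
    n = t.n
    return np.array([[r1 * c1, r1 * c2], [r2 * c1, r2 * c2]], float) / n


def chi2_yates_2x2(t: ContingencyTable2x2) -> tuple[float, int]:
    """Continuity-corrected chi-square statistic for a 2x2 table; df = 1.

    The correction is min(0.5, |O - E|), so observed == expected gives 0.
    """
    obs = np.array([[t.a, t.b], [t.c, t.d]], float)
    exp = _expected_2x2(t)
    dev = np.abs(obs - exp)
    dev = dev - np.minimum(0.5, dev)
    return float((dev**2 / exp).sum()), 1


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact p: sum of hypergeometric point probabilities
    not exceeding the observed table's probability (with a relative slack for
    floating-point ties, as the common implementations do)."""
    r1, c1, n = t.a + t.b, t.a + t.c, t.n

    def pmf(a):
        return comb(r1, a) * comb(n - r1, c1 - a) / comb(n, c1)

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = pmf(t.a)
    total = 0.0
    for a in range(lo, hi + 1):
        p = pmf(a)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def _pearson(obs: np.ndarray, exp: np.ndarray) -> float:
    return float(((obs - exp) ** 2 / exp).sum())


def simulated_p(table, B: int = 10_000, seed: int = 0) -> float:
    """Monte-Carlo p-value for an r x c table with fixed margins.

    Replicate tables are drawn by permuting the column labels against the row
    labels (equivalent in law to fixed-margin sampling); the statistic is the
    uncorrected Pearson chi-square; p = (1 + #{sim >= obs}) / (B + 1).
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2 or (obs < 0).any() or obs.sum() == 0:
        raise ValueError("table must be a non-negative 2-D count array")
    r, c = obs.shape
    row_m, col_m = obs.sum(axis=1), obs.sum(axis=0)
    if (row_m == 0).any() or (col_m == 0).any():
        raise ValueError("degenerate table: zero margin")
    exp = np.outer(row_m, col_m) / obs.sum()
    stat_obs = _pearson(obs, exp)
    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(r), row_m)
    col_labels = np.repeat(np.arange(c), col_m)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(col_labels)
        sim = np.bincount(row_labels * c + perm, minlength=r * c).reshape(r, c)
        if _pearson(sim, exp) >= stat_obs - 1e-9:
            hits += 1
    return (1 + hits) / (B + 1)
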