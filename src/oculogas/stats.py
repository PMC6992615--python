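"""Exact small-sample rank tests and cohort summaries.

The cohort here is tiny (n = 8 eyes measured in two postures), so both
tests are computed exactly by full enumeration: the Wilcoxon signed-rank
test over all sign assignments of the non-zero paired differences, and the
Mann-Whitney U test over all group labelings of the combined sample.  Tied
absolute values receive mid-ranks; zero differences are dropped by default
(Wilcoxon's original rule; Pratt's rule is available behind a flag).
Two-sided p-values double the smaller tail probability and are capped at 1.
A tie-corrected normal approximation is reported alongside the exact value,
because commercial software at these sample sizes may use either.

Note on usage fidelity: prone-vs-supine comparisons of the same eyes are
paired data, yet the study design applies the unpaired Mann-Whitney test to
them; :func:`prone_supine_comparison` reproduces that choice and reports the
paired Wilcoxon alongside as a methodological footnote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "summarize",
    "prone_supine_comparison",
]

EXACT_LIMIT_WILCOXON = 20  # enumerate 2^m sign assignments up to this m
EXACT_LIMIT_MWU = 20       # enumerate C(n, n_a) labelings up to this total n


@dataclass
class TestResult:
    """Outcome of a two-sided nonparametric test."""

    method: str
    statistic: float
    p_value: float
    exact: bool
    n: int
    p_exact: float | None = None
    p_approx: float | None = None
    group_sizes: tuple | None = None

    def __post_init__(self):
        for p in (self.p_value, self.p_exact, self.p_approx):
            if p is not None and not 0.0 <= p <= 1.0 + 1e-12:
                raise ValueError(f"p-value out of range: {p}")


def _two_sided_from_cdf(weights: np.ndarray, values: np.ndarray, observed: float) -> float:
    """Two-sided p by doubling the smaller of P(T <= t), P(T >= t), capped at 1."""
    total = weights.sum()
    lo = weights[values <= observed + 1e-9].sum() / total
    hi = weights[values >= observed - 1e-9].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(x, y=None, zero_rule: str = "wilcoxon") -> TestResult:
    """Wilcoxon signed-rank test on paired data (or precomputed differences).

    ``x`` may be the differences directly, or the first sample with ``y``
    the second (differences ``x - y``).  Mid-ranks are used for tied
    absolute differences.  ``zero_rule='wilcoxon'`` drops zero differences;
    ``'pratt'`` ranks them but excludes them from the statistic.  Exact
    enumeration of all ``2^m`` sign assignments when the number of non-zero
    differences is at most 20, normal approximation (tie-corrected, with
    continuity correction) otherwise; both are reported when available.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if zero_rule not in ("wilcoxon", "pratt"):
        raise ValueError("zero_rule must be 'wilcoxon' or 'pratt'")
    nonzero = d != 0
    m = int(nonzero.sum())
    if m < 2:
        raise ValueError("need at least two non-zero paired differences")
    if zero_rule == "wilcoxon":
        d_used = d[nonzero]
        ranks = rankdata(np.abs(d_used))
    else:
        ranks_all = rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    w_plus = float(ranks[d_used > 0].sum())

    # Null moments with mid-rank ties (and Pratt's zero adjustment folded in
    # through the actual rank values).
    mu = ranks.sum() / 2.0
    sigma2 = float((ranks**2).sum()) / 4.0
    p_approx = None
    if sigma2 > 0:
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(sigma2)
        p_approx = float(min(1.0, 2.0 * (1.0 - _norm_cdf(abs(z)))))

    p_exact = None
    if m <= EXACT_LIMIT_WILCOXON:
        # Distribution of W+ over all 2^m sign assignments via convolution
        # on a half-rank integer grid (mid-ranks are multiples of 1/2).
        scaled = np.rint(ranks * 2).astype(int)
        dist = np.zeros(scaled.sum() + 1)
        dist[0] = 1.0
        for r in scaled:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        values = np.arange(dist.size) / 2.0
        p_exact = _two_sided_from_cdf(dist, values, w_plus)

    exact = p_exact is not None
    return TestResult(
        method="wilcoxon_signed_rank",
        statistic=w_plus,
        p_value=p_exact if exact else p_approx,
        exact=exact,
        n=m,
        p_exact=p_exact,
        p_approx=p_approx,
    )


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Mann-Whitney U test on two independent samples.

    ``U`` counts pairs ``(a, b)`` with ``a > b`` plus half the ties,
    computed from mid-ranks.  Exact two-sided p by enumeration of all
    ``C(n_a + n_b, n_a)`` group labelings when the total sample size is at
    most 20; tie-corrected normal approximation otherwise (both reported
    when available).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    ra = float(ranks[:na].sum())
    u_obs = ra - na * (na + 1) / 2.0

    n = na + nb
    # Normal approximation with tie correction.
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = na * nb / 2.0
    p_approx = None
    if sigma2 > 0:
        z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / math.sqrt(sigma2)
        p_approx = float(min(1.0, 2.0 * (1.0 - _norm_cdf(abs(z)))))
    elif u_obs == mu:
        p_approx = 1.0

    p_exact = None
    if n <= EXACT_LIMIT_MWU:
        offset = na * (na + 1) / 2.0
        us = np.fromiter(
            (ranks[list(idx)].sum() - offset for idx in combinations(range(n), na)),
            dtype=float,
        )
        p_exact = _two_sided_from_cdf(np.ones_like(us), us, u_obs)

    exact = p_exact is not None
    return TestResult(
        method="mann_whitney_u",
        statistic=u_obs,
        p_value=p_exact if exact else p_approx,
        exact=exact,
        n=n,
        p_exact=p_exact,
        p_approx=p_approx,
        group_sizes=(na, nb),
    )


def round_half_up(x: float, decimals: int) -> float:
    """Round to ``decimals`` with ties away from zero, as printed tables do.

    Float summation noise is first flattened at 9 decimals so that an
    exact tie like 1.75 is not perturbed to 1.7499... before rounding.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(f"{x:.9f}").quantize(q, rounding=ROUND_HALF_UP))


def summarize(table: pd.DataFrame, columns: dict) -> pd.DataFrame:
    """Mean and standard error of named columns, at printed precision.

    ``columns`` maps column name to the number of decimals to report
    (1 d.p. for percentages, degrees, mm and years; 2 d.p. for logMAR).
    SE is the sample standard deviation over ``sqrt(n)`` with ``n`` the
    non-missing count.  Raises on non-numeric cells, naming the offender.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to summarize")
    rows = []
    for col, dec in columns.items():
        vals = table[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = vals.index[numeric.isna() & vals.notna()]
        if len(bad):
            raise ValueError(f"non-numeric cell in column {col!r}, row {bad[0]}")
        v = numeric.dropna().to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"column {col!r} has fewer than two numeric values")
        mean = float(np.mean(v))
        se = float(np.std(v, ddof=1) / math.sqrt(len(v)))
        rows.append(
            {
                "column": col,
                "n": len(v),
                "mean": round_half_up(mean, dec),
                "se": round_half_up(se, dec),
                "mean_raw": mean,
                "se_raw": se,
            }
        )
    return pd.DataFrame(rows).set_index("column")


def prone_supine_comparison(prone, supine) -> dict:
    """Prone-vs-supine comparison of one metric over the same eyes.

    Reproduces the study-design choice of an unpaired Mann-Whitney test on
    paired data, and reports the paired Wilcoxon signed-rank test alongside
    as a methodological note (the data are the same eyes in two postures).
    """
    mwu = mann_whitney_u(prone, supine)
    try:
        wil = wilcoxon_signed_rank(np.asarray(prone, float), np.asarray(supine, float))
    except ValueError:
        wil = None
    return {"mann_whitney": mwu, "paired_wilcoxon": wil}
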