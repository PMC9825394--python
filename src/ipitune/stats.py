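"""Interspecific comparison statistics.

* :func:`exact_wilcoxon` -- exact two-sided Wilcoxon rank-sum test.  The null
  distribution of the Mann-Whitney U statistic is enumerated exactly by the
  shift-algorithm dynamic program (the coefficients of the Gaussian binomial,
  computed with exact integer arithmetic), never by normal approximation.
  The two-sided p-value doubles the smaller tail: p = min(1, 2*min(P(U <= u),
  P(U >= u))).  With ties, mid-ranks are used and the p-value comes from a
  seeded Monte-Carlo permutation of the mid-rank statistic, flagged in the
  method tag.
* :func:`bonferroni_t` -- per-IPI two-tailed two-sample t-tests on response
  drops, Bonferroni-adjusted over the tested IPIs (Welch by default).
* :func:`frequency_interaction_lm` -- Gaussian linear model of pure-tone
  responses on frequency, species, and their interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "TwoSampleResult",
    "exact_wilcoxon",
    "rank_sum_null_counts",
    "bonferroni_t",
    "frequency_interaction_lm",
]


@dataclass(frozen=True)
class TwoSampleResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_two_sided: float
    method: str  # "exact" | "mid-rank-permutation"
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0 < self.p_two_sided <= 1):
            raise ValueError(f"invalid p-value {self.p_two_sided}")
        if not (0 <= self.statistic <= self.n1 * self.n2):
            raise ValueError("U outside [0, n1*n2]")


def rank_sum_null_counts(n1: int, n2: int) -> list:
    """Exact null counts of U = 0..n1*n2 for sample sizes (n1, n2).

    Entry u is the number of the C(n1+n2, n1) equally likely tie-free rank
    assignments whose Mann-Whitney statistic equals u.  These are the
    coefficients of the Gaussian binomial [n1+n2, n1]_q, built by the shift
    recurrence N(m, n, u) = N(m, n-1, u) + N(m-1, n, u-n) with exact Python
    integers, so there is no overflow at any supported sample size.
    """
    umax = n1 * n2
    # cols[m][u] holds N(m, n', u); n' sweeps 0..n2 in place.  Updating m
    # ascending and u descending makes the two recurrence terms read
    # N(m-1, n', .) (already advanced) and N(m, n'-1, .) (not yet advanced).
    cols = [[0] * (umax + 1) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        cols[m][0] = 1  # n' = 0: the only arrangement has u = 0
    for nprime in range(1, n2 + 1):
        for m in range(1, n1 + 1):
            col = cols[m]
            below = cols[m - 1]
            for u in range(umax, nprime - 1, -1):
                col[u] += below[u - nprime]
    return cols[n1]


def exact_wilcoxon(x, y, n_permutations: int = 100_000, seed: int = 0) -> TwoSampleResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test, exact when tie-free."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_stat = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= 60:
        counts = rank_sum_null_counts(n1, n2)
        total = sum(counts)
        u = int(round(u_stat))
        lower = sum(counts[: u + 1])
        upper = sum(counts[u:])
        from fractions import Fraction

        p = min(1, 2 * min(Fraction(lower, total), Fraction(upper, total)))
        return TwoSampleResult(
            statistic=u_stat, p_two_sided=float(p), method="exact", n1=n1, n2=n2
        )

    # mid-rank Monte-Carlo permutation fallback
    rng = np.random.default_rng(seed)
    perm_u = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(ranks)
        perm_u[b] = perm[:n1].sum() - n1 * (n1 + 1) / 2
    # add-one correction keeps p in (0, 1]
    lower = (np.sum(perm_u <= u_stat + 1e-9) + 1) / (n_permutations + 1)
    upper = (np.sum(perm_u >= u_stat - 1e-9) + 1) / (n_permutations + 1)
    p = min(1.0, 2 * min(lower, upper))
    return TwoSampleResult(
        statistic=u_stat, p_two_sided=float(p), method="mid-rank-permutation", n1=n1, n2=n2
    )


def bonferroni_t(
    delta_first: dict,
    delta_second: dict,
    equal_var: bool = False,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Two-tailed t-tests on response drops per IPI, Bonferroni-adjusted.

    ``delta_first``/``delta_second`` map IPI (ms) -> array of per-individual
    drops for each group.  Welch's unequal-variance t is the default.  The
    Bonferroni family defaults to the number of IPIs actually tested.  Two
    degenerate equal groups (zero variance, equal means) give p = 1.
    """
    ipis = sorted(delta_first)
    if sorted(delta_second) != ipis:
        raise ValueError("both groups must cover the same IPIs")
    m = family_size if family_size is not None else len(ipis)
    rows = []
    for ipi in ipis:
        g1 = np.asarray(delta_first[ipi], dtype=float)
        g2 = np.asarray(delta_second[ipi], dtype=float)
        if g1.size < 2 or g2.size < 2:
            raise ValueError(f"need >= 2 observations per group at IPI {ipi}")
        if g1.var() == 0 and g2.var() == 0:
            stat, p_raw = 0.0, 1.0
            if g1.mean() != g2.mean():
                stat, p_raw = np.inf, 0.0
        else:
            stat, p_raw = sps.ttest_ind(g1, g2, equal_var=equal_var)
        rows.append(
            {
                "ipi_ms": ipi,
                "t_statistic": float(stat),
                "p_raw": float(p_raw),
                "p_adjusted": float(min(1.0, p_raw * m)),
            }
        )
    return pd.DataFrame(rows)


def frequency_interaction_lm(responses: pd.DataFrame) -> pd.DataFrame:
    """Linear model: response ~ frequency + species + frequency:species.

    ``responses`` needs columns ``response``, ``frequency_hz``, ``species``
    (Gaussian family, identity link -- ordinary least squares).  Returns the
    coefficient table with estimates, standard errors and p-values.
    """
    required = {"response", "frequency_hz", "species"}
    if not required <= set(responses.columns):
        raise ValueError(f"responses table needs columns {sorted(required)}")
    if responses["species"].nunique() < 2:
        raise ValueError("both species must be present")
    if responses["frequency_hz"].nunique() < 2:
        raise ValueError("need at least two frequencies")
    model = smf.ols("response ~ frequency_hz * species", data=responses)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = model.fit()
    return pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.to_numpy(),
            "std_error": res.bse.to_numpy(),
            "p_value": res.pvalues.to_numpy(),
        }
    )
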