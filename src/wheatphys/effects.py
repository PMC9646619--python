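"""Treatment-effect estimation for factorial trait and gas-exchange tables.

Percent changes between treatment cells with percentile-bootstrap
confidence intervals, three-way factorial analysis of variance
(sequential sums of squares via OLS; all SS types coincide on the
balanced designs the generator emits), and Tukey-style compact letter
displays from the studentized-range criterion.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import norm, studentized_range, t as t_dist

__all__ = ["EffectEstimate", "percent_change", "factorial_anova",
           "tukey_letters", "significance_stars"]


@dataclass(frozen=True)
class EffectEstimate:
    """Percent change of a treatment group over a reference group."""

    percent: float
    ci_low: float
    ci_high: float
    level: float
    n_treat: int
    n_ref: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.percent <= self.ci_high:
            raise ValueError("CI must contain the point estimate")


def percent_change(treat, ref, B: int = 2000, seed: int | None = None,
                   level: float = 0.95) -> EffectEstimate:
    """100*(mean(treat) - mean(ref))/mean(ref) with a bootstrap CI.

    Groups need >= 2 positive-mean observations; B seeded resamples of
    each group give an expanded-percentile interval at ``level`` (the
    percentile quantiles widened by the t-based small-sample correction,
    which counters the narrowness of the plain percentile method at the
    group sizes of a glasshouse cell).
    """
    treat = np.asarray(treat, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if treat.size < 2 or ref.size < 2:
        raise ValueError("each group needs at least 2 observations")
    mref = ref.mean()
    if mref <= 0:
        raise ValueError("reference mean must be positive for a percent change")
    point = 100.0 * (treat.mean() - mref) / mref

    rng = np.random.default_rng(seed)
    ti = rng.integers(0, treat.size, size=(B, treat.size))
    ri = rng.integers(0, ref.size, size=(B, ref.size))
    mt = treat[ti].mean(axis=1)
    mr = ref[ri].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        boot = 100.0 * (mt - mr) / mr
    alpha = 1.0 - level
    # expanded percentile: replace z_{alpha/2} by t_{alpha/2, n-1}*sqrt(n/(n-1))
    n_eff = min(treat.size, ref.size)
    t_mult = t_dist.ppf(1.0 - alpha / 2.0, n_eff - 1) \
        * np.sqrt(n_eff / (n_eff - 1.0))
    alpha_exp = 2.0 * norm.cdf(-t_mult)
    lo, hi = np.nanquantile(boot, [alpha_exp / 2.0, 1.0 - alpha_exp / 2.0])
    # The percentile interval is not guaranteed to bracket the plug-in
    # point estimate on tiny groups; widen minimally if needed.
    lo, hi = min(lo, point), max(hi, point)
    return EffectEstimate(percent=float(point), ci_low=float(lo),
                          ci_high=float(hi), level=level,
                          n_treat=treat.size, n_ref=ref.size)


def factorial_anova(table: pd.DataFrame, response: str,
                    factors: tuple[str, ...] = ("cultivar", "co2", "hs"),
                    ) -> pd.DataFrame:
    """Full-factorial ANOVA table (df, sum_sq, F, PR(>F)) for one response.

    Sequential (type I) sums of squares from an OLS fit of the fully
    crossed model; on balanced designs these coincide with the other SS
    types and are invariant to factor order.  Raises on empty design
    cells, naming the first missing cell.
    """
    for f in factors:
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    counts = table.groupby(list(factors), observed=True).size()
    full = pd.MultiIndex.from_product(
        [table[f].unique() for f in factors], names=factors)
    missing = full.difference(counts.index)
    if len(missing) > 0:
        raise ValueError(f"empty design cell {dict(zip(factors, missing[0]))}")
    if (counts < 2).any():
        raise ValueError("every design cell needs >= 2 replicates")

    terms = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"{response} ~ {terms}", data=table).fit()
    return sm.stats.anova_lm(model, typ=1)


def significance_stars(p: float) -> str:
    """Map a p value to the conventional star notation (alpha = 0.05)."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def tukey_letters(means: dict[str, float], mse: float, df_resid: int,
                  n_per_cell: int | float, alpha: float = 0.05,
                  ) -> dict[str, str]:
    """Compact letter display from the Tukey studentized-range criterion.

    Two cells differ when |mean_i - mean_j| exceeds
    q(1-alpha; k, df) * sqrt(mse / n); cells sharing a letter are not
    significantly different.  ``n_per_cell`` may be a harmonic mean for
    mildly unbalanced designs.  Because the criterion depends only on the
    mean difference, letter groups are maximal runs of the sorted means.
    """
    if df_resid < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    if n_per_cell <= 0 or mse < 0:
        raise ValueError("need positive n and non-negative mse")
    k = len(means)
    if k == 1:
        return {next(iter(means)): "a"}
    qcrit = studentized_range.ppf(1.0 - alpha, k, df_resid)
    hsd = qcrit * np.sqrt(mse / n_per_cell)

    names = sorted(means, key=means.get, reverse=True)
    vals = [means[n] for n in names]

    # Maximal runs of mutually non-different cells along the sorted means.
    runs = []
    for i in range(k):
        j = i
        while j + 1 < k and vals[i] - vals[j + 1] <= hsd:
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = {n: "" for n in names}
    for letter, (lo, hi) in zip(string.ascii_lowercase, maximal):
        for idx in range(lo, hi + 1):
            letters[names[idx]] += letter
    return letters
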