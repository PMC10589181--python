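"""Statistical layer: per-occasion regressions, ANOVA + Tukey letters.

Each carbon pool is regressed (per jar, ordinary least squares) on a
treatment-level litter-quality indicator (C:N ratio or a DRIFT compound
ratio) at each sampling occasion; the mineral-N-amended treatment is
excluded because its amendment C:N does not describe the litter itself.
Treatment differences at the final occasion are tested with one-way ANOVA
and Tukey's HSD, summarised as a compact letter display (groups sharing a
letter are not significantly different).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["RegressionResult", "TukeyLetters", "linear_fit", "regress_pools",
           "anova_tukey", "compact_letter_display", "residual_normality_note"]


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope/intercept with fit and test statistics."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residuals: tuple[float, ...] = field(default=(), repr=False, compare=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope t-test.

    Degenerate cases are resolved explicitly: a constant y gives slope 0,
    R-squared 0 and p 1 (no variance to explain); an exact fit gives
    R-squared 1 and p 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope is not identifiable")
    if np.ptp(y) == 0:
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, n,
                                tuple(np.zeros(n)))
    model = sm.OLS(y, sm.add_constant(x)).fit()
    sse = float(np.sum(model.resid ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    se = float(model.bse[1])
    if se == 0 or not np.isfinite(se):
        p = 0.0 if sse == 0 else 1.0
    else:
        t = model.params[1] / se
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return RegressionResult(float(model.params[1]), float(model.params[0]),
                            r2, p, n, tuple(model.resid))


def regress_pools(pool_table: pd.DataFrame, quality_indicator: pd.Series | dict,
                  *, pools: list[str] | None = None,
                  exclude_labels: tuple[str, ...] = ("CN124N",),
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-jar OLS of each pool on a treatment-level quality indicator.

    One regression per pool x sampling occasion. Treatments in
    ``exclude_labels`` and treatments with no indicator value (the
    unamended control) are dropped. Requires at least three distinct
    included treatments.
    """
    indicator = pd.Series(quality_indicator, dtype=float)
    pools = pools or [c for c in ("poc_new", "poc_old", "maoc_new",
                                  "maoc_old", "bulk_total")
                      if c in pool_table.columns]
    keep = (~pool_table["treatment"].isin(exclude_labels)
            & pool_table["treatment"].isin(indicator.index))
    data = pool_table[keep]
    if data["treatment"].nunique() < 3:
        raise ValueError("fewer than 3 included treatments")
    rows = []
    for month, grp in data[data["month"] > 0].groupby("month", sort=True):
        x = grp["treatment"].map(indicator).to_numpy()
        for pool in pools:
            res = linear_fit(x, grp[pool].to_numpy())
            rows.append({"pool": pool, "month": month,
                         "slope": res.slope, "intercept": res.intercept,
                         "r_squared": res.r_squared, "p_value": res.p_value,
                         "n": res.n, "significant": res.p_value < alpha})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TukeyLetters:
    """Compact letter display plus the underlying Tukey-adjusted p-values."""

    letters: dict[str, str]
    p_values: pd.DataFrame
    anova_f: float
    anova_p: float
    alpha: float = 0.05


def compact_letter_display(groups: list[str],
                           significant: set[frozenset[str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``groups`` must be pre-ordered (descending mean); ``significant``
    holds the pairs that must NOT share a letter. Guarantees: a
    significant pair never shares a letter; a non-significant pair shares
    at least one. Deterministic for a given ordering.
    """
    # columns: ordered list of letter-classes, each a set of group names
    columns: list[set[str]] = [set(groups)]
    for i, gi in enumerate(groups):
        for gj in groups[i + 1:]:
            if frozenset((gi, gj)) not in significant:
                continue
            for col in [c for c in columns if gi in c and gj in c]:
                columns.remove(col)
                a, b = col - {gj}, col - {gi}
                for new in (a, b):
                    # absorb: drop duplicates/subsets of existing columns
                    if not any(new <= other for other in columns):
                        columns.append(new)
    # order columns by the position of their first (highest-mean) member
    rank = {g: k for k, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for idx, col in enumerate(columns):
        for g in groups:
            if g in col:
                letters[g] += alphabet[idx % len(alphabet)]
    return letters


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> TukeyLetters:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display.

    Pairwise p-values come from the studentized-range distribution
    (computed numerically); letters are assigned with groups ordered by
    mean, descending.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("need at least 2 observations per group")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    f_stat, f_p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    pmat = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    order = sorted(names, key=lambda n: -float(np.mean(groups[n])))
    significant = {frozenset((a, b))
                   for i, a in enumerate(names) for b in names[i + 1:]
                   if pmat.loc[a, b] < alpha}
    letters = compact_letter_display(order, significant)
    return TukeyLetters(letters=letters, p_values=pmat,
                        anova_f=float(f_stat), anova_p=float(f_p), alpha=alpha)


def residual_normality_note(residuals) -> dict:
    """Advisory residual-normality summary (never gates any result).

    Reports skewness and excess kurtosis plus theoretical-vs-sample
    quantile pairs for an external QQ plot; below four residuals the
    diagnostic is declared not assessable.
    """
    res = np.asarray(getattr(residuals, "resid", residuals), dtype=float)
    if res.size < 4:
        return {"assessable": False, "n": int(res.size),
                "note": "fewer than 4 residuals; normality not assessable"}
    skew = float(stats.skew(res))
    kurt = float(stats.kurtosis(res))
    order = np.sort(res)
    theo = stats.norm.ppf((np.arange(1, res.size + 1) - 0.5) / res.size)
    approx_normal = abs(skew) < 1.0 and abs(kurt) < 2.0
    return {"assessable": True, "n": int(res.size), "skewness": skew,
            "excess_kurtosis": kurt, "approximately_normal": approx_normal,
            "qq_theoretical": theo.tolist(), "qq_sample": order.tolist()}
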