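"""Bootstrap group comparisons and the standard statistical layer.

Three bootstrap schemes compare cell populations while neutralising the
unequal cell counts between groups:

* ``bootstrap_between`` — resample one group's per-cell metric at full size
  and count resample means strictly beyond a fixed reference mean.
* ``bootstrap_within_subsampled`` — resample both conditions down to a
  common cell count and count the sign of the mean difference.
* ``bootstrap_proportion`` — resample a class-label list and count resampled
  category fractions beyond a reference proportion.

p-values are raw directional proportions (ties count as non-exceeding, so a
complete separation reports p = 0); a (k+1)/(n+1)-corrected estimate is
carried alongside.  Every scheme is reproducible bit-for-bit under a seed.

The conventional layer (two-way ANOVA with post-hocs, chi-squared test of
two proportions, the trial-by-session regression of directionality-index
slopes) delegates to statsmodels / scipy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BootstrapResult",
    "bootstrap_between",
    "bootstrap_within_subsampled",
    "bootstrap_proportion",
    "AnovaTable",
    "two_way_anova",
    "pairwise_posthoc",
    "chi2_proportions",
    "di_slope_regression",
    "RegressionSlope",
]

_DIRECTIONS = ("greater", "smaller")


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of one directional bootstrap comparison."""

    statistic: str
    observed: float  # statistic on the original sample
    reference: float  # fixed comparison value (0 for paired-difference schemes)
    n_resamples: int
    exceedance: int  # resamples strictly beyond the reference, stated direction
    direction: str
    seed: int | None

    @property
    def p(self) -> float:
        """Raw proportion-based p-value (can be exactly 0)."""
        return self.exceedance / self.n_resamples

    @property
    def p_corrected(self) -> float:
        """(k+1)/(n+1) estimate, bounded away from 0."""
        return (self.exceedance + 1) / (self.n_resamples + 1)


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}")


def _count(values: np.ndarray, reference: float, direction: str) -> int:
    # strict inequalities: ties are non-exceeding
    if direction == "greater":
        return int((values > reference).sum())
    return int((values < reference).sum())


def bootstrap_between(values: Sequence[float], reference_mean: float,
                      n_resamples: int = 10000, direction: str = "smaller",
                      seed: int | None = None) -> BootstrapResult:
    """Between-group scheme: resample one group against a fixed reference mean.

    ``values`` (one per cell) are resampled with replacement at full size
    ``n_resamples`` times; the p-value is the proportion of resample means
    strictly beyond ``reference_mean`` in the stated direction.
    """
    _check_direction(direction)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_resamples, v.size))
    means = v[idx].mean(axis=1)
    return BootstrapResult(
        statistic="mean", observed=float(v.mean()), reference=float(reference_mean),
        n_resamples=n_resamples, exceedance=_count(means, reference_mean, direction),
        direction=direction, seed=seed,
    )


def bootstrap_within_subsampled(values_fam: Sequence[float], values_nov: Sequence[float],
                                n_target: int, n_resamples: int = 10000,
                                direction: str = "greater",
                                seed: int | None = None) -> BootstrapResult:
    """Within-group scheme: subsample both conditions to a common cell count.

    Each resample draws ``n_target`` cells with replacement from each
    condition independently and takes the mean difference (novel - familiar);
    the p-value counts differences strictly beyond 0 in the stated
    direction.  ``n_target`` is typically the smaller (control) group size.
    """
    _check_direction(direction)
    fam = np.asarray(values_fam, dtype=float)
    nov = np.asarray(values_nov, dtype=float)
    if fam.size == 0 or nov.size == 0:
        raise ValueError("both conditions must be non-empty")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    fam_means = fam[rng.integers(0, fam.size, size=(n_resamples, n_target))].mean(axis=1)
    nov_means = nov[rng.integers(0, nov.size, size=(n_resamples, n_target))].mean(axis=1)
    diffs = nov_means - fam_means
    return BootstrapResult(
        statistic="mean difference (novel - familiar)",
        observed=float(nov.mean() - fam.mean()), reference=0.0,
        n_resamples=n_resamples, exceedance=_count(diffs, 0.0, direction),
        direction=direction, seed=seed,
    )


def bootstrap_proportion(labels: Sequence, category, reference_prop: float,
                         n_resamples: int = 10000, direction: str = "greater",
                         seed: int | None = None) -> BootstrapResult:
    """Proportion scheme: resample class labels against a reference fraction.

    The category count of a with-replacement resample of ``n`` labels is
    Binomial(n, p_hat) with p_hat the observed fraction, so the resampled
    fractions are drawn directly from that distribution.
    """
    _check_direction(direction)
    lab = np.asarray(labels)
    if lab.size == 0:
        raise ValueError("labels must be non-empty")
    p_hat = float((lab == category).mean())
    if p_hat == 0.0:
        warnings.warn(
            f"category {category!r} absent from labels; resampled fractions are all 0",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    props = rng.binomial(lab.size, p_hat, size=n_resamples) / lab.size
    return BootstrapResult(
        statistic=f"proportion({category})", observed=p_hat,
        reference=float(reference_prop), n_resamples=n_resamples,
        exceedance=_count(props, reference_prop, direction),
        direction=direction, seed=seed,
    )


# ---------------------------------------------------------------------------
# Conventional statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    """F, p and degrees of freedom for the two main effects and interaction."""

    f_group: float
    p_group: float
    df_group: int
    f_session: float
    p_session: float
    df_session: int
    f_interaction: float
    p_interaction: float
    df_interaction: int
    df_residual: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "F": [self.f_group, self.f_session, self.f_interaction],
                "p": [self.p_group, self.p_session, self.p_interaction],
                "df": [self.df_group, self.df_session, self.df_interaction],
            },
            index=["group", "session", "group:session"],
        )


def two_way_anova(df: pd.DataFrame, value: str = "value", group: str = "group",
                  session: str = "session") -> AnovaTable:
    """Independent two-way ANOVA (group x session), fixed effects.

    Uses partial (type-II) sums of squares with sum-to-zero contrasts, which
    coincides with the textbook decomposition for balanced designs and
    remains well defined for the unbalanced cell counts typical of pooled
    cell populations.
    """
    data = df[[value, group, session]].dropna()
    for factor in (group, session):
        if data[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    if (data.groupby([group, session], observed=True).size() == 0).any() or (
        data.groupby([group, session], observed=True).ngroups
        < data[group].nunique() * data[session].nunique()
    ):
        raise ValueError("empty cell in the group x session design")
    model = smf.ols(
        f"Q('{value}') ~ C(Q('{group}'), Sum) * C(Q('{session}'), Sum)", data=data
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    rows = list(table.index)
    g_row, s_row, i_row = rows[0], rows[1], rows[2]

    def _fp(row) -> tuple[float, float, int]:
        f = table.loc[row, "F"]
        p = table.loc[row, "PR(>F)"]
        # an all-constant response has zero SS everywhere: report F=0, p=1
        if not np.isfinite(f):
            f, p = 0.0, 1.0
        return float(f), float(p), int(table.loc[row, "df"])

    fg, pg, dfg = _fp(g_row)
    fs, ps, dfs = _fp(s_row)
    fi, pi, dfi = _fp(i_row)
    return AnovaTable(
        f_group=fg, p_group=pg, df_group=dfg,
        f_session=fs, p_session=ps, df_session=dfs,
        f_interaction=fi, p_interaction=pi, df_interaction=dfi,
        df_residual=int(table.loc["Residual", "df"]),
    )


def pairwise_posthoc(df: pd.DataFrame, value: str = "value", group: str = "group",
                     session: str = "session", correction: str = "holm") -> pd.DataFrame:
    """Pairwise comparisons between the group x session cells.

    ``correction="tukey"`` runs Tukey's HSD over the four cells;
    ``"holm"`` runs Welch t-tests with Holm step-down adjustment.
    """
    data = df[[value, group, session]].dropna().copy()
    data["cell"] = data[group].astype(str) + ":" + data[session].astype(str)
    if correction == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(data[value], data["cell"])
        frame = pd.DataFrame(
            res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        )
        return frame.rename(columns={"p-adj": "p_adj"})
    if correction != "holm":
        raise ValueError("correction must be 'holm' or 'tukey'")
    cells = sorted(data["cell"].unique())
    rows = []
    for i, a in enumerate(cells):
        for b in cells[i + 1:]:
            va = data.loc[data["cell"] == a, value]
            vb = data.loc[data["cell"] == b, value]
            t, p = scipy.stats.ttest_ind(va, vb, equal_var=False)
            rows.append({"group1": a, "group2": b, "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    return out


def chi2_proportions(k1: int, n1: int, k2: int, n2: int) -> float:
    """Chi-squared test (no continuity correction) of two proportions.

    Compares k1/n1 against k2/n2 via the 2x2 table of counts; symmetric in
    the two samples.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= k <= n:
            raise ValueError("count k must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        return 1.0  # both proportions 0 or both 1: no difference testable
    res = scipy.stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


@dataclass(frozen=True)
class RegressionSlope:
    """Trial-slope difference between two sessions from a linear model."""

    beta: float  # interaction slope (second session minus first)
    se: float
    p: float
    slopes: dict  # per-session trial slopes


def di_slope_regression(df: pd.DataFrame, value: str = "di", trial: str = "trial",
                        session: str = "session") -> RegressionSlope:
    """Linear model ``DI ~ trial * session``; returns the interaction slope.

    ``beta`` is the difference between the per-trial slopes of the second
    and first session levels (sorted order), with its standard error and
    p-value.  Needs at least 3 trials per session.
    """
    data = df[[value, trial, session]].dropna()
    levels = sorted(data[session].unique())
    if len(levels) != 2:
        raise ValueError("di_slope_regression expects exactly 2 session levels")
    for lev in levels:
        if data.loc[data[session] == lev, trial].nunique() < 3:
            raise ValueError(f"session {lev!r} has fewer than 3 trials")
    data = data.copy()
    data["_is_second"] = (data[session] == levels[1]).astype(float)
    X = sm.add_constant(
        np.column_stack([
            data[trial].to_numpy(float),
            data["_is_second"].to_numpy(),
            data[trial].to_numpy(float) * data["_is_second"].to_numpy(),
        ])
    )
    fit = sm.OLS(data[value].to_numpy(float), X).fit()
    beta = float(fit.params[3])
    slope_first = float(fit.params[1])
    return RegressionSlope(
        beta=beta, se=float(fit.bse[3]), p=float(fit.pvalues[3]),
        slopes={levels[0]: slope_first, levels[1]: slope_first + beta},
    )
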