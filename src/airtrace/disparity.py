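"""Group disparity statistics and the hierarchical exposure regression.

Group distribution summaries (means with t-based 95 % CIs, percentiles),
one-way ANOVA with Games-Howell post hoc pairwise testing (which does not
assume equal variances or sample sizes), paired t tests, and a hierarchical
stepwise OLS of activity-based exposure concentration on sociodemographic,
urbanicity, and activity-time predictors, entered in fixed blocks with
per-block backward elimination at p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "RegressionResult",
    "DegenerateInputError",
    "CollinearityError",
    "group_summary",
    "one_way_anova",
    "games_howell",
    "paired_t",
    "hierarchical_stepwise_ols",
    "add_interactions",
]


class DegenerateInputError(ValueError):
    """Input has no variability where the statistic requires some."""


class CollinearityError(ValueError):
    """The regression design matrix is rank-deficient."""


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    ci_lo: float
    ci_hi: float
    minimum: float
    maximum: float
    percentiles: dict[int, float]   # keys 5, 25, 50, 75, 95


@dataclass(frozen=True)
class PairwiseComparison:
    group_i: str
    group_j: str
    mean_difference: float   # mean_i − mean_j
    statistic: float         # studentized-range statistic q*
    df: float                # Welch-Satterthwaite, used unrounded
    p_value: float
    significant: bool        # at α = 0.05


@dataclass
class RegressionResult:
    """Final stepwise OLS fit: retained coefficients and fit statistics."""

    params: pd.Series        # includes the intercept as "const"
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    n: int
    retained: list[str]
    dropped: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.params, "t": self.tvalues, "p": self.pvalues}
        )


def group_summary(values, labels) -> dict[str, GroupSummary]:
    """Distribution summary per group: mean, t-based 95 % CI, percentiles.

    Percentiles use linear interpolation.  A single-observation group gets a
    degenerate CI equal to its mean; empty groups are skipped.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    out: dict[str, GroupSummary] = {}
    for lab in pd.unique(labels):
        v = values[labels == lab]
        if v.size == 0:
            continue
        mean = float(v.mean())
        if v.size >= 2:
            sem = v.std(ddof=1) / math.sqrt(v.size)
            half = stats.t.ppf(0.975, v.size - 1) * sem
        else:
            half = 0.0
        pcts = np.percentile(v, [5, 25, 50, 75, 95])
        out[str(lab)] = GroupSummary(
            label=str(lab),
            n=int(v.size),
            mean=mean,
            ci_lo=mean - half,
            ci_hi=mean + half,
            minimum=float(v.min()),
            maximum=float(v.max()),
            percentiles=dict(zip((5, 25, 50, 75, 95), map(float, pcts))),
        )
    return out


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    if all(np.var(g) == 0 for g in groups) and np.var(np.concatenate(groups)) == 0:
        raise DegenerateInputError("all values identical; F undefined")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return float(f), k - 1, n - k, float(p)


def _welch_df(s2_i, n_i, s2_j, n_j) -> float:
    num = (s2_i / n_i + s2_j / n_j) ** 2
    den = (s2_i / n_i) ** 2 / (n_i - 1) + (s2_j / n_j) ** 2 / (n_j - 1)
    return num / den


def games_howell(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> list[PairwiseComparison]:
    """Games-Howell post hoc pairwise comparisons.

    For each pair: standard error √(s_i²/n_i + s_j²/n_j), statistic
    q* = |Δmean|·√2 / se, Welch-Satterthwaite degrees of freedom (unrounded),
    and p from the upper tail of the studentized range distribution with k
    groups.  Suitable for unequal variances and group sizes; with k = 2 it
    reduces to the Welch two-sample t test.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    data = {n: np.asarray(groups[n], dtype=float) for n in names}
    for n, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {n!r} needs at least 2 values")
        if v.var(ddof=1) == 0:
            raise DegenerateInputError(f"group {n!r} has zero variance")
    k = len(names)
    out = []
    for gi, gj in itertools.combinations(names, 2):
        vi, vj = data[gi], data[gj]
        s2_i, s2_j = vi.var(ddof=1), vj.var(ddof=1)
        n_i, n_j = vi.size, vj.size
        se = math.sqrt(s2_i / n_i + s2_j / n_j)
        diff = float(vi.mean() - vj.mean())
        q = abs(diff) * math.sqrt(2.0) / se
        df = _welch_df(s2_i, n_i, s2_j, n_j)
        p = float(stats.studentized_range.sf(q, k, df))
        out.append(
            PairwiseComparison(gi, gj, diff, q, df, p, p < alpha)
        )
    return out


def paired_t(sample_a, sample_b) -> tuple[float, int, float]:
    """Paired-sample t test on the differences a − b; returns (t, df, p).

    Degenerate zero-variance differences are handled explicitly: all-zero
    differences give (0, df, 1); a constant nonzero difference is an exact
    shift, reported as (±inf, df, 0).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("samples must have equal length n >= 2")
    d = a - b
    df = a.size - 1
    if d.std(ddof=1) == 0:
        if d[0] == 0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, d[0]), df, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), df, float(p)


def add_interactions(
    design: pd.DataFrame, terms: list[tuple[str, str]]
) -> pd.DataFrame:
    """Append elementwise-product interaction columns named ``"a×b"``."""
    out = design.copy()
    for a, b in terms:
        for col in (a, b):
            if col not in design.columns:
                raise KeyError(f"unknown design column {col!r}")
        out[f"{a}×{b}"] = design[a] * design[b]
    return out


def hierarchical_stepwise_ols(
    design: pd.DataFrame,
    response,
    blocks: list[list[str]],
    alpha: float = 0.05,
) -> RegressionResult:
    """Blockwise-hierarchical stepwise OLS with backward elimination.

    Predictor blocks are entered in the given order (sociodemographics, then
    income, then urbanicity, then the continuous activity-time variable, for
    the exposure model).  Within each block, the fit includes all previously
    retained predictors plus the block's candidates; the candidate with the
    largest p ≥ ``alpha`` is dropped and the model refit, one predictor at a
    time, until every current-block candidate is significant.  Predictors
    retained in earlier blocks are never re-dropped.  Binary predictors are
    coded 0/1 against their reference category, so the intercept is the mean
    for the joint reference profile.
    """
    y = np.asarray(response, dtype=float)
    for block in blocks:
        for col in block:
            if col not in design.columns:
                raise KeyError(f"unknown design column {col!r}")
    retained: list[str] = []
    dropped: list[str] = []
    fit = None
    for block in blocks:
        current = list(block)
        while True:
            fit = _fit_ols(design, y, retained + current)
            if not current:
                break
            p_block = fit.pvalues[current]
            worst = p_block.idxmax()
            if p_block[worst] >= alpha:
                current.remove(worst)
                dropped.append(worst)
            else:
                break
        retained.extend(current)
    fit = _fit_ols(design, y, retained)
    return RegressionResult(
        params=fit.params,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        n=int(fit.nobs),
        retained=retained,
        dropped=dropped,
    )


def _fit_ols(design: pd.DataFrame, y: np.ndarray, cols: list[str]):
    X = sm.add_constant(design[cols].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        offenders = _collinear_columns(X)
        raise CollinearityError(
            f"design is rank-deficient; suspect columns: {offenders}"
        )
    return sm.OLS(y, X).fit()


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    cols = [c for c in X.columns if c != "const"]
    offenders = []
    for c in cols:
        others = [o for o in X.columns if o != c]
        sub = X[others].to_numpy()
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X.to_numpy()):
            offenders.append(c)
    return offenders
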