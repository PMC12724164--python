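"""Effect-size statistics: Type-III ANOVA/ANCOVA with partial eta squared,
Cohen's d, group slopes and slope differences, stratified bootstrap
confidence intervals, the meaningful-effect decision rule, and unsmoothed
empirical probability mass functions (epmf) with asymmetric MAD error bars.

With thousands of dendrites per group, p-values are uninformative (tiny
effects reach arbitrary significance), so decisions rest on effect sizes:
partial eta squared

    eta_p^2 = SS_effect / (SS_effect + SS_error)

with >= 0.01 / 0.06 / 0.14 read as small / medium / large, and Cohen's d

    d = (mu_i - mu_j) / s_pooled,   s_pooled = sqrt((sd_i^2 + sd_j^2) / 2)

for post hoc pairwise contrasts.  An effect is *meaningful* only when the
point estimate and its entire bootstrap confidence interval clear the small
threshold.  Type-III sums of squares require sum-to-zero contrasts, which
the model builder enforces.  p-values are computed but never drive any
decision, and no multiplicity correction is applied: the decision rule is
the effect-size/CI threshold, not significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "EffectReport",
    "PairwiseEffect",
    "EPMF",
    "SMALL",
    "MEDIUM",
    "LARGE",
    "anova_type3",
    "ancova_slopes",
    "cohens_d",
    "bootstrap_ci",
    "meaningful",
    "asymmetric_mad",
    "epmf",
]

SMALL, MEDIUM, LARGE = 0.01, 0.06, 0.14  # partial eta squared benchmarks
D_SMALL = 0.2  # Cohen's d benchmark


@dataclass
class EffectReport:
    term: str
    ss_effect: float
    ss_error: float
    eta_p2: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    slope: float = np.nan
    p_value: float = np.nan
    meaningful: bool | None = None


@dataclass
class PairwiseEffect:
    group_i: object
    group_j: object
    cohens_d: float
    pooled_sd: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    meaningful: bool | None = None


@dataclass
class EPMF:
    group: object
    edges: np.ndarray
    mass: np.ndarray
    err_low: np.ndarray
    err_high: np.ndarray
    mode: str
    bin_median: np.ndarray | None = None


# -- bootstrap -------------------------------------------------------------


def _strata_indices(strata: np.ndarray):
    return {s: np.where(strata == s)[0] for s in pd.unique(strata)}


def bootstrap_ci(statistic, data: pd.DataFrame, strata=None, reps: int = 1000,
                 seed=0, level: float = 0.95):
    """Percentile bootstrap CI of ``statistic(resampled_frame)``.

    Resampling is with replacement *within* each stratum so the group sizes
    of the design are preserved.  Strata of size 1 contribute themselves with
    a warning.  Deterministic under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(data)
    if strata is None:
        groups = {None: np.arange(n)}
    else:
        arr = data[strata].astype(str).agg("|".join, axis=1).to_numpy() if isinstance(
            strata, (list, tuple)
        ) else np.asarray(data[strata] if isinstance(strata, str) else strata)
        groups = _strata_indices(arr)
    for s, idx in groups.items():
        if len(idx) == 1:
            warnings.warn(f"stratum {s!r} has a single row; resampled as-is")
    vals = np.empty(reps)
    for r in range(reps):
        take = np.concatenate(
            [idx[rng.integers(0, len(idx), len(idx))] for idx in groups.values()]
        )
        vals[r] = statistic(data.iloc[take])
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(vals, alpha)), float(np.quantile(vals, 1.0 - alpha))


def meaningful(point: float, ci_low: float, ci_high: float,
               threshold: float = SMALL, signed: bool = False) -> bool:
    """True iff the point AND its whole CI clear the threshold.

    For signed statistics (Cohen's d) the rule applies to the magnitude with
    a sign-consistent interval: a positive effect needs ci_low >= threshold,
    a negative one ci_high <= -threshold.
    """
    if signed:
        if point >= 0:
            return bool(point >= threshold and ci_low >= threshold)
        return bool(-point >= threshold and ci_high <= -threshold)
    return bool(point >= threshold and ci_low >= threshold)


# -- ANOVA / ANCOVA --------------------------------------------------------


def _model_formula(response, factors, covariates):
    parts = [f"C({f}, Sum)" for f in factors]
    fact = " * ".join(parts) if parts else "1"
    terms = [fact]
    for cov in covariates or []:
        terms.append(cov)
        for f in factors:
            terms.append(f"C({f}, Sum):{cov}")
    return f"{response} ~ " + " + ".join(terms)


def _eta_table(fitted):
    aov = sm.stats.anova_lm(fitted, typ=3)
    ss_error = float(aov.loc["Residual", "sum_sq"])
    out = {}
    for term in aov.index:
        if term in ("Intercept", "Residual"):
            continue
        ss = float(aov.loc[term, "sum_sq"])
        denom = ss + ss_error
        # a constant response has no variance to attribute anywhere
        eta = ss / denom if denom > 1e-10 else 0.0
        out[term] = (ss, ss_error, eta, float(aov.loc[term, "PR(>F)"]))
    return out


def anova_type3(
    data: pd.DataFrame,
    response: str,
    factors=("type", "subtype"),
    covariates=None,
    reps: int = 1000,
    seed=0,
    threshold: float = SMALL,
) -> list[EffectReport]:
    """Full-factorial Type-III ANOVA/ANCOVA with partial eta squared.

    Factors are sum-to-zero coded (required for order-invariant Type-III
    sums of squares).  Each term gets a stratified-bootstrap CI on eta_p^2
    (``reps`` resamples, strata = factor cells) and the meaningful flag.
    Raises on empty factorial cells.
    """
    factors = [f for f in factors if data[f].nunique() > 1]
    if len(factors) > 1:
        full = pd.MultiIndex.from_product(
            [sorted(data[f].unique()) for f in factors], names=list(factors)
        )
        cells = (
            data.groupby(list(factors)).size().reindex(full, fill_value=0)
        )
        empty = cells[cells == 0]
        if len(empty):
            raise ValueError(f"empty factorial cells: {list(empty.index)}")
    formula = _model_formula(response, factors, covariates)
    fitted = smf.ols(formula, data=data).fit()
    base = _eta_table(fitted)

    cis = {t: (np.nan, np.nan) for t in base}
    if reps and reps > 0:
        rng = np.random.default_rng(seed)
        samples = {t: [] for t in base}
        for _ in range(reps):
            take = _stratified_take(data, factors, rng)
            try:
                tab = _eta_table(smf.ols(formula, data=data.iloc[take]).fit())
            except Exception:
                continue
            for t in samples:
                if t in tab:
                    samples[t].append(tab[t][2])
        for t, vals in samples.items():
            if vals:
                cis[t] = (float(np.quantile(vals, 0.025)),
                          float(np.quantile(vals, 0.975)))

    slopes = {}
    for cov in covariates or []:
        if cov in fitted.params.index:
            slopes[cov] = float(fitted.params[cov])
    reports = []
    for term, (ss, sse, eta, p) in base.items():
        lo, hi = cis[term]
        reports.append(
            EffectReport(
                term=term,
                ss_effect=ss,
                ss_error=sse,
                eta_p2=eta,
                ci_low=lo,
                ci_high=hi,
                slope=slopes.get(term, np.nan),
                p_value=p,
                meaningful=meaningful(eta, lo, hi, threshold)
                if np.isfinite(lo)
                else None,
            )
        )
    return reports


def _stratified_take(data, factors, rng):
    if not factors:
        return rng.integers(0, len(data), len(data))
    strata = data.groupby(list(factors), observed=True).indices
    return np.concatenate(
        [idx[rng.integers(0, len(idx), len(idx))] for idx in strata.values()]
    )


def ancova_slopes(
    data: pd.DataFrame,
    response: str,
    covariate: str,
    group: str,
    reps: int = 1000,
    seed=0,
):
    """Per-group regression slopes and their pairwise differences.

    Fits ``response ~ C(group) + C(group):covariate`` so each group's slope
    is read directly off the interaction coefficients.  Returns
    ``(slopes, deltas)``: a Series of slopes per group level and a DataFrame
    of pairwise differences ``delta = beta_i - beta_j`` with stratified
    bootstrap CIs.
    """
    levels = sorted(data[group].unique())
    for lev in levels:
        grp = data[data[group] == lev]
        if len(grp) < 10:
            raise ValueError(f"group {lev!r} has fewer than 10 points")
        if np.isclose(grp[covariate].var(), 0):
            raise ValueError(f"covariate is constant within group {lev!r}")
    formula = f"{response} ~ C({group}) + C({group}):{covariate}"

    def _slopes(frame):
        fitted = smf.ols(formula, data=frame).fit()
        return {
            lev: float(fitted.params[f"C({group})[{lev}]:{covariate}"])
            for lev in levels
        }

    point = _slopes(data)
    slopes = pd.Series(point, name="slope")
    rows = []
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(reps if reps else 0):
        take = _stratified_take(data, [group], rng)
        boot.append(_slopes(data.iloc[take]))
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            delta = point[gi] - point[gj]
            if boot:
                dd = np.array([b[gi] - b[gj] for b in boot])
                lo, hi = float(np.quantile(dd, 0.025)), float(np.quantile(dd, 0.975))
            else:
                lo = hi = np.nan
            rows.append(
                {"group_i": gi, "group_j": gj, "delta_beta": delta,
                 "ci_low": lo, "ci_high": hi}
            )
    return slopes, pd.DataFrame(rows)


# -- pairwise effects ------------------------------------------------------


def cohens_d(group_i, group_j, reps: int = 1000, seed=0,
             labels=("i", "j"), threshold: float = D_SMALL) -> PairwiseEffect:
    """Signed Cohen's d with a stratified-bootstrap percentile CI."""
    x = np.asarray(group_i, dtype=float)
    y = np.asarray(group_j, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")

    sp = float(np.sqrt((x.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2.0))
    if sp == 0:
        raise ValueError("zero pooled standard deviation")
    d = (x.mean() - y.mean()) / sp
    lo = hi = np.nan
    if reps:
        rng = np.random.default_rng(seed)
        xi = rng.integers(0, len(x), size=(reps, len(x)))
        yi = rng.integers(0, len(y), size=(reps, len(y)))
        xs, ys = x[xi], y[yi]
        sps = np.sqrt((xs.std(ddof=1, axis=1) ** 2 + ys.std(ddof=1, axis=1) ** 2) / 2)
        ds = (xs.mean(axis=1) - ys.mean(axis=1)) / sps
        lo, hi = float(np.quantile(ds, 0.025)), float(np.quantile(ds, 0.975))
    return PairwiseEffect(
        labels[0], labels[1], float(d), float(sp), lo, hi,
        meaningful(d, lo, hi, threshold, signed=True) if np.isfinite(lo) else None,
    )


# -- epmf ------------------------------------------------------------------


def asymmetric_mad(values):
    """(MAD_low, MAD_high): median absolute deviation below/above the median.

    Empty sides give 0 (no spread observable on that side).
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    below = np.abs(x[x < med] - med)
    above = np.abs(x[x > med] - med)
    lo = float(np.median(below)) if len(below) else 0.0
    hi = float(np.median(above)) if len(above) else 0.0
    return lo, hi


def epmf(samples_by_group: dict, bins, error_mode: str = "bootstrap_ci",
         per_dendrite: bool = False, reps: int = 1000, seed=0) -> list[EPMF]:
    """Unsmoothed empirical probability mass functions on shared bin edges.

    Pooled mode (``per_dendrite=False``): one epmf per group with a
    bootstrap CI per bin.  Per-dendrite mode: each group's samples are a
    sequence of per-dendrite arrays; the reported mass is the mean of the
    per-dendrite epmfs (sums to 1) and the error bars are the asymmetric MAD
    of the per-dendrite bin masses around the per-bin median.
    """
    edges = np.asarray(bins, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for grp, vals in samples_by_group.items():
        if per_dendrite:
            per = []
            for arr in vals:
                arr = np.asarray(arr, dtype=float)
                if len(arr) == 0:
                    continue
                h, _ = np.histogram(arr, bins=edges)
                per.append(h / len(arr))
            if not per:
                raise ValueError(f"group {grp!r} is empty")
            per = np.array(per)
            med = np.median(per, axis=0)
            lo = np.empty(per.shape[1])
            hi = np.empty(per.shape[1])
            for b in range(per.shape[1]):
                lo[b], hi[b] = asymmetric_mad(per[:, b])
            out.append(EPMF(grp, edges, per.mean(axis=0), lo, hi,
                            "asymmetric_mad", bin_median=med))
        else:
            arr = np.asarray(vals, dtype=float)
            if len(arr) == 0:
                raise ValueError(f"group {grp!r} is empty")
            h, _ = np.histogram(arr, bins=edges)
            mass = h / len(arr)
            idx = rng.integers(0, len(arr), size=(reps, len(arr)))
            boot = np.stack(
                [np.histogram(arr[i], bins=edges)[0] / len(arr) for i in idx]
            )
            out.append(EPMF(grp, edges, mass,
                            np.quantile(boot, 0.025, axis=0),
                            np.quantile(boot, 0.975, axis=0),
                            "bootstrap_ci"))
    return out
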