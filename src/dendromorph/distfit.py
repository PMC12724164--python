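"""Maximum-likelihood fitting and BIC selection of right-skewed families.

Section-length samples are compared across six candidate families — Wald
(inverse Gaussian), log-normal, gamma, exponential, log-logistic and minimum
Weibull — all fitted as 2-parameter (1 for exponential) positive-support
forms with no location shift.  Closed-form MLEs are used where they exist
(exponential, log-normal, Wald); gamma, log-logistic and Weibull are fitted
numerically with the location pinned at zero.  Models are ranked by

    BIC = k * ln(n) - 2 * l(theta_hat)

with k the number of free parameters; lower is better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DistributionFit", "FAMILIES", "fit", "select", "group_select"]

FAMILIES = ("wald", "lognormal", "gamma", "exponential", "loglogistic", "weibull_min")


@dataclass
class DistributionFit:
    family: str
    params: dict
    loglik: float
    k_params: int
    n: int
    bic: float

    def logpdf(self, x):
        return _LOGPDF[self.family](np.asarray(x, dtype=float), self.params)


def _wald_logpdf(x, p):
    return stats.invgauss.logpdf(x, p["mu"] / p["lam"], scale=p["lam"])


_LOGPDF = {
    "wald": _wald_logpdf,
    "lognormal": lambda x, p: stats.lognorm.logpdf(x, p["sigma"], scale=np.exp(p["mu"])),
    "gamma": lambda x, p: stats.gamma.logpdf(x, p["k"], scale=p["theta"]),
    "exponential": lambda x, p: stats.expon.logpdf(x, scale=p["theta"]),
    "loglogistic": lambda x, p: stats.fisk.logpdf(x, p["c"], scale=p["s"]),
    "weibull_min": lambda x, p: stats.weibull_min.logpdf(x, p["c"], scale=p["lam"]),
}


def _fit_params(family: str, x: np.ndarray) -> dict:
    if family == "exponential":
        return {"theta": float(x.mean())}
    if family == "lognormal":
        lx = np.log(x)
        return {"mu": float(lx.mean()), "sigma": float(lx.std(ddof=0))}
    if family == "wald":
        mu = float(x.mean())
        lam = float(len(x) / np.sum(1.0 / x - 1.0 / mu))
        return {"mu": mu, "lam": lam}
    if family == "gamma":
        k, _, theta = stats.gamma.fit(x, floc=0)
        return {"k": float(k), "theta": float(theta)}
    if family == "loglogistic":
        c, _, s = stats.fisk.fit(x, floc=0)
        return {"c": float(c), "s": float(s)}
    if family == "weibull_min":
        c, _, lam = stats.weibull_min.fit(x, floc=0)
        return {"c": float(c), "lam": float(lam)}
    raise ValueError(f"unknown family {family!r}")


def fit(family: str, sample) -> DistributionFit:
    """MLE fit of one family to a strictly positive sample (n >= 10)."""
    x = np.asarray(sample, dtype=float)
    if np.any(x <= 0):
        raise ValueError("sample must be strictly positive")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    params = _fit_params(family, x)
    for name, v in params.items():
        sign_free = family == "lognormal" and name == "mu"
        if not np.isfinite(v) or (not sign_free and v <= 0):
            raise FloatingPointError(
                f"{family} fit did not converge to valid parameters ({name}={v})"
            )
    loglik = float(_LOGPDF[family](x, params).sum())
    if not np.isfinite(loglik):
        raise FloatingPointError(f"{family} log-likelihood not finite")
    k = 1 if family == "exponential" else 2
    bic = k * np.log(len(x)) - 2.0 * loglik
    return DistributionFit(family, params, loglik, k, len(x), float(bic))


def select(sample, families=FAMILIES):
    """Fit all families and rank ascending by BIC.

    Non-converging fits are excluded with a warning.  BIC ties within 1e-6
    break toward fewer parameters.  Returns the ranked list; element 0 is
    the winner.
    """
    fits = []
    for fam in families:
        try:
            fits.append(fit(fam, sample))
        except (FloatingPointError, ValueError) as exc:
            warnings.warn(f"{fam} fit excluded: {exc}")
    if len(fits) < 1:
        raise ValueError("all fits failed")
    fits.sort(key=lambda f: (round(f.bic / 1e-6) * 1e-6, f.k_params))
    return fits


def group_select(
    sections: pd.DataFrame,
    value: str = "length",
    grouping=("type", "subtype", "kind", "scaling"),
    min_n: int = 50,
    families=FAMILIES,
) -> pd.DataFrame:
    """Winning family per (type, subtype, section-kind, scaling) group.

    Groups with fewer than ``min_n`` observations are skipped with a
    warning.  The output carries the winner, its parameters and the BIC gap
    to the runner-up; a ``consistent`` flag per (kind, scaling) stratum marks
    strata where every group agrees on the family.
    """
    grouping = [g for g in grouping if g in sections.columns]
    rows = []
    for key, grp in sections.groupby(list(grouping), observed=True):
        x = grp[value].to_numpy()
        x = x[np.isfinite(x) & (x > 0)]
        if len(x) < min_n:
            warnings.warn(f"group {key}: only {len(x)} observations, skipped")
            continue
        ranked = select(x, families=families)
        row = dict(zip(grouping, key if isinstance(key, tuple) else (key,)))
        row.update(
            family=ranked[0].family,
            params=ranked[0].params,
            loglik=ranked[0].loglik,
            bic=ranked[0].bic,
            delta_bic_runner_up=(
                ranked[1].bic - ranked[0].bic if len(ranked) > 1 else np.nan
            ),
            n=ranked[0].n,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        strata = [g for g in ("kind", "scaling") if g in out.columns]
        if strata:
            out["consistent"] = out.groupby(strata)["family"].transform(
                lambda s: s.nunique() == 1
            )
    return out
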