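"""Group-difference inference: Welch t, JZS Bayes factors, HDI/pd, correlations.

The Bayesian t-test follows the default-prior (JZS) formulation: a Cauchy
prior with scale r on the standardised effect size, integrated out via the
equivalent inverse-gamma mixture on g.  BF01 > 1 favours the null.  Posterior
group differences use the narrowest-interval HDI and the probability of
direction pd = max(P(diff > 0), P(diff < 0)); a difference is flagged
credible iff the 95% HDI excludes zero.  Direction convention throughout:
non-anhedonic minus anhedonic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .hierfit import PosteriorFit

__all__ = [
    "ComparisonResult",
    "welch_t_test",
    "jzs_bf01",
    "jzs_bf10",
    "hdi",
    "prob_direction",
    "group_difference_report",
    "correlation_table",
]

DEFAULT_RSCALE = math.sqrt(2) / 2


@dataclass(frozen=True)
class ComparisonResult:
    """One parameter's group comparison (non-anhedonic minus anhedonic)."""

    parameter: str
    welch_t: float
    df: float
    p: float
    bf01: float
    hdi_low: float
    hdi_high: float
    pd: float
    credible: bool


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Unequal-variance t-test with Welch-Satterthwaite df; two-sided p.

    Returns (t, df, p) for sample_a vs sample_b (positive t means a > b).
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples constant: variance undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def jzs_bf10(t: float, n1: int, n2: int, rscale: float = DEFAULT_RSCALE) -> float:
    """JZS two-sample Bayes factor for the alternative, from sufficient stats.

    Integrates the g-prior mixture (g ~ InvGamma(1/2, rscale^2/2), the
    Cauchy(0, rscale) prior on effect size) by adaptive quadrature:

        BF10 = int (1+Ng)^(-1/2) (1 + t^2/((1+Ng) nu))^(-(nu+1)/2) pi(g) dg
               / (1 + t^2/nu)^(-(nu+1)/2)

    with nu = n1+n2-2 and effective sample size N = n1*n2/(n1+n2).
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    nu = n1 + n2 - 2
    N = n1 * n2 / (n1 + n2)
    r2 = rscale**2

    def integrand(g):
        prior = (r2 / 2) ** 0.5 / math.gamma(0.5) * g**-1.5 * math.exp(-r2 / (2 * g))
        return (1 + N * g) ** -0.5 * (1 + t**2 / ((1 + N * g) * nu)) ** (-(nu + 1) / 2) * prior

    num, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    den = (1 + t**2 / nu) ** (-(nu + 1) / 2)
    return num / den


def jzs_bf01(t: float, n1: int, n2: int, rscale: float = DEFAULT_RSCALE) -> float:
    """Evidence for the null: BF01 = 1 / BF10."""
    return 1.0 / jzs_bf10(t, n1, n2, rscale)


def hdi(draws, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``ceil(mass * n)`` draws."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for an HDI")
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + k - 1])


def prob_direction(draws) -> float:
    """pd = max(P(draw > 0), P(draw < 0)); lies in [0.5, 1] up to ties at 0."""
    x = np.asarray(draws, float)
    if len(x) < 100:
        raise ValueError("need at least 100 draws")
    return float(max(np.mean(x > 0), np.mean(x < 0)))


def group_difference_report(
    fit_anhedonic: PosteriorFit, fit_non_anhedonic: PosteriorFit, mass: float = 0.95
) -> list[ComparisonResult]:
    """Per-parameter group comparison from two per-group hierarchical fits.

    The Bayesian part contrasts the group-level posterior means on the
    natural scale (difference = non-anhedonic - anhedonic, draws paired by
    index after trimming to equal length); the frequentist/BF part applies a
    Welch t-test and JZS Bayes factor to the subject-level posterior means.
    """
    fa, fb = fit_anhedonic, fit_non_anhedonic
    if fa.model.name != fb.model.name:
        raise ValueError("fits use different models")
    sub_a = fa.posterior_mean_subject_values()
    sub_b = fb.posterior_mean_subject_values()
    out = []
    for k, sym in enumerate(fa.param_names):
        da = fa.group_mean_draws(sym)
        db = fb.group_mean_draws(sym)
        m = min(len(da), len(db))
        diff = db[:m] - da[:m]
        lo, hi = hdi(diff, mass)
        pd_ = prob_direction(diff)
        t, df, p = welch_t_test(sub_b[:, k], sub_a[:, k])
        bf01 = jzs_bf01(t, sub_b.shape[0], sub_a.shape[0])
        out.append(
            ComparisonResult(
                parameter=sym,
                welch_t=t,
                df=df,
                p=p,
                bf01=bf01,
                hdi_low=lo,
                hdi_high=hi,
                pd=pd_,
                credible=not (lo <= 0.0 <= hi),
            )
        )
    return out


def correlation_table(
    x: pd.DataFrame, y: pd.DataFrame, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Pearson correlations of every x-column against every y-column.

    Uses pairwise-complete observations; p-values are two-sided and the
    Bonferroni adjustment multiplies by the full number of pairs in the table
    (capped at 1).  Returns columns {x, y, n, r, p_raw, p_adj}.
    """
    if correction != "bonferroni":
        raise ValueError("only Bonferroni correction is implemented")
    rows = []
    m = len(x.columns) * len(y.columns)
    for cx in x.columns:
        for cy in y.columns:
            xv = pd.to_numeric(x[cx], errors="coerce")
            yv = pd.to_numeric(y[cy], errors="coerce")
            ok = xv.notna() & yv.notna()
            if ok.sum() < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({cx}, {cy})")
            r, p = stats.pearsonr(xv[ok], yv[ok])
            rows.append(
                {
                    "x": cx,
                    "y": cy,
                    "n": int(ok.sum()),
                    "r": float(r),
                    "p_raw": float(p),
                    "p_adj": float(min(1.0, p * m)),
                }
            )
    return pd.DataFrame(rows)
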