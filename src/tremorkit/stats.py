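"""Method-comparison statistics: correlation/agreement, Bland-Altman,
TOST equivalence, paired contrasts with rank-biserial effect sizes,
post-hoc power for correlations, and ROUT robust outlier removal.

These are the tools used to validate a new tremor-measurement method
against a reference (e.g. video tracking against marker-based motion
capture): agreement is quantified by correlation plus Bland-Altman limits
of agreement, and *equivalence* is claimed only when the 90 % CI of the
paired differences lies entirely inside the smallest effect size of
interest (SESOI: 10 mm for amplitude, 0.5 Hz for frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as st

from .io_formats import ParameterError


@dataclass
class AgreementReport:
    """Correlation + error + Bland-Altman summary of two paired methods."""

    correlation: float
    correlation_p: float
    correlation_method: str          # "pearson" | "spearman"
    mae: float                       # mean signed error a - b, measurement units
    mae_ci95: tuple[float, float]
    bland_altman_bias: float
    loa_low: float
    loa_high: float
    proportional_bias_slope_p: float
    n: int


@dataclass
class EquivalenceResult:
    """Two one-sided tests of a paired difference against +/- SESOI."""

    mean_diff: float
    ci90: tuple[float, float]
    sesoi: float
    p_lower: float
    p_upper: float
    equivalent: bool
    degenerate: bool = False         # zero-variance differences


@dataclass
class ContrastResult:
    """Paired two-sample contrast with a standardised effect size."""

    test_name: str                   # "wilcoxon" | "paired_t"
    statistic: float
    p: float
    effect_size: float               # Cohen's d or matched rank-biserial r
    effect_ci95: tuple[float, float]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

def _normal_enough(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return True                  # constant: Shapiro is undefined, treat as fine
    return st.shapiro(x).pvalue > alpha


def agreement_report(a, b, method: str = "auto",
                     alpha: float = 0.05) -> AgreementReport:
    """Agreement of two paired measurement series.

    ``method='auto'`` uses Pearson when Shapiro-Wilk accepts normality of
    both series at ``alpha``, else Spearman.  The mean signed error
    ``mean(a - b)`` gets a t-based 95 % CI; Bland-Altman bias and 1.96-SD
    limits of agreement come from the differences against the means, and
    proportional bias is the regression slope of differences on means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired series must have equal length")
    n = len(a)
    if n < 4:
        raise ParameterError("need at least 4 pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ParameterError("non-finite values in input")

    if method == "auto":
        method = ("pearson" if _normal_enough(a, alpha) and _normal_enough(b, alpha)
                  else "spearman")
    if method == "pearson":
        r, p = st.pearsonr(a, b)
    elif method == "spearman":
        r, p = st.spearmanr(a, b)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")

    d = a - b
    m = (a + b) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    se = sd / np.sqrt(n)
    tcrit = st.t.ppf(0.975, n - 1)
    ci = (bias - tcrit * se, bias + tcrit * se)
    if np.ptp(m) > 0:
        slope_p = float(st.linregress(m, d).pvalue)
    else:
        slope_p = float("nan")
    return AgreementReport(
        correlation=float(r), correlation_p=float(p), correlation_method=method,
        mae=bias, mae_ci95=(float(ci[0]), float(ci[1])),
        bland_altman_bias=bias, loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd, proportional_bias_slope_p=slope_p, n=n)


# ---------------------------------------------------------------------------
# TOST equivalence
# ---------------------------------------------------------------------------

def tost_equivalence(diffs, sesoi: float, alpha: float = 0.05
                     ) -> EquivalenceResult:
    """Two one-sided one-sample t-tests of paired differences vs +/- SESOI.

    Equivalence is declared iff both one-sided p-values fall below ``alpha``,
    which is exactly the condition that the (1 - 2*alpha) CI (90 % at the
    default) lies inside the equivalence band.  Zero-variance differences
    are flagged degenerate: the verdict is then simply |mean| < sesoi.
    """
    d = np.asarray(diffs, dtype=float)
    if sesoi <= 0:
        raise ParameterError("sesoi must be > 0")
    n = len(d)
    if n < 3:
        raise ParameterError("need at least 3 differences")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        inside = abs(mean) < sesoi
        return EquivalenceResult(mean_diff=mean, ci90=(mean, mean), sesoi=sesoi,
                                 p_lower=0.0 if inside else 1.0,
                                 p_upper=0.0 if inside else 1.0,
                                 equivalent=inside, degenerate=True)
    se = sd / np.sqrt(n)
    df = n - 1
    t_lower = (mean + sesoi) / se          # H0: mean <= -sesoi
    t_upper = (mean - sesoi) / se          # H0: mean >= +sesoi
    p_lower = float(st.t.sf(t_lower, df))
    p_upper = float(st.t.cdf(t_upper, df))
    tcrit = st.t.ppf(1 - alpha, df)
    ci90 = (mean - tcrit * se, mean + tcrit * se)
    equivalent = max(p_lower, p_upper) < alpha
    return EquivalenceResult(mean_diff=mean, ci90=(float(ci90[0]), float(ci90[1])),
                             sesoi=sesoi, p_lower=p_lower, p_upper=p_upper,
                             equivalent=equivalent)


# ---------------------------------------------------------------------------
# paired contrasts
# ---------------------------------------------------------------------------

def matched_rank_biserial(x, y) -> float:
    """Matched rank-biserial correlation of paired samples.

    Signed ranks of the non-zero differences ``y - x``:
    ``r = (sum of positive ranks - sum of negative ranks) / total``.
    """
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        return float("nan")
    ranks = st.rankdata(np.abs(d))
    pos = ranks[d > 0].sum()
    neg = ranks[d < 0].sum()
    return float((pos - neg) / (pos + neg))


def paired_contrast(x, y, method: str = "auto",
                    alpha: float = 0.05) -> ContrastResult:
    """Paired contrast of two conditions (e.g. DBS OFF vs ON).

    ``auto`` picks the paired t-test when the differences pass Shapiro-Wilk
    at ``alpha``, else the Wilcoxon signed-rank test with the matched
    rank-biserial correlation as effect size.  Effect-size CIs use normal
    approximations (noncentral-free, documented in the methods note).
    All-zero differences are degenerate: no effect is defined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired series must have equal length")
    n = len(x)
    if n < 5:
        raise ParameterError("need at least 5 pairs")
    d = y - x
    if np.all(d == 0):
        return ContrastResult(test_name="degenerate", statistic=float("nan"),
                              p=float("nan"), effect_size=float("nan"),
                              effect_ci95=(float("nan"), float("nan")),
                              degenerate=True)
    if method == "auto":
        method = "paired_t" if _normal_enough(d, alpha) else "wilcoxon"
    if method == "paired_t":
        res = st.ttest_rel(y, x)
        dz = float(np.mean(d) / np.std(d, ddof=1))
        se = np.sqrt(1.0 / n + dz ** 2 / (2.0 * n))
        return ContrastResult(test_name="paired_t", statistic=float(res.statistic),
                              p=float(res.pvalue), effect_size=dz,
                              effect_ci95=(dz - 1.96 * se, dz + 1.96 * se))
    if method == "wilcoxon":
        nz = d[d != 0]
        res = st.wilcoxon(nz)
        r = matched_rank_biserial(x, y)
        m = len(nz)
        total = m * (m + 1) / 2.0
        se_w = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
        se_r = 2.0 * se_w / total
        ci = (max(-1.0, r - 1.96 * se_r), min(1.0, r + 1.96 * se_r))
        return ContrastResult(test_name="wilcoxon", statistic=float(res.statistic),
                              p=float(res.pvalue), effect_size=r,
                              effect_ci95=(float(ci[0]), float(ci[1])))
    raise ParameterError(f"unknown contrast method {method!r}")


# ---------------------------------------------------------------------------
# post-hoc power for correlations
# ---------------------------------------------------------------------------

def posthoc_power_correlation(rho: float, n: int, alpha: float = 0.05,
                              sided: str = "one") -> float:
    """Power of the test of zero correlation at a given true correlation.

    The critical sample correlation is exact, from the t-transform
    ``t = r * sqrt(n-2) / sqrt(1-r^2)`` with ``n-2`` df; the sampling
    distribution under the alternative uses the Fisher-z approximation with
    mean ``atanh(rho) + rho / (2*(n-1))`` and SD ``1/sqrt(n-3)``.  At
    ``rho=0`` the null and alternative coincide, so the power is exactly
    ``alpha`` (the critical value is the exact null quantile).
    """
    if not (abs(rho) < 1):
        raise ParameterError("|rho| must be < 1")
    if n < 4:
        raise ParameterError("need n >= 4")
    if sided not in ("one", "two"):
        raise ParameterError("sided must be 'one' or 'two'")
    if rho == 0:
        return float(alpha)
    df = n - 2
    tail = alpha if sided == "one" else alpha / 2
    t_crit = st.t.ppf(1 - tail, df)
    r_crit = t_crit / np.sqrt(t_crit ** 2 + df)
    mu = np.arctanh(rho) + rho / (2.0 * (n - 1))
    sd = 1.0 / np.sqrt(n - 3)
    z_hi = (np.arctanh(r_crit) - mu) / sd
    power = float(st.norm.sf(z_hi))
    if sided == "two":
        z_lo = (np.arctanh(-r_crit) - mu) / sd
        power += float(st.norm.cdf(z_lo))
    return power


# ---------------------------------------------------------------------------
# ROUT outlier removal
# ---------------------------------------------------------------------------

@dataclass
class RoutResult:
    outlier_mask: np.ndarray         # True where flagged
    slope: float
    intercept: float
    rsdr: float                      # robust SD of residuals


def rout_outliers(x, y, Q: float = 0.01, max_iter: int = 50) -> RoutResult:
    """Robust straight-line fit with FDR-controlled outlier flagging.

    The line is fitted by iteratively reweighted least squares with a
    Lorentzian loss (weights ``1/(1 + (r/RSDR)^2)``); the robust scale RSDR
    is the 68.27th percentile of |residuals| inflated by ``n/(n-2)``.
    Residual t-scores get two-tailed p-values (``n-2`` df) and points are
    flagged by the Benjamini-Hochberg step-up rule at rate ``Q``; ``Q=0``
    never flags.  The returned slope/intercept are refitted by ordinary
    least squares on the clean points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ParameterError("x and y must have equal length")
    n = len(x)
    if n < 5:
        raise ParameterError("need at least 5 points")
    if np.ptp(x) == 0:
        raise ParameterError("x is constant: rank-deficient design")
    if not (0 <= Q < 1):
        raise ParameterError("Q must be in [0, 1)")

    # IRLS with Lorentzian weights
    slope, intercept = np.polyfit(x, y, 1)
    rsdr = 1.0
    for _ in range(max_iter):
        resid = y - (slope * x + intercept)
        rsdr = np.percentile(np.abs(resid), 68.27) * n / max(n - 2, 1)
        if rsdr == 0:
            break
        w = 1.0 / (1.0 + (resid / rsdr) ** 2)
        W = np.sqrt(w)
        A = np.column_stack([x, np.ones(n)]) * W[:, None]
        new_slope, new_intercept = np.linalg.lstsq(A, y * W, rcond=None)[0]
        if (abs(new_slope - slope) < 1e-12 * max(1, abs(slope))
                and abs(new_intercept - intercept) < 1e-12 * max(1, abs(intercept))):
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept

    resid = y - (slope * x + intercept)
    mask = np.zeros(n, dtype=bool)
    if Q > 0 and rsdr > 0:
        p = 2.0 * st.t.sf(np.abs(resid) / rsdr, df=n - 2)
        order = np.argsort(p)
        thresh = Q * (np.arange(1, n + 1)) / n
        passing = np.flatnonzero(p[order] <= thresh)
        if passing.size:
            mask[order[: passing.max() + 1]] = True
    clean = ~mask
    slope, intercept = np.polyfit(x[clean], y[clean], 1)
    return RoutResult(outlier_mask=mask, slope=float(slope),
                      intercept=float(intercept), rsdr=float(rsdr))
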