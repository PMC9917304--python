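"""Statistical layer: within-subject ANOVA with Dunnett post hoc,
Friedman ANOVA, matched-pairs tests, vapor-pressure regression, and
Fisher z comparison of correlation coefficients.

The repeated-measures ANOVA reports uncorrected degrees of freedom
(df_effect = k-1, df_error = (k-1)(n-1)); a Greenhouse-Geisser option is
available but off by default.  The Dunnett many-to-one post hoc reuses
the ANOVA error mean square and evaluates adjusted p-values under the
equicorrelated (rho = 1/2) multivariate-t null by numerical quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps
from scipy.special import gammaln

from .types import AmplitudeTable, OdorPanel, ValidationError


@dataclass
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    effect_name: str = "stimulus"
    ms_error: float = float("nan")
    gg_epsilon: float | None = None


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    F: float
    df: tuple[int, int]
    p: float


def rm_anova(table: AmplitudeTable, greenhouse_geisser: bool = False) -> AnovaResult:
    """One-way repeated-measures ANOVA with stimulus as the within factor."""
    wide = table.wide().to_numpy(dtype=float)
    n, k = wide.shape
    if n < 2 or k < 2:
        raise ValidationError("RM-ANOVA needs >= 2 bees and >= 2 stimuli")
    grand = wide.mean()
    ss_subject = k * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_effect = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((wide - grand) ** 2).sum()
    # cancellation can leave a tiny negative residual when the design
    # is exactly additive
    ss_error = max(ss_total - ss_subject - ss_effect, 0.0)
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error <= 0:
        f = 0.0 if ms_effect == 0 else float("inf")
    else:
        f = ms_effect / ms_error
    eps = None
    if greenhouse_geisser:
        eps = _gg_epsilon(wide)
        p = float(sps.f.sf(f, df_effect * eps, df_error * eps))
    else:
        p = float(sps.f.sf(f, df_effect, df_error))
    return AnovaResult(
        float(f), df_effect, df_error, p, "stimulus", float(ms_error), eps
    )


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from the sample covariance."""
    k = wide.shape[1]
    s = np.cov(wide, rowvar=False)
    mean_diag = np.trace(s) / k
    mean_all = s.mean()
    row_means = s.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (s**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _dunnett_cdf_max_abs(q: float, k: int, df: int) -> float:
    """P(max_j |T_j| <= q) for k balanced many-to-one comparisons.

    T_j = (Z_j - Z_0) / (sqrt(2) U) with Z iid standard normal and
    U = S/sigma distributed as chi_df/sqrt(df); the T_j are
    equicorrelated with rho = 1/2.  Evaluated by Gauss-Hermite quadrature
    over the shared control variate and adaptive quadrature over U.
    """
    if q <= 0:
        return 0.0
    gh_x, gh_w = np.polynomial.hermite.hermgauss(80)
    z = math.sqrt(2.0) * gh_x  # nodes for the standard normal integral
    wz = gh_w / math.sqrt(math.pi)

    def inner(u: float) -> float:
        a = sps.norm.cdf(z + math.sqrt(2.0) * q * u)
        b = sps.norm.cdf(z - math.sqrt(2.0) * q * u)
        return float((wz * (a - b) ** k).sum())

    log_c = math.log(2.0) + 0.5 * df * math.log(df / 2.0) - gammaln(df / 2.0)

    def integrand(u: float) -> float:
        if u <= 0:
            return 0.0
        log_pdf = log_c + (df - 1) * math.log(u) - df * u * u / 2.0
        return math.exp(log_pdf) * inner(u)

    hi = 1.0 + 8.0 / math.sqrt(max(df, 1))
    val, _ = integrate.quad(integrand, 0.0, hi, limit=200)
    tail, _ = integrate.quad(integrand, hi, np.inf, limit=200)
    return min(1.0, val + tail)


def dunnett_vs_control(
    table: AmplitudeTable, control: str
) -> pd.DataFrame:
    """Two-sided Dunnett many-to-one comparisons against a control.

    Uses the RM-ANOVA error mean square and degrees of freedom; returns a
    frame with per-stimulus mean difference, t, raw and adjusted p.
    """
    if control not in set(table.data["stimulus"]):
        raise ValidationError(f"control stimulus {control!r} not in the table")
    anova = rm_anova(table)
    wide = table.wide()
    n = wide.shape[0]
    others = [s for s in wide.columns if s != control]
    k = len(others)
    if anova.ms_error <= 0:
        raise ValidationError(
            "zero error mean square: Dunnett comparisons are undefined"
        )
    se = math.sqrt(2.0 * anova.ms_error / n)
    rows = []
    for stim in others:
        diff = float(wide[stim].mean() - wide[control].mean())
        t = diff / se
        p_raw = 2.0 * float(sps.t.sf(abs(t), anova.df_error))
        p_adj = 1.0 - _dunnett_cdf_max_abs(abs(t), k, anova.df_error)
        rows.append(
            {
                "stimulus": stim,
                "mean_difference": diff,
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": float(np.clip(p_adj, p_raw, 1.0)),
            }
        )
    return pd.DataFrame(rows)


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("paired t needs two equal-length samples, n >= 2")
    d = x - y
    if np.all(d == 0):
        return 0.0, x.size - 1, 1.0
    if d.std(ddof=1) == 0:
        raise ValidationError("differences have zero variance but nonzero mean")
    t, p = sps.ttest_rel(x, y)
    return float(t), x.size - 1, float(p)


def wilcoxon_matched(x, y) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test, two-sided.

    Zero differences are dropped; the exact null distribution is used for
    up to 25 nonzero pairs, the normal approximation above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("samples must have equal length")
    d = x - y
    n_nonzero = int(np.count_nonzero(d))
    if n_nonzero == 0:
        raise ValidationError("all paired differences are zero")
    method = "exact" if n_nonzero <= 25 else "approx"
    try:
        res = sps.wilcoxon(
            x, y, zero_method="wilcox", correction=False, method=method
        )
    except ValueError:
        # ties make the exact distribution unavailable in scipy
        res = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                           method="approx")
    return float(res.statistic), float(res.pvalue)


def matched_pairs_battery(x, y, alpha: float = 0.05) -> dict:
    """Run both the paired t and the Wilcoxon matched-pairs test.

    Which of the two is appropriate for a given contrast (e.g. pheromone
    responses vs a control) depends on normality of the differences; both
    results are reported, with a Shapiro-Wilk check at ``alpha`` deciding
    the ``preferred`` entry (t when normality is not rejected).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, df, p_t = paired_t(x, y)
    w, p_w = wilcoxon_matched(x, y)
    shapiro_p = float(sps.shapiro(x - y).pvalue)
    return {
        "t": t,
        "df": df,
        "p_t": p_t,
        "wilcoxon_statistic": w,
        "p_wilcoxon": p_w,
        "shapiro_p": shapiro_p,
        "preferred": "t" if shapiro_p >= alpha else "wilcoxon",
    }


def friedman(table: AmplitudeTable) -> tuple[float, int, float]:
    """Friedman chi-square ANOVA over stimuli; returns (chi2, df, p)."""
    wide = table.wide()
    n, k = wide.shape
    if k < 3:
        raise ValidationError("Friedman test needs at least 3 stimuli")
    cols = [wide[c].to_numpy() for c in wide.columns]
    ranks = sps.rankdata(np.column_stack(cols), axis=1)
    if np.allclose(ranks.var(axis=1), 0):
        return 0.0, k - 1, 1.0
    stat, p = sps.friedmanchisquare(*cols)
    return float(stat), k - 1, float(p)


def vp_regression(
    mean_amplitudes, vapor_pressures
) -> RegressionResult:
    """OLS of per-odorant mean amplitude on log10 vapor pressure (mmHg)."""
    y = np.asarray(mean_amplitudes, dtype=float)
    vp = np.asarray(vapor_pressures, dtype=float)
    if y.shape != vp.shape or y.size < 3:
        raise ValidationError("regression needs >= 3 odorants")
    if np.any(vp <= 0):
        raise ValidationError("vapor pressures must be positive")
    x = np.log10(vp)
    res = sps.linregress(x, y)
    n = y.size
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f = float("inf")
        p = 0.0
    else:
        f = (n - 2) * r2 / (1.0 - r2)
        p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(
        float(res.slope), float(res.intercept), r2, float(f), (1, n - 2), p
    )


def regression_amplitude_vs_vp(
    table: AmplitudeTable, panel: OdorPanel
) -> RegressionResult:
    """Vapor-pressure regression on a cohort's cross-bee mean amplitudes."""
    means = table.mean_per_stimulus()
    odorants = [s for s in panel.odorants if s.vapor_pressure]
    y = [means[s.name] for s in odorants]
    vp = [s.vapor_pressure for s in odorants]
    return vp_regression(y, vp)


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher z-test for the difference of two independent correlations."""
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValidationError("|r| must be < 1 for the Fisher z transform")
    if min(n1, n2) < 4:
        raise ValidationError("Fisher z comparison needs n >= 4 in each sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return z, p


def stats_battery(
    table: AmplitudeTable, panel: OdorPanel, control: str = "air"
) -> pd.DataFrame:
    """The full test battery on one amplitude table, as a tidy frame."""
    rows = []
    anova = rm_anova(table)
    rows.append(
        {
            "test": "rm_anova",
            "term": "stimulus",
            "statistic": anova.F,
            "df1": anova.df_effect,
            "df2": anova.df_error,
            "p": anova.p,
        }
    )
    if control in set(table.data["stimulus"]):
        for _, row in dunnett_vs_control(table, control).iterrows():
            rows.append(
                {
                    "test": "dunnett_vs_control",
                    "term": row["stimulus"],
                    "statistic": row["t"],
                    "df1": 1,
                    "df2": anova.df_error,
                    "p": row["p_adjusted"],
                }
            )
    reg = regression_amplitude_vs_vp(table, panel)
    rows.append(
        {
            "test": "vp_regression",
            "term": f"R2={reg.r_squared:.3f}",
            "statistic": reg.F,
            "df1": reg.df[0],
            "df2": reg.df[1],
            "p": reg.p,
        }
    )
    return pd.DataFrame(rows)
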