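"""Similarity measures and inferential statistics for prime-probe designs.

The similarity of prime and probe pinches is quantified per participant and
condition in two ways: the trial-level Pearson correlation between prime and
probe values of a dependent variable (variance-stabilized with Fisher's
Z = atanh r before testing), and the mean absolute prime-probe difference.
Condition contrasts use classical two-sided paired t-tests reported with
Cohen's dz = |t|/sqrt(n) and a Jeffreys-Zellner-Siow (JZS) Bayes factor: the
alternative places a zero-centered Cauchy prior (scale 0.707 by default) on
the standardized effect size, and

    BF10 = ∫ f_nct(t; n-1, δ√n) Cauchy(δ; 0, r) dδ / f_t(t; n-1)

is evaluated by adaptive quadrature.  A noncentral-t power solver covers
prospective design (any one of n, dz, power from the other two), and a 2
(between) × 2 (within) mixed ANOVA with generalized eta squared supports
cross-experiment comparisons of prime vs probe forcefulness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats as sps

from .errors import (DataError, DegenerateDataError, InvalidParameterError,
                     NoSolutionError)

__all__ = [
    "ConditionSummary", "TestResult", "AnovaResult", "PowerSpec",
    "fisher_z", "cohens_dz", "prime_probe_summary", "paired_t", "jzs_bf10",
    "power_paired_t", "solve_power", "bonferroni_alpha", "mixed_anova_2x2",
    "dz_confint",
]


def fisher_z(r):
    """Fisher's variance-stabilizing transformation, z = atanh(r)."""
    return np.arctanh(r)


def cohens_dz(t: float, n: int) -> float:
    """Paired-design effect size dz = |t| / sqrt(n)."""
    if n < 2:
        raise InvalidParameterError("n must be at least 2")
    return abs(t) / math.sqrt(n)


@dataclass
class ConditionSummary:
    participant_id: str
    condition: str
    dv: str
    n_trials: int
    r: float
    z_r: float
    mean_abs_diff: float
    mean_prime: float
    mean_probe: float


@dataclass
class TestResult:
    label: str
    t: float
    df: int
    p: float
    dz: float
    bf10: float
    n: int
    mean_x: float
    mean_y: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnovaResult:
    effect: str         # between | within | interaction
    F: float
    df1: int
    df2: int
    p: float
    ges: float

    def to_dict(self) -> dict:
        return asdict(self)


def prime_probe_summary(trials: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Per participant × condition similarity summary for one DV.

    ``trials`` is a screened wide trial table with ``prime_<dv>`` and
    ``probe_<dv>`` columns.  Cells with fewer than 3 paired trials or zero
    variance in either part yield NaN r (warned, excluded from z-based
    tests); |r| = 1 yields infinite z_r, likewise excluded from z-based
    tests but retained for difference measures.
    """
    px, py = f"prime_{dv}", f"probe_{dv}"
    rows = []
    for (pid, cond), cell in trials.groupby(["participant_id", "condition"],
                                            observed=True):
        x = cell[px].to_numpy(dtype=float)
        y = cell[py].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        n = x.size
        r = np.nan
        if n < 3:
            warnings.warn(f"cell ({pid}, {cond}, {dv}): n={n} < 3, r undefined")
        elif np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(f"cell ({pid}, {cond}, {dv}): zero variance, r undefined")
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) > 1.0 - 1e-12:   # numerically singular cell
                r = math.copysign(1.0, r)
                warnings.warn(f"cell ({pid}, {cond}, {dv}): |r| = 1, "
                              "z_r infinite; excluded from z-based tests")
        if np.isnan(r):
            z = np.nan
        elif abs(r) >= 1.0:
            z = math.inf if r > 0 else -math.inf
        else:
            z = float(fisher_z(r))
        rows.append(ConditionSummary(
            participant_id=pid, condition=cond, dv=dv, n_trials=int(n),
            r=r, z_r=z,
            mean_abs_diff=float(np.mean(np.abs(y - x))) if n else np.nan,
            mean_prime=float(np.mean(x)) if n else np.nan,
            mean_probe=float(np.mean(y)) if n else np.nan))
    return pd.DataFrame([asdict(s) for s in rows])


def paired_t(x, y, label: str = "", cauchy_scale: float = 0.707,
             compute_bf: bool = True) -> TestResult:
    """Two-sided paired t-test with dz and JZS BF10.

    ``x`` and ``y`` are aligned participant-level vectors (pairs with a
    non-finite member are dropped).  Zero difference variance raises
    :class:`DegenerateDataError` rather than returning infinite t.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 2:
        raise DataError(f"paired t-test needs at least 2 complete pairs, got {n}")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise DegenerateDataError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    t = float(res.statistic)
    p = float(res.pvalue)
    dz = abs(t) / math.sqrt(n)
    bf = jzs_bf10(t, n, cauchy_scale) if compute_bf else np.nan
    return TestResult(label=label, t=t, df=n - 1, p=p, dz=dz, bf10=bf, n=n,
                      mean_x=float(x.mean()), mean_y=float(y.mean()))


def jzs_bf10(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """JZS Bayes factor (alternative over null) for a one-sample/paired t.

    Marginal likelihood under H1 integrates the noncentral-t density over a
    zero-centered Cauchy prior on the standardized effect size; H0 is the
    central t.  Adaptive quadrature, relative tolerance 1e-8.
    """
    if n < 2:
        raise InvalidParameterError("n must be at least 2")
    if not np.isfinite(t):
        raise InvalidParameterError("t must be finite")
    if cauchy_scale <= 0:
        raise InvalidParameterError("cauchy_scale must be positive")
    nu = n - 1
    rootn = math.sqrt(n)
    m0 = sps.t.pdf(t, nu)

    def integrand(delta):
        # nct.pdf underflows to NaN deep in the tail; the true value is ~0
        val = (sps.nct.pdf(t, nu, delta * rootn)
               * sps.cauchy.pdf(delta, loc=0.0, scale=cauchy_scale))
        return val if np.isfinite(val) else 0.0

    # split at the prior mode and the MLE so quadrature sees both peaks
    cuts = sorted({0.0, t / rootn})
    bounds = [(-np.inf, cuts[0])] + \
        [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)] + \
        [(cuts[-1], np.inf)]
    m1 = 0.0
    m1_err = 0.0
    for a, b in bounds:
        val, err = integrate.quad(integrand, a, b, epsrel=1e-8, epsabs=1e-15,
                                  limit=300)
        if not np.isfinite(val):
            raise ArithmeticError(
                f"JZS quadrature failed on ({a}, {b}): value={val}, err={err}")
        m1 += val
        m1_err += err
    if m1 <= 0 or m1_err / m1 > 1e-5:
        raise ArithmeticError(
            f"JZS quadrature did not converge: m1={m1}, err={m1_err}")
    return m1 / m0


def power_paired_t(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of the two-sided paired t-test at sample size ``n``, effect ``d``."""
    if n < 2:
        raise InvalidParameterError("n must be at least 2")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    nu = n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, nu)
    ncp = abs(d) * math.sqrt(n)
    upper = sps.nct.sf(tcrit, nu, ncp)
    lower = sps.nct.cdf(-tcrit, nu, ncp)
    # scipy's nct tail underflows to NaN for large ncp; the term is ~0 there
    if not np.isfinite(upper):
        upper = 0.0
    if not np.isfinite(lower):
        lower = 0.0
    return float(upper + lower)


@dataclass
class PowerSpec:
    """Paired t-test power triplet; exactly one of n, d, power is unknown."""
    n: Optional[int] = None
    d: Optional[float] = None
    power: Optional[float] = None
    alpha: float = 0.05
    sidedness: str = "two-sided"


def solve_power(spec: PowerSpec) -> PowerSpec:
    """Complete a PowerSpec by solving the noncentral-t power equation.

    Solving for n returns the smallest integer reaching the target power;
    solving for d or power uses root finding / direct evaluation to 1e-6.
    """
    unknowns = [name for name in ("n", "d", "power")
                if getattr(spec, name) is None]
    if len(unknowns) != 1:
        raise InvalidParameterError(
            f"exactly one of n, d, power must be unknown, got {unknowns}")
    if not 0 < spec.alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    out = PowerSpec(**vars(spec))
    unknown = unknowns[0]
    if unknown == "power":
        out.power = round(power_paired_t(spec.n, spec.d, spec.alpha), 10)
        return out
    if not 0 < spec.power < 1:
        raise InvalidParameterError("target power must lie in (0, 1)")
    if unknown == "d":
        lo, hi = 1e-8, 1.0
        while power_paired_t(spec.n, hi, spec.alpha) < spec.power:
            hi *= 2.0
            if hi > 64:
                raise NoSolutionError("target power unreachable at this n")
        out.d = float(optimize.brentq(
            lambda d: power_paired_t(spec.n, d, spec.alpha) - spec.power,
            lo, hi, xtol=1e-10))
        return out
    # unknown == "n": smallest integer meeting the target
    n = 2
    while power_paired_t(n, spec.d, spec.alpha) < spec.power:
        n += 1
        if n > 1_000_000:
            raise NoSolutionError("required n exceeds 1e6; effect too small")
    out.n = n
    return out


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test alpha, alpha / m."""
    if m < 1:
        raise InvalidParameterError("number of tests m must be >= 1")
    return alpha / m


def mixed_anova_2x2(data: pd.DataFrame, dv: str = "value",
                    within: str = "part", between: str = "group",
                    subject: str = "participant_id") -> list[AnovaResult]:
    """2 (between) × 2 (within) mixed ANOVA with generalized eta squared.

    Expects long-format data with one observation per subject × within-level
    and complete cells.  Effects are tested with subjects as a random factor:
    the between effect against subjects-within-groups, the within effect and
    the interaction against the within×subject residual.  Unbalanced group
    sizes are handled with unweighted (cell-mean) contrasts.  With a single
    between level only the within effect is returned (its F then equals the
    square of the paired t, a property the test suite pins down).

    Generalized eta squared follows the additive decomposition with subjects
    random: ges = SS_effect / (SS_effect + SS_subjects + SS_within_error).
    """
    wide = data.pivot_table(index=[subject, between], columns=within,
                            values=dv, observed=True)
    if wide.shape[1] != 2:
        raise DataError("the within factor must have exactly 2 levels")
    if wide.isna().any().any():
        raise DataError("unbalanced missing cells in the within factor")
    w1, w2 = sorted(wide.columns)
    groups = wide.index.get_level_values(between)
    levels = sorted(set(groups))
    if len(levels) > 2:
        raise DataError("the between factor must have at most 2 levels")

    m = wide.mean(axis=1)                     # subject means
    dvec = wide[w1] - wide[w2]                # within-part differences
    N = len(wide)

    # error strata
    group_mean_m = m.groupby(groups).transform("mean")
    ss_subj = 2.0 * float(((m - group_mean_m) ** 2).sum())
    group_mean_d = dvec.groupby(groups).transform("mean")
    ss_werr = float(((dvec - group_mean_d) ** 2).sum()) / 2.0
    df_err = N - len(levels)
    if df_err < 1:
        raise DataError("not enough subjects for the error degrees of freedom")
    ms_subj = ss_subj / df_err
    ms_werr = ss_werr / df_err

    d_means = dvec.groupby(groups).mean()
    n_g = dvec.groupby(groups).size()
    inv_n = float(sum(1.0 / n_g[g] for g in levels))

    results: list[AnovaResult] = []

    def add(effect: str, contrast: float, var_unit: float, ms_err: float,
            ss_err_total: float) -> None:
        # F from the unweighted contrast; SS reconstructed as F * MS_error
        F = (contrast ** 2) / var_unit if var_unit > 0 else np.nan
        ss_eff = F * ms_err
        ges = ss_eff / (ss_eff + ss_subj + ss_werr)
        p = float(sps.f.sf(F, 1, df_err))
        results.append(AnovaResult(effect=effect, F=float(F), df1=1,
                                   df2=df_err, p=p, ges=float(ges)))

    if len(levels) == 2:
        m_means = m.groupby(groups).mean()
        # between main effect: pooled t on subject means (x2 obs per subject)
        add("between", float(m_means[levels[0]] - m_means[levels[1]]),
            (ms_subj / 2.0) * inv_n, ms_subj, ss_subj)
        # within main effect: unweighted mean of group difference means
        add("within", float(d_means.mean()),
            (ms_werr * 2.0) * inv_n / 4.0, ms_werr, ss_werr)
        # interaction: group contrast on difference means
        add("interaction", float(d_means[levels[0]] - d_means[levels[1]]),
            (ms_werr * 2.0) * inv_n, ms_werr, ss_werr)
    else:
        n = int(n_g.iloc[0])
        add("within", float(d_means.iloc[0]), (ms_werr * 2.0) / n,
            ms_werr, ss_werr)
    return results


def dz_confint(t: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Noncentral-t confidence interval for the standardized effect dz.

    Inverts the noncentral-t CDF in the noncentrality parameter at the
    observed t and divides by sqrt(n); signed (a negative t yields a CI
    below zero), symmetric about 0 when t = 0.
    """
    if n < 2:
        raise InvalidParameterError("n must be at least 2")
    nu = n - 1
    alpha = 1.0 - conf
    rootn = math.sqrt(n)

    def cdf(ncp: float) -> float:
        val = sps.nct.cdf(t, nu, ncp)
        if not np.isfinite(val):        # scipy tail underflow; use the limit
            return 0.0 if ncp > t else 1.0
        return float(val)

    def solve(prob: float) -> float:
        # find ncp with P(T_nu,ncp <= t) = prob
        f = lambda ncp: cdf(ncp) - prob
        lo, hi = t - 2.0, t + 2.0
        width = 2.0
        while f(lo) < 0:       # cdf too small -> ncp too large -> move left
            width *= 2.0
            lo -= width
            if lo < -1e3:
                return -np.inf
        while f(hi) > 0:
            width *= 2.0
            hi += width
            if hi > 1e3:
                return np.inf
        return float(optimize.brentq(f, lo, hi, xtol=1e-9))

    return solve(1.0 - alpha / 2.0) / rootn, solve(alpha / 2.0) / rootn
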