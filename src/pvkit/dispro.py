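"""The four disproportionality statistics with interval estimates.

For a 2x2 report table (a, b, c, d) against the rest of a database:

* ROR  = (a d)/(b c), Wald 95% CI on the log scale
  (``exp(ln ROR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))``).
* PRR  = [a/(a+b)] / [c/(c+d)], with the Pearson chi-squared statistic
  ``N(ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]`` (Yates-corrected variant
  available) and its chi2(1) upper-tail p-value.
* BCPNN information component, closed form with the Bate-1998 priors:
  IC = log2 of the shrunken observed-to-expected co-reporting ratio,
  with IC025 = E(IC) - 2 sqrt(V(IC)).
* MGPS: DuMouchel's gamma-Poisson shrinker. The relative reporting
  rate lambda has a two-component gamma mixture prior fitted by
  marginal (negative-binomial) maximum likelihood across all tables;
  the posterior for each table is again a gamma mixture, EBGM is the
  posterior geometric mean of lambda and EBGM05 its 5th percentile.

Zero cells: ROR and PRR use the Haldane-Anscombe +0.5 correction on all
four cells, applied only when some cell is zero; the Bayesian methods
are finite on raw counts and never corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import ContingencyTable

_Z95 = 1.959963984540054


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    corrected: bool


class PrrResult(NamedTuple):
    prr: float
    chi2: float
    p: float
    corrected: bool


class IcResult(NamedTuple):
    e_ic: float
    v_ic: float
    ic025: float


class EbgmResult(NamedTuple):
    ebgm: float
    ebgm05: float


def _cells(t, haldane: bool):
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0.0:
        if not haldane:
            return a, b, c, d, False, True  # undefined flag
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True, False
    return a, b, c, d, False, False


def ror(t: ContingencyTable, haldane: bool = True) -> RorResult:
    """Reporting odds ratio with Wald 95% CI.

    A zero cell with the correction disabled yields NaNs (an
    undefined-result flag, not an exception).
    """
    a, b, c, d, corrected, undefined = _cells(t, haldane)
    if undefined:
        return RorResult(math.nan, math.nan, math.nan, False)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(
        est, est * math.exp(-_Z95 * se), est * math.exp(_Z95 * se), corrected
    )


def prr(t: ContingencyTable, haldane: bool = True, yates: bool = False) -> PrrResult:
    """Proportional reporting ratio with the Pearson chi-squared test.

    The chi-squared statistic is always computed on the raw counts
    (uncorrected by default, matching the PRR>=2 & chi2>=4 convention);
    the Haldane correction applies to the ratio only.
    """
    a, b, c, d, corrected, undefined = _cells(t, haldane)
    if undefined:
        est = math.nan
        corrected = False
    else:
        est = (a / (a + b)) / (c / (c + d))

    ar, br, cr, dr = float(t.a), float(t.b), float(t.c), float(t.d)
    n = ar + br + cr + dr
    denom = (ar + br) * (cr + dr) * (ar + cr) * (br + dr)
    if denom == 0.0:
        chi2 = 0.0
    else:
        diff = abs(ar * dr - br * cr)
        if yates:
            diff = max(diff - n / 2.0, 0.0)
        chi2 = n * diff * diff / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return PrrResult(est, chi2, p, corrected)


@dataclass(frozen=True)
class BcpnnPriors:
    """Bate-1998 prior constants for the closed-form BCPNN."""

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0


def bcpnn_ic(t: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()) -> IcResult:
    """Closed-form BCPNN information component in bits.

    The priors guarantee finiteness for every table, including zero
    cells; IC025 is the E(IC) - 2 sqrt(V(IC)) lower bound.
    """
    a = float(t.a)
    n = float(t.n)
    a1, b1 = priors.alpha1, priors.beta1
    al, be, g11 = priors.alpha, priors.beta, priors.gamma11
    row = a + float(t.b)  # a+b, drug margin
    col = a + float(t.c)  # a+c, event margin
    gamma = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (row + a1) * (col + b1))
    )
    ln2sq = math.log(2.0) ** 2
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row + al - a1) / ((row + a1) * (1 + n + al))
        + (n - col + be - b1) / ((col + b1) * (1 + n + be))
    ) / ln2sq
    return IcResult(e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic))


# ---------------------------------------------------------------------------
# MGPS


@dataclass(frozen=True)
class GammaMixturePrior:
    """Two-component gamma prior (shape alpha_j, rate beta_j; weight w on
    component 1) for the relative reporting rate lambda."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma parameters must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("mixture weight outside [0,1]")

    @property
    def mean(self) -> float:
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2


#: DuMouchel's published starting point (alpha1, beta1, alpha2, beta2, w).
DUMOUCHEL_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


class MgpsFitError(RuntimeError):
    """Optimizer failure; carries the best parameters found."""

    def __init__(self, message: str, best: GammaMixturePrior):
        super().__init__(message)
        self.best = best


def _nb_logpmf(a, alpha, beta, e):
    """Marginal log-likelihood of count a when lambda ~ Gamma(alpha, beta)
    and a | lambda ~ Poisson(lambda * e): negative binomial."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    # log1p forms: stable when beta >> e (near-degenerate components)
    logp = -np.log1p(e / beta)
    log1mp = np.log(e) - np.log(beta) + logp
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * logp
        + a * log1mp
    )


def _mixture_loglik(theta, a, e):
    la1, lb1, la2, lb2, logit_w = theta
    w = special.expit(logit_w)
    l1 = _nb_logpmf(a, math.exp(la1), math.exp(lb1), e)
    l2 = _nb_logpmf(a, math.exp(la2), math.exp(lb2), e)
    m = np.logaddexp(np.log(w + 1e-300) + l1, np.log(1 - w + 1e-300) + l2)
    return float(np.sum(m))


def fit_mgps_prior(
    tables: Optional[Sequence[ContingencyTable]] = None,
    *,
    a: Optional[np.ndarray] = None,
    expected: Optional[np.ndarray] = None,
    start: Sequence[float] = DUMOUCHEL_START,
) -> GammaMixturePrior:
    """Fit the gamma-mixture prior by marginal maximum likelihood.

    Accepts either contingency tables or raw ``(a, expected)`` arrays.
    Bounded quasi-Newton (L-BFGS-B on log/logit-transformed parameters)
    from DuMouchel's published start, with a small multi-start fallback;
    a failure after restarts raises :class:`MgpsFitError` carrying the
    best parameters found.
    """
    if tables is not None:
        a = np.array([t.a for t in tables], dtype=float)
        expected = np.array([t.expected for t in tables], dtype=float)
    if a is None or expected is None:
        raise ValueError("provide tables or both a and expected")
    a = np.asarray(a, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if a.size == 0:
        raise ValueError("no tables to fit")
    if np.all(a == 0):
        raise ValueError("degenerate input: all observed counts are zero")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")

    a1, b1, a2, b2, w = start
    theta0 = np.array(
        [math.log(a1), math.log(b1), math.log(a2), math.log(b2), special.logit(w)]
    )
    ll0 = _mixture_loglik(theta0, a, expected)

    def neg(theta):
        return -_mixture_loglik(theta, a, expected)

    bounds = [(-10, 10)] * 4 + [(-12, 12)]
    starts = [theta0]
    # deterministic multi-start: the likelihood surface of a 5-parameter
    # mixture over few cells has local optima, in particular a
    # null-dominated basin (spike near lambda=1 plus a diffuse signal
    # component) that the DuMouchel start can miss
    for alt in ((1.0, 1.0, 1.0, 1.0, 0.5), (0.5, 0.5, 4.0, 4.0, 0.2),
                (2.0, 2.0, 0.2, 0.2, 0.8), (100.0, 100.0, 2.0, 0.5, 0.9),
                (2.0, 0.5, 100.0, 100.0, 0.1)):
        starts.append(
            np.array([math.log(alt[0]), math.log(alt[1]), math.log(alt[2]),
                      math.log(alt[3]), special.logit(alt[4])])
        )
    best = None
    for th0 in starts:
        res = optimize.minimize(neg, th0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    # Nelder-Mead polish from the best basin (L-BFGS-B's finite-difference
    # gradient can stall on the flat spike direction); same box
    polish = optimize.minimize(neg, best.x, method="Nelder-Mead", bounds=bounds,
                               options={"xatol": 1e-6, "fatol": 1e-8,
                                        "maxiter": 2000})
    if polish.fun < best.fun:
        best = polish

    la1, lb1, la2, lb2, lw = best.x
    prior = GammaMixturePrior(
        math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2),
        float(special.expit(lw)),
    )
    if -best.fun < ll0 - 1e-6:
        raise MgpsFitError(
            "MGPS optimizer failed to improve on the starting parameters", prior
        )
    return prior


def _posterior_mixture(t_a: float, e: float, prior: GammaMixturePrior):
    """Posterior component parameters and weights for one table."""
    la = np.array([
        math.log(prior.w + 1e-300) + float(_nb_logpmf(t_a, prior.alpha1, prior.beta1, e)),
        math.log(1 - prior.w + 1e-300) + float(_nb_logpmf(t_a, prior.alpha2, prior.beta2, e)),
    ])
    q = np.exp(la - special.logsumexp(la))
    shapes = np.array([prior.alpha1 + t_a, prior.alpha2 + t_a])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    return q, shapes, rates


def ebgm(t: ContingencyTable, prior: GammaMixturePrior) -> EbgmResult:
    """Empirical-Bayes geometric mean and its posterior 5th percentile.

    EBGM = exp(E[ln lambda | a]) via the digamma expectation of the
    posterior gamma mixture; EBGM05 by monotone root-finding on the
    mixture CDF.
    """
    e = t.expected
    if e <= 0:
        raise ValueError("expected count must be positive")
    q, shapes, rates = _posterior_mixture(float(t.a), e, prior)
    elog = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    ebgm_val = math.exp(elog)

    def cdf(x):
        return float(np.sum(q * stats.gamma.cdf(x, shapes, scale=1.0 / rates)))

    lo = float(np.min(stats.gamma.ppf(0.001, shapes, scale=1.0 / rates)))
    hi = float(np.max(stats.gamma.ppf(0.5, shapes, scale=1.0 / rates)))
    lo = max(lo, 1e-12)
    f_lo, f_hi = cdf(lo) - 0.05, cdf(hi) - 0.05
    tries = 0
    while f_lo > 0 and tries < 60:
        lo /= 4.0
        f_lo = cdf(lo) - 0.05
        tries += 1
    while f_hi < 0 and tries < 120:
        hi *= 4.0
        f_hi = cdf(hi) - 0.05
        tries += 1
    if f_lo > 0 or f_hi < 0:
        raise ArithmeticError(
            f"EBGM05 root not bracketed: cdf({lo})={f_lo + 0.05:.3g}, "
            f"cdf({hi})={f_hi + 0.05:.3g}"
        )
    q05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12)
    return EbgmResult(ebgm_val, float(q05))


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: p_adj = min(1, m p). ``m`` is the family
    size (>= number of tests)."""
    p = np.asarray(p_values, dtype=float)
    if m <= 0:
        raise ValueError("family size m must be positive")
    if p.ndim == 0:
        return float(min(1.0, m * float(p)))
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# All-statistics table


def signal_table(
    tables: Sequence[ContingencyTable],
    prior: Optional[GammaMixturePrior] = None,
    haldane: bool = True,
    yates: bool = False,
    bonferroni_m: Optional[int] = None,
) -> pd.DataFrame:
    """One row per label with all four statistics, CIs and adjusted p.

    The MGPS prior is fitted across the supplied tables unless given;
    the Bonferroni family size defaults to the number of labels tested.
    """
    if prior is None:
        prior = fit_mgps_prior(tables)
    m = bonferroni_m if bonferroni_m is not None else len(tables)
    rows = []
    for t in tables:
        r = ror(t, haldane=haldane)
        p_ = prr(t, haldane=haldane, yates=yates)
        ic = bcpnn_ic(t)
        eb = ebgm(t, prior)
        rows.append(
            {
                "label": t.label,
                "level": t.level,
                "a": t.a,
                "expected": t.expected,
                "ror": r.ror,
                "ror_ci_low": r.ci_low,
                "ror_ci_high": r.ci_high,
                "prr": p_.prr,
                "chi2": p_.chi2,
                "p_chi2": p_.p,
                "e_ic": ic.e_ic,
                "v_ic": ic.v_ic,
                "ic025": ic.ic025,
                "ebgm": eb.ebgm,
                "ebgm05": eb.ebgm05,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(df["p_chi2"].to_numpy(), m)
    df.attrs["bonferroni_m"] = m
    df.attrs["prior"] = prior
    return df
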