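"""Classical disproportionality statistics: PRR, ROR, BCPNN-IC and EBGM.

Each statistic compares the observed report count c_ij of a drug-ADE pair
with the count expected under independence, and signals when the lower bound
of its 95% interval crosses the conventional threshold:

* PRR   — proportional reporting ratio; signal when PRR025 > 1
* ROR   — reporting odds ratio; signal when ROR025 > 1
* IC    — BCPNN information component log2(p_ij / (p_i+ p_+j)) with beta
          priors (all hyperparameters 1); signal when IC05 > 0
* EBGM  — DuMouchel gamma-Poisson shrinker, the geometric mean
          2^{E[log2 λ | c]} of the posterior relative report rate; signal
          when the posterior 5th percentile EB05 >= 2

Interval conventions: PRR/ROR use log-scale Wald intervals (the standard
companions of these ratios), IC uses the delta-method posterior SD of the
original BCPNN, EBGM uses exact posterior quantiles of the gamma mixture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import optimize, special, stats

from .srs_data import ContingencyTable, DataError, ReportDatabase, build_all_contingencies

logger = logging.getLogger(__name__)

METHODS = ("PRR", "ROR", "IC", "EBGM")
Z95 = 1.959963984540054  # two-sided 95% normal quantile


class DegenerateTableError(DataError):
    """A 2x2 cell needed by a frequentist ratio is zero (no continuity correction)."""


@dataclass(frozen=True)
class SignalScore:
    """A method's point estimate, interval bounds and signal flag for one pair."""

    method: str
    point: float
    lower95: float
    upper95: float
    is_signal: bool

    def __post_init__(self):
        if all(map(math.isfinite, (self.lower95, self.point, self.upper95))):
            if not (self.lower95 <= self.point + 1e-12 and
                    self.point <= self.upper95 + 1e-12):
                raise ValueError(
                    f"interval bounds disordered: {self.lower95} / {self.point} / {self.upper95}")


def _missing(method: str) -> SignalScore:
    return SignalScore(method, float("nan"), float("nan"), float("nan"), False)


# ---------------------------------------------------------------------------
# frequentist ratios


def _corrected_cells(t: ContingencyTable, continuity: bool):
    a, b, c, d = t.cells()
    if continuity and min(a, b, c, d) == 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def prr(t: ContingencyTable, continuity: bool = False) -> SignalScore:
    """Proportional reporting ratio with a log-scale Wald 95% interval.

    PRR = (c_ij / c_i+) / ((c_+j - c_ij) / (c_++ - c_i+)); the optional
    Haldane continuity correction adds 0.5 to every 2x2 cell when any is zero.
    """
    a, b, c, d = _corrected_cells(t, continuity)
    n1, n0 = a + b, c + d  # exposed / unexposed report counts
    if n1 <= 0 or n0 <= 0 or a <= 0 or c <= 0:
        raise DegenerateTableError(f"degenerate table for PRR: cells {t.cells()}")
    point = (a / n1) / (c / n0)
    se = math.sqrt(1.0 / a - 1.0 / n1 + 1.0 / c - 1.0 / n0)
    lower = math.exp(math.log(point) - Z95 * se)
    upper = math.exp(math.log(point) + Z95 * se)
    return SignalScore("PRR", point, lower, upper, lower > 1.0)


def ror(t: ContingencyTable, continuity: bool = False) -> SignalScore:
    """Reporting odds ratio ad/(bc) with a log-scale Wald 95% interval."""
    a, b, c, d = _corrected_cells(t, continuity)
    if min(a, b, c, d) <= 0:
        raise DegenerateTableError(f"degenerate table for ROR: cells {t.cells()}")
    point = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lower = math.exp(math.log(point) - Z95 * se)
    upper = math.exp(math.log(point) + Z95 * se)
    return SignalScore("ROR", point, lower, upper, lower > 1.0)


# ---------------------------------------------------------------------------
# BCPNN information component


@dataclass(frozen=True)
class ICPriorConfig:
    """Beta hyperparameters of the BCPNN priors; the conventional choice is all 1.

    p_i+ ~ Beta(alpha1, alpha - alpha1), p_+j ~ Beta(beta1, beta - beta1) and
    p_ij ~ Beta(gamma11, gamma - gamma11) with gamma tied to the margins so
    that the prior IC expectation is 0.  ``z`` is the number of posterior
    standard deviations subtracted for the signalling lower bound.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0
    z: float = Z95

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.gamma11) <= 0:
            raise ValueError("beta hyperparameters must be positive")


def ic(t: ContingencyTable, prior: ICPriorConfig | None = None) -> SignalScore:
    """BCPNN information component with delta-method posterior mean and SD.

    With all first-shape hyperparameters 1, the prior totals are
    alpha = beta = 2 and gamma is chosen so the prior expectation of
    p_ij/(p_i+ p_+j) is 1; zero cells are therefore regularized and never
    raise.  The lower bound is E(IC) - z * SD(IC).
    """
    prior = prior or ICPriorConfig()
    cij, ci, cj, C = (float(t.c_ij), float(t.c_i_plus),
                      float(t.c_plus_j), float(t.c_plus_plus))
    a1, b1, g11 = prior.alpha1, prior.beta1, prior.gamma11
    alpha = 2.0 * a1
    beta = 2.0 * b1
    gamma = g11 * (C + alpha) * (C + beta) / ((ci + a1) * (cj + b1))
    point = math.log2((cij + g11) * (C + alpha) * (C + beta)
                      / ((C + gamma) * (ci + a1) * (cj + b1)))
    var = ((C - cij + gamma - g11) / ((cij + g11) * (1 + C + gamma))
           + (C - ci + alpha - a1) / ((ci + a1) * (1 + C + alpha))
           + (C - cj + beta - b1) / ((cj + b1) * (1 + C + beta))) / math.log(2.0) ** 2
    sd = math.sqrt(var)
    lower = point - prior.z * sd
    upper = point + prior.z * sd
    return SignalScore("IC", point, lower, upper, lower > 0.0)


def raw_ic(t: ContingencyTable) -> float:
    """Prior-free information component log2((c_ij/c_++)/((c_i+/c_++)(c_+j/c_++)))."""
    return math.log2((t.c_ij / t.c_plus_plus) / ((t.c_i_plus / t.c_plus_plus)
                                                 * (t.c_plus_j / t.c_plus_plus)))


# ---------------------------------------------------------------------------
# EBGM gamma-Poisson shrinker


@dataclass(frozen=True)
class EBGMPrior:
    """Two-component gamma mixture prior on the relative report rate λ.

    λ ~ mix_p * Gamma(alpha1, rate beta1) + (1 - mix_p) * Gamma(alpha2, rate beta2).
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    mix_p: float
    loglik: float = float("nan")
    converged: bool = True

    def __post_init__(self):
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma shape/rate parameters must be positive")
        if not 0.0 <= self.mix_p <= 1.0:
            raise ValueError("mix_p must lie in [0, 1]")


#: classical starting values for the 5-parameter marginal likelihood
EBGM_DEFAULT_START = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


def _nb_logpmf(c, e, alpha, beta):
    """log P(C=c) when C|λ ~ Poisson(λ e) and λ ~ Gamma(alpha, rate beta)."""
    # negative binomial with size alpha and success prob beta/(beta+e)
    logp = np.log(beta) - np.log(beta + e)
    log1mp = np.log(e) - np.log(beta + e)
    return (special.gammaln(alpha + c) - special.gammaln(alpha)
            - special.gammaln(c + 1.0) + alpha * logp + c * log1mp)


def ebgm_marginal_loglik(counts, expected, prior: EBGMPrior) -> float:
    """Log marginal likelihood of observed counts under the mixture prior."""
    c = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    l1 = _nb_logpmf(c, e, prior.alpha1, prior.beta1)
    l2 = _nb_logpmf(c, e, prior.alpha2, prior.beta2)
    with np.errstate(divide="ignore"):
        stack = np.stack([l1 + np.log(prior.mix_p), l2 + np.log1p(-prior.mix_p)])
    return float(special.logsumexp(stack, axis=0).sum())


def fit_ebgm_prior(
    tables: Iterable[ContingencyTable],
    start: tuple = EBGM_DEFAULT_START,
    squash_threshold: int = 0,
) -> EBGMPrior:
    """Maximum-marginal-likelihood fit of the 5 mixture hyperparameters.

    The likelihood is the product over pairs of the negative-binomial mixture
    pmf at the observed counts given expected counts E_ij = c_i+ c_+j / c_++.
    Positivity is enforced by log-reparameterization and mix_p by a logit;
    non-convergence is reported via ``converged`` rather than raised.
    ``squash_threshold`` drops tables with c_ij below it before fitting.
    """
    tabs = [t for t in tables if t.c_ij >= squash_threshold]
    if len(tabs) < 2:
        raise DataError("insufficient data: need at least 2 contingency tables")
    c = np.array([t.c_ij for t in tabs], dtype=float)
    e = np.array([t.expected for t in tabs], dtype=float)
    if np.any(e <= 0):
        raise DataError("zero expected count in EBGM prior fit")

    def nll(theta):
        a1, b1, a2, b2 = np.exp(theta[:4])
        p = special.expit(theta[4])
        prior = EBGMPrior(a1, b1, a2, b2, min(max(p, 1e-12), 1 - 1e-12))
        return -ebgm_marginal_loglik(c, e, prior)

    theta0 = np.array([math.log(start[0]), math.log(start[1]),
                       math.log(start[2]), math.log(start[3]),
                       special.logit(start[4])])
    # shapes/rates bounded in [1e-3, 1e3]: outside that range a component is
    # numerically degenerate and the posterior quantile machinery unreliable
    bounds = [(-3 * math.log(10.0), 3 * math.log(10.0))] * 4 + [(-12.0, 12.0)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    polish = optimize.minimize(nll, res.x, method="Nelder-Mead",
                               options={"maxiter": 600, "xatol": 1e-8,
                                        "fatol": 1e-8})
    if polish.fun < res.fun:
        res = optimize.minimize(
            nll, np.clip(polish.x, [b[0] for b in bounds],
                         [b[1] for b in bounds]),
            method="L-BFGS-B", bounds=bounds)
    a1, b1, a2, b2 = np.exp(res.x[:4])
    p = float(special.expit(res.x[4]))
    prior = EBGMPrior(float(a1), float(b1), float(a2), float(b2), p,
                      loglik=-float(res.fun), converged=bool(res.success))
    if not res.success:
        logger.warning("EBGM prior fit did not converge: %s", res.message)
    return prior


def _posterior_mixture(c: float, e: float, prior: EBGMPrior):
    """Posterior over λ given count c: gamma mixture with updated weights."""
    shapes = np.array([prior.alpha1 + c, prior.alpha2 + c])
    rates = np.array([prior.beta1 + e, prior.beta2 + e])
    with np.errstate(divide="ignore"):
        logw = np.array([
            math.log(prior.mix_p) if prior.mix_p > 0 else -np.inf,
            math.log1p(-prior.mix_p) if prior.mix_p < 1 else -np.inf,
        ])
    logw = logw + np.array([_nb_logpmf(c, e, prior.alpha1, prior.beta1),
                            _nb_logpmf(c, e, prior.alpha2, prior.beta2)])
    w = np.exp(logw - special.logsumexp(logw))
    return shapes, rates, w


def posterior_lambda_quantile(c, e, prior: EBGMPrior, q: float,
                              tol: float = 1e-8) -> float:
    """Quantile of the posterior gamma mixture by root-finding on its CDF."""
    shapes, rates, w = _posterior_mixture(float(c), float(e), prior)

    def cdf(x):
        return float(np.dot(w, special.gammainc(shapes, rates * x))) - q

    hi = float(np.max(stats.gamma.ppf(q, shapes, scale=1.0 / rates))) + 1e-9
    lo = float(np.min(stats.gamma.ppf(q, shapes, scale=1.0 / rates)))
    lo = max(lo * 0.5, 0.0)
    while cdf(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(cdf, lo, hi, xtol=tol, rtol=8.9e-16))


def ebgm(t: ContingencyTable, prior: EBGMPrior) -> SignalScore:
    """Empirical-Bayes geometric mean 2^{E[log2 λ | c]} with EB05/EB95 bounds.

    The posterior of λ is the gamma mixture obtained by the Poisson update of
    the prior at the observed c_ij and expected E_ij; E[log λ] has the closed
    form Σ_k w_k (ψ(shape_k) - log rate_k).  Signal when EB05 >= 2.
    """
    e = t.expected
    if e <= 0:
        raise DataError("zero expected count")
    shapes, rates, w = _posterior_mixture(float(t.c_ij), float(e), prior)
    mean_log = float(np.dot(w, special.digamma(shapes) - np.log(rates)))
    point = math.exp(mean_log)
    lower = posterior_lambda_quantile(t.c_ij, e, prior, 0.05)
    upper = posterior_lambda_quantile(t.c_ij, e, prior, 0.95)
    return SignalScore("EBGM", point, lower, upper, lower >= 2.0)


# ---------------------------------------------------------------------------
# batch driver


def score_all(
    db: ReportDatabase,
    pairs: Iterable,
    method: str,
    continuity: bool = False,
    ic_prior: ICPriorConfig | None = None,
    ebgm_prior: EBGMPrior | None = None,
) -> dict:
    """Score many pairs with one classical method.

    For EBGM, the prior is fitted on every co-occurring pair of the database
    when not supplied.  Pairs whose table violates a method's preconditions
    receive a score with NaN point and ``is_signal=False`` (logged), so batch
    evaluation can account for coverage explicitly.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    pairs = list(pairs)
    tables = build_all_contingencies(db, pairs)
    if method == "EBGM" and ebgm_prior is None:
        ebgm_prior = fit_ebgm_prior(build_all_contingencies(db).values())
    out: dict = {}
    n_missing = 0
    for pair in pairs:
        t = tables[pair]
        try:
            if method == "PRR":
                out[pair] = prr(t, continuity=continuity)
            elif method == "ROR":
                out[pair] = ror(t, continuity=continuity)
            elif method == "IC":
                out[pair] = ic(t, prior=ic_prior)
            else:
                out[pair] = ebgm(t, ebgm_prior)
        except DataError:
            out[pair] = _missing(method)
            n_missing += 1
    if n_missing:
        logger.info("score_all(%s): %d/%d pairs unscorable (degenerate tables)",
                    method, n_missing, len(pairs))
    return out
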