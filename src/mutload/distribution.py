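"""Moments and lognormal form of whole-genome fitness at equilibrium.

Whole-genome fitness ``W`` is the product of per-site fitnesses over the
``n`` functional sites (multiplicative fitness, no linkage
disequilibrium), with per-site genotypes drawn independently from the
balance frequencies.  The mean of ``W`` is 1 by normalization.  Its log is
a sum of ``n`` i.i.d. terms and hence asymptotically normal, so ``W`` is
lognormal with

    sigma^2 = n*u*s,   mu = -n*u*s/2        (additive and recessive)
    sigma^2 = 2*n*u*h*s,  mu = -n*u*h*s     (general dominance)

and the variance of ``W`` itself is ``exp(sigma^2) - 1``.  Exact
(pre-asymptotic) moments follow from multinomial formulas and are
evaluated in log space: ``n ~ 1e8`` makes naive per-site products
meaningless in floating point.

A discrete spectrum of mutation classes ``(u_i, s_i)`` generalizes the
single-class results with ``n*u*s -> n * sum_i u_i * s_i``, i.e. an
effective selection coefficient ``s_bar = sum_i u_i s_i / sum_i u_i``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


from scipy.stats import norm

from mutload.parameters import LoadParameters, ParameterError, Scheme
from mutload.equilibrium import genotype_table

__all__ = [
    "FitnessDistribution",
    "MutationClassSpectrum",
    "variance_exact",
    "variance_asymptotic",
    "lognormal_parameters",
    "fitness_range_probability",
    "lognormal_range_probability",
    "spectrum_variance",
    "spectrum_lognormal_parameters",
]


@dataclass(frozen=True)
class FitnessDistribution:
    """Lognormal summary of whole-genome fitness ``W``.

    ``mu_log`` and ``sigma2_log`` are the mean and variance of ``log W``;
    ``mean_W = exp(mu_log + sigma2_log/2) = 1`` under normalization, which
    forces ``sigma2_log = -2 * mu_log``.
    """

    mean_W: float
    var_W: float
    mu_log: float
    sigma2_log: float
    scheme: Scheme

    @property
    def sd_W(self) -> float:
        return math.sqrt(self.var_W)


@dataclass(frozen=True)
class MutationClassSpectrum:
    """Discrete classes of deleterious mutations ``(u_i, s_i)``."""

    classes: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.classes:
            raise ParameterError("classes: spectrum must be non-empty")
        object.__setattr__(self, "classes", tuple(map(tuple, self.classes)))
        for u_i, s_i in self.classes:
            if u_i <= 0:
                raise ParameterError(f"u_i: class rate must be positive, got {u_i}")
            if not 0 < s_i < 1:
                raise ParameterError(f"s_i: must be in (0, 1), got {s_i}")

    @property
    def u_total(self) -> float:
        return math.fsum(u_i for u_i, _ in self.classes)

    @property
    def us_sum(self) -> float:
        """``sum_i u_i * s_i`` — the per-site log-variance contribution."""
        return math.fsum(u_i * s_i for u_i, s_i in self.classes)

    @property
    def s_bar(self) -> float:
        """Mutation-rate-weighted mean selection coefficient."""
        return self.us_sum / self.u_total


def _per_site_log_moments(params: LoadParameters) -> tuple[float, float]:
    """Return (log mean(W), log E[W^2]) for the whole genome, exactly.

    Per site, with raw (unnormalized) fitnesses w_i, frequencies p_i and
    normalizer d (1-2u or 1-u): E[w_raw] and Var[w_raw] are accumulated
    from deviations w_i - E[w_raw] so that the tiny O(u*s) excess of
    E[w_raw^2] over E[w_raw]^2 survives cancellation, then raised to the
    n-th power in log space.
    """
    delta, var_raw, d = _per_site_raw_moments(params)
    n = params.n
    log_mean_W = n * math.log1p(delta / d)
    mean_raw = d + delta
    log_E_W2 = 2 * log_mean_W + n * math.log1p(var_raw / mean_raw**2)
    return log_mean_W, log_E_W2


def _per_site_raw_moments(params: LoadParameters) -> tuple[float, float, float]:
    """(E[w_raw] - d, Var[w_raw], d) with d the normalizer 1-2u or 1-u.

    The mean excess over the normalizer is evaluated from its closed form
    rather than by summation: the additive and recessive identities
    E[w_raw] = d hold exactly, and the general-dominance excess is the
    order-u^2 term (2 - 1/h) * u^2/(h*s).  Summing the O(1) genotype terms
    in floating point would bury these tiny excesses (amplified n-fold
    downstream) under cancellation noise.
    """
    u, s, h = params.u, params.s, params.h
    table = genotype_table(params)
    if params.scheme is Scheme.RECESSIVE:
        d = 1.0 - u
        raw_w = (1.0, 1.0, 1.0 - s)
        delta = 0.0
    elif params.scheme is Scheme.ADDITIVE:
        d = 1.0 - 2 * u
        raw_w = (1.0, 1.0 - 0.5 * s, 1.0 - s)
        delta = 0.0
    else:
        d = 1.0 - 2 * u
        raw_w = (1.0, 1.0 - h * s, 1.0 - s)
        delta = (2.0 - 1.0 / h) * u * u / (h * s)
    mean_raw = d + delta
    var_raw = math.fsum(
        p * (w - mean_raw) ** 2 for p, w in zip(table.frequencies, raw_w)
    )
    return delta, var_raw, d


def variance_exact(params: LoadParameters) -> float:
    """Exact (pre-asymptotic) variance of whole-genome fitness ``W``.

    Evaluates the multinomial second moment ``E[W^2] - E[W]^2`` with the
    truncated balance frequencies, via log-space accumulation.  For the
    additive and recessive schemes ``E[W] = 1`` exactly; for general
    dominance it is 1 up to order ``u**2``.
    """
    delta, var_raw, d = _per_site_raw_moments(params)
    mean_raw = d + delta
    log_mean_W = params.n * math.log1p(delta / d)
    # Var(W) = mean(W)^2 * [(1 + var_raw/mean_raw^2)^n - 1]
    return math.exp(2 * log_mean_W) * math.expm1(
        params.n * math.log1p(var_raw / mean_raw**2)
    )


def variance_asymptotic(params: LoadParameters) -> float:
    """Asymptotic variance of ``W``: ``exp(nus) - 1`` for the additive and
    recessive schemes, ``exp(2*n*u*h*s) - 1`` under general dominance."""
    return math.expm1(_sigma2_log(params))


def _sigma2_log(params: LoadParameters) -> float:
    if params.scheme is Scheme.GENERAL_H:
        return 2 * params.n * params.u * params.h * params.s
    return params.nus


def lognormal_parameters(params: LoadParameters) -> FitnessDistribution:
    """Lognormal parameters of ``W``: ``(mu, sigma^2)`` of ``log W``."""
    sigma2 = _sigma2_log(params)
    return FitnessDistribution(
        mean_W=1.0,
        var_W=math.expm1(sigma2),
        mu_log=-0.5 * sigma2,
        sigma2_log=sigma2,
        scheme=params.scheme,
    )


def lognormal_range_probability(
    mu: float, sigma2: float, w_lo: float, w_hi: float
) -> float:
    """``P(w_lo < W < w_hi)`` for ``log W ~ Normal(mu, sigma2)``.

    ``w_lo = 0`` is accepted as the lower boundary of the support.
    """
    if w_lo < 0:
        raise ValueError("w_lo: fitness bounds must be non-negative")
    if w_hi <= w_lo:
        return 0.0 if w_hi == w_lo else _raise_order(w_lo, w_hi)
    sigma = math.sqrt(sigma2)
    upper = norm.cdf((math.log(w_hi) - mu) / sigma) if math.isfinite(w_hi) else 1.0
    lower = norm.cdf((math.log(w_lo) - mu) / sigma) if w_lo > 0 else 0.0
    return float(upper - lower)


def _raise_order(w_lo: float, w_hi: float) -> float:
    raise ValueError(f"w_lo must not exceed w_hi, got ({w_lo}, {w_hi})")


def fitness_range_probability(
    params: LoadParameters, w_lo: float, w_hi: float
) -> float:
    """``P(w_lo < W < w_hi)`` under the lognormal approximation for the
    parameter set's equilibrium fitness distribution."""
    dist = lognormal_parameters(params)
    return lognormal_range_probability(dist.mu_log, dist.sigma2_log, w_lo, w_hi)


def spectrum_variance(n: float, spectrum: MutationClassSpectrum) -> float:
    """Variance of ``W`` for a multi-class spectrum:
    ``exp(n * sum_i u_i s_i) - 1`` (additive classes)."""
    return math.expm1(n * spectrum.us_sum)


def spectrum_lognormal_parameters(
    n: float, spectrum: MutationClassSpectrum
) -> FitnessDistribution:
    """Lognormal parameters with the generalized ``sigma^2 = n*sum u_i s_i``."""
    sigma2 = n * spectrum.us_sum
    return FitnessDistribution(
        mean_W=1.0,
        var_W=math.expm1(sigma2),
        mu_log=-0.5 * sigma2,
        sigma2_log=sigma2,
        scheme=Scheme.ADDITIVE,
    )
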