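"""Extreme-value fitness: the fittest individual likely to exist.

In a population of ``N`` individuals at equilibrium, the count of
mutation-bearing sites per individual is approximately Poisson (mean
``m = 4nu/s`` heterozygous sites under additivity; ``k = nu/s`` mutant
homozygous sites under recessivity).  The fittest individual likely to
occur carries about ``c * sqrt(mean)`` fewer such sites than average,
where ``c`` is an extreme-value multiplier (the conservative working value
is 5 for ``N = 1e9``; the exact normal quantile at ``1 - 1/N`` is about
6).  Its fitness is asymptotically ``exp(c * sqrt(nus))`` under both
schemes — in contrast to the idealized, mutation-free individual, whose
fitness ``exp(2nu)`` (additive) can be enormous, but who will never
actually exist.

Both extremes and the associated load measures (Crow load
``(w_max - w_bar)/w_max`` and Haldane load ``1 - exp(-2nu)``) are
computed here, along with the reference grid of fittest-likely fitness
over functional fraction ``f`` and selection coefficient ``s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from mutload.parameters import LoadParameters, ParameterError, Scheme
from mutload.distribution import variance_asymptotic, lognormal_parameters

__all__ = [
    "ExtremeFitness",
    "IdealizedMax",
    "LoadMetrics",
    "fittest_likely",
    "idealized_max",
    "idealized_z_score",
    "load_metrics",
    "table1_grid",
    "format_table1",
    "extreme_multiplier",
    "TABLE1_F_VALUES",
    "TABLE1_S_VALUES",
]

TABLE1_F_VALUES = (0.02, 0.05, 0.10, 0.25, 0.50, 1.0)
TABLE1_S_VALUES = (1e-4, 1e-3, 1e-2)


@dataclass(frozen=True)
class ExtremeFitness:
    """Fittest-likely fitness and its extreme-value bookkeeping.

    ``m_or_k`` is the mean count of fitness-reducing sites per individual
    (heterozygous AM sites for additive/general dominance, homozygous MM
    sites for recessive); ``r = c * sqrt(m_or_k)`` is the downward
    deviation of the fittest-likely individual's count.
    """

    scheme: Scheme
    m_or_k: float
    r: float
    c: float
    w_max_likely: float
    w_max_likely_exact: float
    w_max_ideal: float


@dataclass(frozen=True)
class IdealizedMax:
    """Fitness of the idealized mutation-free individual: exact product
    form and its exponential asymptote."""

    exact: float
    asymptotic: float

    def __float__(self) -> float:
        return self.exact


@dataclass(frozen=True)
class LoadMetrics:
    """Mutational-load measures relative to a chosen fitness optimum."""

    L_crow: float
    L_haldane: float
    ratio: float


def extreme_multiplier(N: float, mode: str = "paper") -> float:
    """Extreme-value multiplier ``c`` for a population of size ``N``.

    ``mode='paper'`` returns the conservative constant 5 used for
    ``N = 1e9``.  ``mode='quantile'`` returns the standard-normal quantile
    at ``1 - 1/N`` — the count threshold exceeded by about one individual
    in ``N`` — as an extension for other population sizes.
    """
    if N < 2:
        raise ParameterError("N: extreme multiplier requires N >= 2")
    if mode == "paper":
        return 5.0
    if mode == "quantile":
        return float(norm.ppf(1.0 - 1.0 / N))
    raise ValueError(f"mode must be 'paper' or 'quantile', got {mode!r}")


def _log_ideal(params: LoadParameters) -> tuple[float, float]:
    """(log exact, log asymptotic) fitness of the mutation-free genotype."""
    n, u = params.n, params.u
    if params.scheme is Scheme.RECESSIVE:
        return -n * math.log1p(-u), n * u
    return -n * math.log1p(-2 * u), 2 * n * u


def idealized_max(params: LoadParameters) -> IdealizedMax:
    """Fitness of the individual wild-type at every functional site
    (additive: ``(1-2u)^-n ~ exp(2nu)``); for the recessive scheme, of the
    individual with no mutant homozygous site (``(1-u)^-n ~ exp(nu)``).

    Computed in log space; for human-scale parameters the exact and
    asymptotic forms agree to several digits.
    """
    log_exact, log_asym = _log_ideal(params)
    return IdealizedMax(exact=math.exp(log_exact), asymptotic=math.exp(log_asym))


def fittest_likely(params: LoadParameters, c: float = 5.0) -> ExtremeFitness:
    """Fitness of the fittest individual likely to exist among ``N``.

    The exact product form evaluates the genotype that is ``c*sqrt(mean)``
    mutant-site counts below the mean (mutant homozygous sites are ignored
    in the additive calculation — their expected count is order ``u**2``);
    the asymptotic form is ``exp(c * sigma)`` with ``sigma^2`` the log-
    fitness variance (``exp(c*sqrt(nus))`` for additive and recessive
    alike).
    """
    if c <= 0:
        raise ParameterError("c: extreme multiplier must be positive")
    n, u, s, h = params.n, params.u, params.s, params.h
    log_ideal_exact, _ = _log_ideal(params)
    if params.scheme is Scheme.RECESSIVE:
        mean_count = n * u / s  # k: mean number of MM sites
        per_site_log = math.log1p(-s)
    elif params.scheme is Scheme.ADDITIVE:
        mean_count = 4 * n * u / s  # m: mean number of AM sites
        per_site_log = math.log1p(-0.5 * s)
    else:
        if h == 0:
            raise ParameterError("h: use scheme=recessive for h=0")
        mean_count = 2 * n * u / (h * s)
        per_site_log = math.log1p(-h * s)
    r = c * math.sqrt(mean_count)
    count = max(mean_count - r, 0.0)
    log_exact = log_ideal_exact + count * per_site_log
    sigma2 = lognormal_parameters(params).sigma2_log
    return ExtremeFitness(
        scheme=params.scheme,
        m_or_k=mean_count,
        r=r,
        c=c,
        w_max_likely=math.exp(c * math.sqrt(sigma2)),
        w_max_likely_exact=math.exp(log_exact),
        w_max_ideal=math.exp(log_ideal_exact),
    )


def idealized_z_score(params: LoadParameters) -> float:
    """How many standard deviations of ``W`` the idealized mutation-free
    fitness lies above the mean of 1."""
    var = variance_asymptotic(params)
    if var == 0:
        raise ParameterError("u: z-score undefined when the fitness variance is 0")
    return (idealized_max(params).exact - 1.0) / math.sqrt(var)


def load_metrics(
    params: LoadParameters, which: str = "ideal", c: float = 5.0
) -> LoadMetrics:
    """Load measures for the chosen fitness optimum.

    ``which`` selects the ``w_max`` entering the Crow load
    ``L = (w_max - w_bar)/w_max``: ``'ideal'`` (the mutation-free
    genotype — the classic, in our view unrealistic, choice) or
    ``'likely'`` (the fittest individual likely to exist).  The Haldane
    load ``1 - exp(-2nu)`` (``1 - exp(-nu)`` recessive) is independent of
    ``s`` and always refers to the idealized optimum.  Mean fitness is 1
    by normalization, so the max-to-mean ratio equals ``w_max``.
    """
    ext = fittest_likely(params, c=c)
    if which == "ideal":
        w_max = ext.w_max_ideal
    elif which == "likely":
        w_max = ext.w_max_likely_exact
    else:
        raise ValueError(f"which must be 'ideal' or 'likely', got {which!r}")
    _, log_asym = _log_ideal(params)
    return LoadMetrics(
        L_crow=(w_max - 1.0) / w_max,
        L_haldane=-math.expm1(-log_asym),
        ratio=w_max,
    )


def table1_grid(
    f_values: Sequence[float] = TABLE1_F_VALUES,
    s_values: Sequence[float] = TABLE1_S_VALUES,
    params: LoadParameters | None = None,
    c: float = 5.0,
) -> pd.DataFrame:
    """Fittest-likely fitness ``exp(c*sqrt(nus))`` over a grid of
    functional fractions (columns) and selection coefficients (rows), with
    a bottom ``All sites AA`` row giving the idealized ``exp(2nu)``.

    ``params`` supplies ``g``, ``u`` and ``N`` (canonical defaults if
    omitted); the grid applies to additive and recessive schemes alike.
    """
    from mutload.parameters import make_parameters

    if len(f_values) == 0 or len(s_values) == 0:
        raise ParameterError("f_values/s_values: grids must be non-empty")
    base = params if params is not None else make_parameters()
    rows = {}
    for s in s_values:
        p = base.with_(s=s, scheme=Scheme.ADDITIVE)
        rows[s] = [
            fittest_likely(p.with_(f=f), c=c).w_max_likely for f in f_values
        ]
    ideal = [
        idealized_max(base.with_(f=f, scheme=Scheme.ADDITIVE)).asymptotic
        for f in f_values
    ]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(f_values))
    frame.loc["All sites AA"] = ideal
    frame.index.name = "s"
    frame.columns.name = "f"
    return frame


def _format_cell(x: float) -> str:
    # 2 decimals for small values, 2-significant-digit scientific above 1e3
    if x < 1e3:
        return f"{x:.2f}"
    exponent = math.floor(math.log10(x))
    mantissa = x / 10**exponent
    return f"{mantissa:.1f}e{exponent:d}"


def format_table1(grid: pd.DataFrame) -> pd.DataFrame:
    """Render a :func:`table1_grid` frame as display strings."""
    return grid.map(_format_cell)
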