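"""Monte-Carlo population sampler for whole-genome fitness.

Individuals are sampled i.i.d. from the equilibrium genotype frequencies:
per individual, the counts ``(x, y, z)`` of wild-type homozygous (AA),
heterozygous (AM) and mutant homozygous (MM) sites follow a multinomial
over the ``n`` sites.  Because the AM and MM frequencies are tiny, the
default sampler draws ``y`` and ``z`` as independent Poisson variates with
means ``n*p_AM`` and ``n*p_MM`` (the same approximation the analytic
extreme-value argument relies on); exact multinomial sampling is provided
as a cross-check for ``n <= 1e6``.  Fitness is then assembled in log
space, e.g. additive

    log w = -n*log(1-2u) + y*log(1-s/2) + z*log(1-s).

No per-site genome is represented: with no linkage disequilibrium the
counts are sufficient, and ``n ~ 1e8``--``1e9`` sites per individual are
tractable only this way.  Mutant homozygotes ARE simulated even though the
analytic additive extreme calculation neglects them, so the simulation
independently validates that neglect.

Randomness: one root seed; replicate substreams are spawned
deterministically by counter via ``numpy.random.SeedSequence`` (PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mutload.parameters import LoadParameters, ParameterError, Scheme
from mutload.equilibrium import genotype_table
from mutload.extremes import extreme_multiplier, fittest_likely

__all__ = [
    "GenotypeCounts",
    "PopulationSample",
    "sample_counts",
    "sample_fitness",
    "figure1_histograms",
    "empirical_max_check",
    "EmpiricalMaxCheck",
]

#: Exact multinomial sampling is offered only up to this many sites.
MULTINOMIAL_N_MAX = 10**6


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of AA (x), AM (y) and MM (z) sites for one individual."""

    x: int
    y: int
    z: int

    @property
    def n(self) -> int:
        return self.x + self.y + self.z


@dataclass(frozen=True)
class PopulationSample:
    """Simulated whole-genome fitnesses of ``M`` individuals."""

    fitnesses: np.ndarray
    log_fitnesses: np.ndarray
    counts_y: np.ndarray
    counts_z: np.ndarray
    params: LoadParameters
    seed: int
    M: int

    @property
    def mean(self) -> float:
        return float(self.fitnesses.mean())

    @property
    def variance(self) -> float:
        return float(self.fitnesses.var(ddof=1))


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, *stream])))


def _count_arrays(
    params: LoadParameters,
    M: int,
    rng: np.random.Generator,
    method: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Draw (y, z) site-count arrays for M individuals; returns (y, z, n_int)."""
    if M < 1:
        raise ParameterError("M: need at least one individual")
    table = genotype_table(params)
    n_int = round(params.n)
    if method == "poisson":
        mean_y = n_int * table.p_AM
        mean_z = n_int * table.p_MM
        if not (math.isfinite(mean_y) and math.isfinite(mean_z)):
            raise ParameterError("n*p: Poisson means must be finite")
        y = rng.poisson(mean_y, size=M)
        z = rng.poisson(mean_z, size=M)
    elif method == "multinomial":
        if n_int > MULTINOMIAL_N_MAX:
            raise ParameterError(
                f"n: exact multinomial sampling limited to n <= {MULTINOMIAL_N_MAX}"
            )
        probs = np.asarray(table.frequencies, dtype=float)
        probs = probs / probs.sum()  # guard rounding in the truncated freqs
        draws = rng.multinomial(n_int, probs, size=M)
        y, z = draws[:, 1], draws[:, 2]
    else:
        raise ValueError(f"method must be 'poisson' or 'multinomial', got {method!r}")
    return y, z, n_int


def sample_counts(
    params: LoadParameters,
    M: int,
    seed: int,
    method: str = "poisson",
) -> list[GenotypeCounts]:
    """Sample per-individual genotype-site counts from equilibrium.

    ``method='poisson'`` (default) draws the heterozygous and mutant-
    homozygous counts as independent Poissons; ``method='multinomial'``
    draws the exact multinomial (``n <= 1e6`` only).
    """
    y, z, n_int = _count_arrays(params, M, _rng(seed), method)
    return [
        GenotypeCounts(x=int(n_int - yi - zi), y=int(yi), z=int(zi))
        for yi, zi in zip(y, z)
    ]


def _log_fitness(
    params: LoadParameters, y: np.ndarray, z: np.ndarray
) -> np.ndarray:
    u, s, h = params.u, params.s, params.h
    n = params.n
    if params.scheme is Scheme.ADDITIVE:
        base = -n * math.log1p(-2 * u)
        return base + y * math.log1p(-0.5 * s) + z * math.log1p(-s)
    if params.scheme is Scheme.RECESSIVE:
        base = -n * math.log1p(-u)
        return base + z * math.log1p(-s)
    if h == 0:
        raise ParameterError("h: use scheme=recessive for h=0")
    base = -n * math.log1p(-2 * u)
    return base + y * math.log1p(-h * s) + z * math.log1p(-s)


def sample_fitness(
    params: LoadParameters,
    M: int,
    seed: int,
    method: str = "poisson",
) -> PopulationSample:
    """Sample the whole-genome fitnesses of ``M`` individuals.

    Deterministic for fixed ``(params, M, seed, method)``.
    """
    y, z, _ = _count_arrays(params, M, _rng(seed), method)
    logw = _log_fitness(params, y.astype(float), z.astype(float))
    return PopulationSample(
        fitnesses=np.exp(logw),
        log_fitnesses=logw,
        counts_y=y,
        counts_z=z,
        params=params,
        seed=seed,
        M=M,
    )


#: Number of fixed-width histogram bins used for the fitness distributions.
HISTOGRAM_BINS = 200


def figure1_histograms(
    params: LoadParameters | None = None,
    s_values: Sequence[float] = (1e-4, 1e-3, 1e-2),
    M: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned simulated fitness distributions across selection coefficients.

    For each ``s`` the fitness of ``M`` individuals is sampled (default
    parameters use ``f = 0.25``, the canonical illustration) and binned
    into :data:`HISTOGRAM_BINS` fixed-width bins on
    ``[0, max(3, 1.2*exp(5*sqrt(nus)))]``.  The frame carries columns
    ``s, bin_left, bin_right, frequency, w_max_likely`` where
    ``w_max_likely`` is the analytic fittest-likely marker
    ``exp(5*sqrt(nus))``; frequencies sum to 1 per ``s``.
    """
    from mutload.parameters import make_parameters

    if params is None:
        params = make_parameters(f=0.25)
    if len(s_values) == 0:
        raise ParameterError("s_values: grid must be non-empty")
    frames = []
    for i, s in enumerate(sorted(s_values)):
        p = params.with_(s=s)
        marker = fittest_likely(p, c=5.0).w_max_likely
        sample = sample_fitness(p, M, seed=seed, method="poisson")
        top = max(3.0, 1.2 * marker)
        edges = np.linspace(0.0, top, HISTOGRAM_BINS + 1)
        hist, _ = np.histogram(np.clip(sample.fitnesses, 0, top), bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "s": s,
                    "bin_left": edges[:-1],
                    "bin_right": edges[1:],
                    "frequency": hist / M,
                    "w_max_likely": marker,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EmpiricalMaxCheck:
    """Replicate maxima of simulated fitness versus the analytic extreme."""

    empirical_maxima: np.ndarray
    analytic: float
    c: float
    N_small: int
    replicates: int

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.empirical_maxima, [25, 75])
        return float(lo), float(hi)

    @property
    def agrees(self) -> bool:
        lo, hi = self.iqr
        return lo <= self.analytic <= hi


def empirical_max_check(
    params: LoadParameters,
    N_small: int,
    replicates: int,
    seed: int,
) -> EmpiricalMaxCheck:
    """Compare the maximum simulated fitness among ``N_small`` individuals
    with the analytic fittest-likely product form.

    The analytic prediction uses the normal quantile at ``1 - 1/N_small``
    as the extreme-value multiplier (the constant 5 is calibrated to
    ``N = 1e9``, not desk-scale populations).  Agreement is declared when
    the analytic value falls inside the interquartile range of the
    replicate maxima.
    """
    if N_small > 10**7:
        raise ParameterError("N_small: empirical check limited to N_small <= 1e7")
    if replicates < 1:
        raise ParameterError("replicates: need at least one replicate")
    c = extreme_multiplier(N_small, mode="quantile") if N_small >= 2 else 0.0
    analytic = fittest_likely(params, c=c).w_max_likely_exact if c > 0 else 1.0
    maxima = np.empty(replicates)
    for rep in range(replicates):
        rng = _rng(seed, rep)
        y, z, _ = _count_arrays(params, N_small, rng, "poisson")
        logw = _log_fitness(params, y.astype(float), z.astype(float))
        maxima[rep] = math.exp(float(logw.max()))
    return EmpiricalMaxCheck(
        empirical_maxima=maxima,
        analytic=analytic,
        c=c,
        N_small=N_small,
        replicates=replicates,
    )
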