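"""Per-site genotype fitnesses and mutation-selection-balance frequencies.

All sites share the same ``u`` and ``s``, so a single per-site genotype
table describes the whole genome.  Fitnesses are normalized so that the
population mean per-site fitness is exactly 1 (constant population size);
frequencies are the standard truncated balance solutions with terms of
order ``u**2`` kept exactly as written (e.g. the additive MM frequency is
``(2u/s)**2``), because the downstream closed forms rely on these
expressions.  Back mutation M -> A is neglected throughout.

Scheme summary (A wild type, M deleterious; allele frequency of M at
balance is ``q``):

========== =================== =========================================
scheme      q at balance        normalized fitness (AA, AM, MM)
========== =================== =========================================
additive    ``2u/s``            ``(1-2u)^-1 * (1, 1-s/2, 1-s)``
recessive   ``sqrt(u/s)``       ``(1-u)^-1  * (1, 1,     1-s)``
general_h   ``u/(h*s)``         ``(1-2u)^-1 * (1, 1-h*s, 1-s)``
========== =================== =========================================

Genotype frequencies are Hardy-Weinberg in ``q``, except the recessive MM
frequency which is written ``u/s`` (= q**2) directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from mutload.parameters import LoadParameters, ParameterError, Scheme

__all__ = ["GenotypeTable", "genotype_table", "wildtype_free_log_probability"]


@dataclass(frozen=True)
class GenotypeTable:
    """Normalized per-site fitnesses and equilibrium genotype frequencies."""

    scheme: Scheme
    w_AA: float
    w_AM: float
    w_MM: float
    p_AA: float
    p_AM: float
    p_MM: float

    @property
    def fitnesses(self) -> tuple[float, float, float]:
        return (self.w_AA, self.w_AM, self.w_MM)

    @property
    def frequencies(self) -> tuple[float, float, float]:
        return (self.p_AA, self.p_AM, self.p_MM)

    def mean_fitness(self) -> float:
        """Frequency-weighted mean fitness (1 up to order-u**2 truncation)."""
        return math.fsum(p * w for p, w in zip(self.frequencies, self.fitnesses))


def genotype_table(params: LoadParameters) -> GenotypeTable:
    """Return the per-site :class:`GenotypeTable` for the parameter scheme.

    Raises
    ------
    ParameterError
        For ``general_h`` with ``h = 0``: the partial-dominance balance
        frequency ``u/(h*s)`` diverges there; use ``scheme=recessive``.
    """
    u, s, h = params.u, params.s, params.h
    scheme = params.scheme
    if scheme is Scheme.ADDITIVE:
        q = 2 * u / s
        norm = 1.0 / (1.0 - 2 * u)
        w = (norm, norm * (1 - 0.5 * s), norm * (1 - s))
        freqs = ((1 - q) ** 2, 2 * q * (1 - q), q**2)
    elif scheme is Scheme.RECESSIVE:
        q = math.sqrt(u / s)
        norm = 1.0 / (1.0 - u)
        w = (norm, norm, norm * (1 - s))
        freqs = ((1 - q) ** 2, 2 * q * (1 - q), u / s)
    elif scheme is Scheme.GENERAL_H:
        if h == 0:
            raise ParameterError(
                "h: h=0 has no partial-dominance equilibrium (u/(h*s) diverges); "
                "use scheme=recessive"
            )
        q = u / (h * s)
        norm = 1.0 / (1.0 - 2 * u)
        w = (norm, norm * (1 - h * s), norm * (1 - s))
        freqs = ((1 - q) ** 2, 2 * q * (1 - q), q**2)
    else:  # pragma: no cover
        raise ParameterError(f"scheme: unknown scheme {scheme}")
    return GenotypeTable(scheme, *w, *freqs)


def wildtype_free_log_probability(params: LoadParameters) -> float:
    """Natural log of the probability that a random individual carries no
    fitness-reducing genotype at any of the ``n`` sites.

    Additive (and general dominance): the probability of being AA at every
    site, ``2n * log(1 - q)`` with ``q`` the balance frequency of M (the
    individual draws ``2n`` independent gametes free of M).  Recessive:
    heterozygotes are unaffected, so the relevant event is carrying no MM
    site, ``n * log(1 - u/s)``.

    Computed entirely in log space: for human-scale parameters the
    probability itself underflows (e.g. ``exp(-320)``).
    """
    u, s, h = params.u, params.s, params.h
    n = params.n
    if params.scheme is Scheme.ADDITIVE:
        return 2 * n * math.log1p(-2 * u / s)
    if params.scheme is Scheme.RECESSIVE:
        return n * math.log1p(-u / s)
    if h == 0:
        raise ParameterError("h: use scheme=recessive for h=0")
    return 2 * n * math.log1p(-u / (h * s))
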