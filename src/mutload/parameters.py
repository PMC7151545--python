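"""Model parameters for the mutational-load calculations.

The model describes ``n = (1/2) * f * g`` functional diploid sites in a
genome of ``g`` base pairs of which a fraction ``f`` is functional (the
factor 1/2 because a diploid site spans two homologous base pairs).  Each
site mutates from the wild-type allele A to a deleterious allele M at rate
``u`` per generation; ``u = v * p`` where ``v`` is the empirical per-base
mutation rate and ``p`` the probability that a mutation at a functional
site is deleterious.  The mutant homozygote MM has fitness reduced by a
factor ``1 - s``; the heterozygote's reduction depends on the scheme
(additive ``1 - s/2``, recessive ``1``, general dominance ``1 - h*s``).
``N`` is the number of reproducing individuals.

Canonical defaults are the human-genome values ``g = 6.4e9``,
``u = 5e-9``, ``s = 1e-2``, ``N = 1e9`` with ``v = 1.2e-8`` and
``p = 0.4``.  Note ``v * p = 4.8e-9``; the canonical rate is the rounded
``5e-9``, which every headline number downstream assumes, so the default
sets ``u`` directly rather than deriving it.  ``u = v * p`` is computed
only when the caller supplies ``v`` and ``p`` but not ``u``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "Scheme",
    "LoadParameters",
    "make_parameters",
    "nus_product",
    "read_config",
    "write_config",
    "DEFAULT_G",
    "DEFAULT_U",
    "DEFAULT_V",
    "DEFAULT_P",
    "DEFAULT_S",
    "DEFAULT_N",
    "DEFAULT_F",
]

DEFAULT_G = 6.4e9
DEFAULT_V = 1.2e-8
DEFAULT_P = 0.4
DEFAULT_U = 5e-9
DEFAULT_S = 1e-2
DEFAULT_N = 1e9
#: The functional fraction has no canonical value (it is the quantity the
#: load argument seeks to bound); 0.05 is the running-example value used
#: throughout the worked numbers.
DEFAULT_F = 0.05


class Scheme(str, enum.Enum):
    """Per-site fitness scheme for the heterozygote.

    ``additive`` is the no-dominance case (heterozygote fitness ``1 - s/2``),
    ``recessive`` gives the heterozygote full wild-type fitness, and
    ``general_h`` scales the heterozygous effect by a dominance coefficient
    ``h`` (``h = 1/2`` reproduces ``additive``).  ``recessive`` is a distinct
    scheme rather than ``general_h`` with ``h = 0`` because the balance
    frequency under partial dominance, ``u/(h*s)``, diverges as ``h -> 0``
    while the true recessive equilibrium allele frequency is ``sqrt(u/s)``.
    """

    ADDITIVE = "additive"
    RECESSIVE = "recessive"
    GENERAL_H = "general_h"


class ParameterError(ValueError):
    """Raised when a parameter set is invalid; names the offending field."""


@dataclass(frozen=True)
class LoadParameters:
    """Validated parameter set shared by every model computation.

    Attributes
    ----------
    g : float
        Diploid genome size in base pairs.
    f : float
        Functional fraction of the genome, in (0, 1].
    v : float
        Empirical per-base mutation rate per generation.
    p : float
        Probability that a mutation at a functional site is deleterious.
    u : float
        Deleterious mutation rate per functional site per generation.
    s : float
        Selection coefficient against the mutant homozygote, in (0, 1).
    h : float
        Dominance coefficient in [0, 1]; ``h = 1/2`` is additive.
    N : float
        Number of reproducing individuals.
    scheme : Scheme
        Per-site fitness scheme.

    ``n``, the number of functional diploid sites, is derived as
    ``f * g / 2`` and kept as a real number: the closed-form results treat
    it continuously, and only the population sampler rounds it.
    """

    g: float
    f: float
    v: float
    p: float
    u: float
    s: float
    h: float
    N: float
    scheme: Scheme

    def __post_init__(self) -> None:
        object.__setattr__(self, "scheme", Scheme(self.scheme))
        _validate(self)

    @property
    def n(self) -> float:
        """Number of functional diploid sites, ``(1/2) * f * g``."""
        return 0.5 * self.f * self.g

    @property
    def nu(self) -> float:
        """Per-genome deleterious mutation rate ``n * u``."""
        return self.n * self.u

    @property
    def nus(self) -> float:
        """``n * u * s`` — the variance of log fitness at equilibrium."""
        return self.n * self.u * self.s

    def with_(self, **changes: Any) -> "LoadParameters":
        """Return a copy with the given fields replaced and re-validated."""
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["scheme"] = self.scheme.value
        return d


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{field}: {msg}")


def _validate(params: LoadParameters) -> None:
    _require(params.g > 0, "g", "genome size must be positive")
    _require(0 < params.f <= 1, "f", "functional fraction must be in (0, 1]")
    _require(0 <= params.v <= 1, "v", "mutation rate must be in [0, 1]")
    _require(0 <= params.p <= 1, "p", "deleterious probability must be in [0, 1]")
    _require(0 <= params.u < 1, "u", "deleterious rate must be in [0, 1)")
    _require(0 < params.s < 1, "s", "selection coefficient must be in (0, 1)")
    _require(0 <= params.h <= 1, "h", "dominance coefficient must be in [0, 1]")
    _require(params.N >= 1, "N", "population size must be at least 1")
    # Equilibrium allele frequencies must stay below 1 for the truncated
    # balance solutions to make sense.
    if params.scheme is Scheme.ADDITIVE:
        if params.s <= 2 * params.u:
            raise ParameterError(
                "s: equilibrium undefined — additive balance requires s > 2u"
            )
    elif params.scheme is Scheme.RECESSIVE:
        if params.u / params.s >= 1:
            raise ParameterError(
                "s: equilibrium undefined — recessive balance requires u/s < 1"
            )
    elif params.scheme is Scheme.GENERAL_H:
        if params.h > 0 and params.u / (params.h * params.s) >= 1:
            raise ParameterError(
                "s: equilibrium undefined — balance requires u/(h*s) < 1"
            )


def make_parameters(
    g: float = DEFAULT_G,
    f: float = DEFAULT_F,
    v: float = DEFAULT_V,
    p: float = DEFAULT_P,
    s: float = DEFAULT_S,
    h: float = 0.5,
    N: float = DEFAULT_N,
    scheme: Scheme | str = Scheme.ADDITIVE,
    u: float | None = None,
) -> LoadParameters:
    """Build a validated :class:`LoadParameters`.

    With no arguments this yields the canonical human-genome parameter set
    (``g = 6.4e9``, ``u = 5e-9``, ``s = 1e-2``, ``N = 1e9``, additive).
    ``u`` defaults to the canonical rounded rate ``5e-9`` whenever ``v`` and
    ``p`` are both left at their defaults; if either is overridden and ``u``
    is not given, ``u = v * p`` is derived.
    """
    if u is None:
        if v == DEFAULT_V and p == DEFAULT_P:
            u = DEFAULT_U
        else:
            u = v * p
    return LoadParameters(g=g, f=f, v=v, p=p, u=u, s=s, h=h, N=N, scheme=Scheme(scheme))


def nus_product(params: LoadParameters) -> float:
    """Return ``n * u * s`` for the parameter set."""
    return params.nus


_CONFIG_KEYS = ("g", "f", "v", "p", "u", "s", "h", "N", "scheme")


def _from_mapping(data: Mapping[str, Any]) -> LoadParameters:
    unknown = set(data) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: data[k] for k in _CONFIG_KEYS if k in data}
    return make_parameters(**kwargs)


def read_config(path: str | Path) -> LoadParameters:
    """Read a parameter set from a JSON or YAML config file.

    Recognized keys are exactly ``g, f, v, p, u, s, h, N, scheme``; missing
    keys take the canonical defaults.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ParameterError(f"config {path} does not contain a mapping")
    return _from_mapping(data)


def write_config(params: LoadParameters, path: str | Path) -> None:
    """Write a parameter set to JSON or YAML; round-trips bit-exactly."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _check_finite(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ParameterError(f"{name}: not finite")
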