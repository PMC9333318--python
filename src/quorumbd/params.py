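"""Model parameters, regulation strategies, and signaling modes.

The model describes a well-mixed bacterial population of public-good
*producers* (count ``n``) and *cheaters* (count ``m``) evolving as a
two-dimensional birth-death process.  All rate constants are expressed in
units of the maximal public-good birth benefit ``g`` (set to 1 by default,
so one time unit is the inverse of that maximal benefit).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Union

__all__ = [
    "ModelParameters",
    "Strategy",
    "SignalingMode",
    "SYMBOLIC_ZERO",
    "SYMBOLIC_INFINITY",
    "DEFAULTS",
]

# Symbolic half-max values: exact algebraic limits of the activation Hill
# factor (never represented as extreme floats, which would overflow in
# (x/K)^h).
SYMBOLIC_ZERO = "zero"
SYMBOLIC_INFINITY = "infinity"

KaValue = Union[float, str]


class Strategy(str, enum.Enum):
    """Public-good regulation strategy of the producer strain.

    QS  -- quorum sensing: production activates through a Hill function of
           the signaling population with half-max ``Ka`` and exponent ``ha``.
    AO  -- always on: activation factor identically 1 (limit Ka -> 0).
    NP  -- no production: activation factor identically 0 (limit Ka -> inf).
    """

    QS = "QS"
    AO = "AO"
    NP = "NP"


class SignalingMode(str, enum.Enum):
    """Who contributes autoinducer to the quorum signal.

    producers_only          -- activation argument is the producer count n.
    producers_and_cheaters  -- cheaters signal too: activation argument n + m.
    """

    PRODUCERS_ONLY = "producers_only"
    PRODUCERS_AND_CHEATERS = "producers_and_cheaters"


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants and Hill parameters of the birth-death model.

    Attributes
    ----------
    lambda0:
        Constitutive per-capita birth rate from an alternative nutrient
        source (time^-1, >= 0).
    g:
        Maximal per-capita birth benefit from the public good (time^-1);
        fixed to 1 by convention so that all rates are in units of g.
    a:
        Producer advantage: extra benefit accruing only to producers, e.g.
        through spatial co-localization (time^-1, >= 0).
    c:
        Maximal per-capita cost of public-good production (time^-1,
        0 <= c <= 1, i.e. at most the full public-good benefit).
    mu0:
        Density-dependent death-rate constant (time^-1 individual^-1, > 0);
        the per-capita death rate is mu0 * (n + m).
    Kg:
        Producer count at which the public-good benefit is half-maximal.
    hg:
        Hill exponent of the benefit function (> 0).
    Ka:
        Signaling count at which production is half-maximal; a positive
        float, or the symbolic strings ``"zero"`` / ``"infinity"`` for the
        exact AO / NP limits.
    ha:
        Hill exponent of the activation function (> 0).
    """

    lambda0: float = 0.2
    g: float = 1.0
    a: float = 0.0
    c: float = 0.15
    mu0: float = 0.01
    Kg: float = 15.0
    hg: float = 2.0
    Ka: KaValue = 15.0
    ha: float = 2.0

    def __post_init__(self) -> None:
        if self.lambda0 < 0:
            raise ValueError(f"lambda0 must be >= 0, got {self.lambda0}")
        if self.g < 0:
            raise ValueError(f"g must be >= 0, got {self.g}")
        if self.a < 0:
            raise ValueError(f"a must be >= 0, got {self.a}")
        if not 0 <= self.c <= 1:
            raise ValueError(f"c must lie in [0, 1], got {self.c}")
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be > 0, got {self.mu0}")
        if not self.Kg > 0:
            raise ValueError(f"Kg must be > 0, got {self.Kg}")
        if not self.hg > 0:
            raise ValueError(f"hg must be > 0, got {self.hg}")
        if not self.ha > 0:
            raise ValueError(f"ha must be > 0, got {self.ha}")
        if isinstance(self.Ka, str):
            if self.Ka not in (SYMBOLIC_ZERO, SYMBOLIC_INFINITY):
                raise ValueError(
                    f"symbolic Ka must be '{SYMBOLIC_ZERO}' or "
                    f"'{SYMBOLIC_INFINITY}', got {self.Ka!r}"
                )
        elif not (isinstance(self.Ka, (int, float)) and self.Ka > 0 and math.isfinite(self.Ka)):
            raise ValueError(f"Ka must be a positive finite number or symbolic, got {self.Ka!r}")

    def with_(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


#: Default parameter set used when a configuration omits values.
DEFAULTS = ModelParameters()
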