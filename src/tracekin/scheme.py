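"""Kinetic schemes for multi-step single-molecule reactions.

A :class:`KineticScheme` describes a continuous-time Markov chain over a
small set of chemical states (substrate ``S``, intermediates ``IM1``/``IM2``,
product ``P``, plus a photophysical ``BLEACHED`` sink).  Rate constants are
either unimolecular (s^-1) or bimolecular (M^-1 s^-1); a bimolecular rate is
coupled to one solution species (catalyst or diene) whose concentration is
held per-molecule constant, so each experimental condition reduces the scheme
to a pseudo-first-order chain via :func:`effective_rates`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ALL_STATES",
    "Condition",
    "RateSpec",
    "KineticScheme",
    "effective_rates",
]

#: Recognised state labels, in canonical (brightest-convention) order.
ALL_STATES = ("S", "IM1", "IM2", "P", "BLEACHED")

_ORDERS = ("unimolecular", "bimolecular")
_SPECIES = ("catalyst", "diene", "none")


@dataclass(frozen=True)
class Condition:
    """One experimental condition: catalyst identity and concentrations (mM)."""

    catalyst_label: str = "cat"
    catalyst_conc_mM: float = 0.0
    diene_conc_mM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("catalyst_conc_mM", "diene_conc_mM"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")

    def key(self) -> tuple:
        return (self.catalyst_label, self.catalyst_conc_mM, self.diene_conc_mM)


@dataclass(frozen=True)
class RateSpec:
    """A single rate constant.

    ``value`` is in s^-1 for unimolecular steps and M^-1 s^-1 for bimolecular
    steps; ``coupled_species`` names the concentration a bimolecular rate
    multiplies ("catalyst" or "diene").
    """

    value: float
    order: str = "unimolecular"
    coupled_species: str = "none"

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(f"rate value must be finite and >= 0, got {self.value!r}")
        if self.order not in _ORDERS:
            raise ValueError(f"order must be one of {_ORDERS}, got {self.order!r}")
        if self.coupled_species not in _SPECIES:
            raise ValueError(
                f"coupled_species must be one of {_SPECIES}, got {self.coupled_species!r}"
            )
        if self.order == "bimolecular" and self.coupled_species == "none":
            raise ValueError("bimolecular rates must name a coupled species")
        if self.order == "unimolecular" and self.coupled_species != "none":
            raise ValueError("unimolecular rates cannot carry a coupled species")


@dataclass(frozen=True)
class KineticScheme:
    """States, allowed transitions and rate constants of the reaction network."""

    states: tuple[str, ...]
    rates: dict[tuple[str, str], RateSpec] = field(default_factory=dict)
    absorbing: frozenset[str] = frozenset({"P", "BLEACHED"})

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        if not self.states:
            raise ValueError("scheme needs at least one state")
        unknown = set(self.states) - set(ALL_STATES)
        if unknown:
            raise ValueError(f"unknown state labels: {sorted(unknown)}")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state labels")
        # P and BLEACHED are sinks whenever present.
        for sink in ("P", "BLEACHED"):
            if sink in self.states and sink not in self.absorbing:
                raise ValueError(f"{sink} must be absorbing")
        for (src, dst), spec in self.rates.items():
            if src == dst:
                raise ValueError(f"self-transition {src}->{dst} not allowed")
            if src not in self.states or dst not in self.states:
                raise ValueError(f"transition {src}->{dst} uses undeclared state")
            if src in self.absorbing and spec.value > 0:
                raise ValueError(f"absorbing state {src} cannot have exits")
            if not isinstance(spec, RateSpec):
                raise TypeError("rates values must be RateSpec")


def effective_rates(
    scheme: KineticScheme, cond: Condition
) -> dict[tuple[str, str], float]:
    """Pseudo-first-order rates (s^-1) of *scheme* under condition *cond*.

    Unimolecular rates pass through unchanged; bimolecular rates are
    multiplied by their coupled concentration converted from mM to M, so a
    zero concentration switches the coupled transition off.
    """
    conc_M = {
        "catalyst": cond.catalyst_conc_mM / 1000.0,
        "diene": cond.diene_conc_mM / 1000.0,
    }
    out: dict[tuple[str, str], float] = {}
    for key, spec in scheme.rates.items():
        if spec.order == "unimolecular":
            out[key] = spec.value
        else:
            if spec.coupled_species not in conc_M:
                raise ValueError(
                    f"no concentration available for coupled species "
                    f"{spec.coupled_species!r} on transition {key}"
                )
            out[key] = spec.value * conc_M[spec.coupled_species]
    return out
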