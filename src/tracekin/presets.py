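"""Reference kinetic schemes for the iminium-catalysed Diels-Alder system.

The substrate S (a BODIPY-tagged alpha,beta-enal) reversibly forms an
N,O-acetal intermediate IM1 with a secondary-amine catalyst, which dehydrates
reversibly to the iminium ion IM2; with a diene present, IM2 reacts
irreversibly to the cycloadduct P:

    S <=> IM1 <=> IM2 -> P

Catalyst addition (S -> IM1) and the Diels-Alder step (IM2 -> P) are
bimolecular, pseudo-first-order in catalyst and diene respectively; the other
steps are unimolecular.  The rate constants below are the single-molecule
estimates for the first-generation MacMillan catalyst ("mac") and for the
pyrrolidine control catalyst ("ctrl"), which differs only in its
product-formation constant.
"""

from __future__ import annotations

from .scheme import KineticScheme, RateSpec

__all__ = ["K_S_IM1", "K_IM1_S", "K_IM1_IM2", "K_IM2_IM1", "K_IM2_P", "reference_scheme"]

#: Bimolecular catalyst-addition constant, M^-1 s^-1.
K_S_IM1 = 23.75
#: Unimolecular reverse/forward constants, s^-1.
K_IM1_S = 0.21
K_IM1_IM2 = 0.20
K_IM2_IM1 = 0.22
#: Bimolecular product-formation constant (coupled to diene), M^-1 s^-1.
K_IM2_P = {"mac": 6.64, "ctrl": 3.82}


def reference_scheme(
    catalyst: str = "mac", *, include_product: bool = False
) -> KineticScheme:
    """The three-state equilibrium scheme, optionally with the product channel.

    Parameters
    ----------
    catalyst
        ``"mac"`` (MacMillan) or ``"ctrl"`` (pyrrolidine control); selects the
        IM2 -> P constant.  Irrelevant when ``include_product`` is False.
    include_product
        Add the absorbing product state P with its diene-coupled exit from
        IM2.  P emits at IM1's intensity level, so it is optically hidden.
    """
    if catalyst not in K_IM2_P:
        raise ValueError(f"catalyst must be one of {sorted(K_IM2_P)}, got {catalyst!r}")
    rates = {
        ("S", "IM1"): RateSpec(K_S_IM1, "bimolecular", "catalyst"),
        ("IM1", "S"): RateSpec(K_IM1_S),
        ("IM1", "IM2"): RateSpec(K_IM1_IM2),
        ("IM2", "IM1"): RateSpec(K_IM2_IM1),
    }
    states = ("S", "IM1", "IM2")
    if include_product:
        rates[("IM2", "P")] = RateSpec(K_IM2_P[catalyst], "bimolecular", "diene")
        states = ("S", "IM1", "IM2", "P")
    return KineticScheme(states=states, rates=rates)
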