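"""Tiny networks with known closed-form dynamics.

These generators emit 1–2 reaction networks whose solutions are textbook
closed forms (irreversible bimolecular binding, first-order transfer, a
single catalytic step), so every stage of the pipeline — engine, solver,
protocols, statistics — can be exercised against an analytic oracle without
the full apoptosis fixture.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .network import NetworkModel, ReactionDef, SpeciesDef, build_network

__all__ = ["toy_fixture_generator", "binding_pair_complex_closed_form"]


def toy_fixture_generator(
    kind: str,
    rates: Mapping[str, float],
    initials: Mapping[str, float],
) -> NetworkModel:
    """Build one of the documented toy networks.

    Kinds
    -----
    ``binding_pair``
        ``E + S <=> E:S`` (paradigm 3).  Rates: ``k_plus``, ``k_minus``;
        initials: ``E``, ``S`` (complex starts at 0).  With ``k_minus = 0``
        the complex follows the irreversible bimolecular closed form
        (:func:`binding_pair_complex_closed_form`).
    ``enzyme_chain``
        ``E + S <=> E:S -> E + P`` (paradigm 1).  Rates: ``k_plus``,
        ``k_minus``, ``k_cat``; initials: ``E``, ``S``.
    ``translocation_pair``
        ``A_src <=> A_dst`` (paradigm 4).  Rates: ``k_plus`` and optional
        ``k_minus`` (default 0); initials: ``A_src`` (``A_dst`` starts 0).
        From zero acceptor and ``k_minus = 0``,
        ``A_dst(t) = total (1 - exp(-k_plus t))``.
    """
    rates = dict(rates)
    initials = dict(initials)

    def pos(d: Mapping[str, float], keys) -> None:
        for k in keys:
            if not (d.get(k, 0.0) >= 0):
                raise ValueError(f"{k} must be >= 0")

    if kind == "binding_pair":
        pos(rates, ("k_plus", "k_minus")); pos(initials, ("E", "S"))
        # E is tagged as the ligand so exposure protocols can remove it
        species = [SpeciesDef("E", initial=initials["E"], role="ligand"),
                   SpeciesDef("S", initial=initials["S"], role="receptor"),
                   SpeciesDef("E:S")]
        reactions = [ReactionDef("bind", 3, enzyme="E", substrate="S", complex="E:S",
                                 k_plus=rates["k_plus"], k_minus=rates.get("k_minus", 0.0))]
    elif kind == "enzyme_chain":
        pos(rates, ("k_plus", "k_minus", "k_cat")); pos(initials, ("E", "S"))
        species = [SpeciesDef("E", initial=initials["E"]),
                   SpeciesDef("S", initial=initials["S"]),
                   SpeciesDef("E:S"), SpeciesDef("P")]
        reactions = [ReactionDef("catalyze", 1, enzyme="E", substrate="S",
                                 complex="E:S", product="P",
                                 k_plus=rates["k_plus"], k_minus=rates.get("k_minus", 0.0),
                                 k_cat=rates["k_cat"])]
    elif kind == "translocation_pair":
        pos(rates, ("k_plus",)); pos(initials, ("A_src",))
        species = [SpeciesDef("A_src", initial=initials["A_src"],
                              compartment="mitochondria"),
                   SpeciesDef("A_dst", initial=initials.get("A_dst", 0.0))]
        reactions = [ReactionDef("translocate", 4, substrate="A_src", product="A_dst",
                                 k_plus=rates["k_plus"], k_minus=rates.get("k_minus", 0.0))]
    else:
        raise ValueError(f"unknown toy kind {kind!r}")
    return build_network(species, reactions)


def binding_pair_complex_closed_form(
    t: np.ndarray, e0: float, s0: float, k_plus: float
) -> np.ndarray:
    """Complex amount for irreversible ``E + S -> E:S`` (k_minus = 0).

    With d = e0 - s0 != 0:
    ``ES(t) = e0 s0 (1 - exp(-d k t)) / (e0 - s0 exp(-d k t))``;
    in the equal-amounts limit it reduces to ``e0^2 k t / (1 + e0 k t)``.
    """
    t = np.asarray(t, dtype=float)
    if e0 == s0:
        return e0 * e0 * k_plus * t / (1.0 + e0 * k_plus * t)
    d = e0 - s0
    expm = np.exp(-d * k_plus * t)
    # ES(t) = e0*s0*(1 - exp(-d k t)) / (e0 - s0*exp(-d k t))
    return e0 * s0 * (1.0 - expm) / (e0 - s0 * expm)
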