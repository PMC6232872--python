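"""The TRAIL-to-cPARP extrinsic apoptosis network and its treatment scenarios.

The downstream cascade — DISC formation, caspase-8 activation, the
caspase-3/XIAP/PARP module, Bcl-2-family regulation of mitochondrial outer
membrane permeabilization (MOMP), Smac and cytochrome-c release, and the
apoptosome — is the well-established per-cell mass-action model of
TRAIL-induced apoptosis of Albeck and co-workers (EARM), transcribed
species-by-species into the repository fixture
``data/apoptosis_network.tsv``.  Only the receptor module (TRAIL/death
receptor amounts and binding rate constants) is replaced per treatment
scenario; every downstream parameter is shared by all scenarios.

Four built-in scenarios describe the treatment conditions compared in this
package (amounts in the surface-density bookkeeping of the source study,
rate constants in cm^2/(molecule s) and 1/s):

========================  =========  =========  ==========  ========  =========
scenario                  sigma_L    sigma_R    k_plus      k_minus   exposure
========================  =========  =========  ==========  ========  =========
soluble                   3.8e9      2e4        1.94e-12    1e-3      continuous
liposomal_static          2e11       2e9        9.1e-9      320       continuous
liposomal_shear_adhesion  2e11       2e9        1e-5        320       1e-3 s
liposomal_shear_no_adhesion 2e11     2e9        1e-5        2.4e5     continuous
========================  =========  =========  ==========  ========  =========

The shear+adhesion scenario models the brief E-selectin tether: ligand is
present for 1e-3 s at the unsheared (adhesion-reduced) off-rate, after which
free ligand is removed and the cascade runs on.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional

from .network import (
    NetworkModel,
    NetworkValidationError,
    ReactionDef,
    SpeciesDef,
    build_network,
    read_network_tsv,
    write_network_tsv,
)

__all__ = [
    "ScenarioConfig",
    "ConfiguredModel",
    "build_apoptosis_network",
    "load_apoptosis_network",
    "builtin_scenarios",
    "configure_scenario",
    "BINDING_REACTION",
    "REQUIRED_SPECIES",
    "SOLUBLE_RECEPTOR_PRESETS",
]

#: Label of the single reaction a scenario is allowed to touch.
BINDING_REACTION = "bind_TRAIL_DR"

#: Species the loaded fixture must contain (the ones the analyses read).
REQUIRED_SPECIES = (
    "TRAIL", "DR", "TRAIL:DR", "DR*", "C8", "C8*", "C3", "C3*", "C6",
    "XIAP", "XIAP:C3*", "C3Ub*", "C8*:C3", "C3*:C6", "Apop", "Apop:C3",
    "Apop:XIAP", "PARP", "C3*:PARP", "cPARP", "Smac", "CyC",
    "Bid", "tBid", "Bax", "Bcl2",
)

#: Receptor surface density presets for the soluble scenario.  The source
#: tabulates 2e4 #/cm^2 for the soluble row while the Methods-style
#: derivation from 1e4 receptors on a 4.8e-6 cm^2 cell gives 2e9 #/cm^2;
#: both are exposed, with the tabulated value as default.
SOLUBLE_RECEPTOR_PRESETS = {"table": 2e4, "derived": 2.1e9}

# mitochondrial compartment volume fraction of the source model; bimolecular
# rate constants inside the mitochondrial compartment are scaled by 1/v
MITO_VOLUME_FRACTION = 0.07


@dataclass(frozen=True)
class ScenarioConfig:
    """One treatment condition for the receptor module.

    ``exposure`` is ``None`` for continuous ligand presence, or the finite
    duration (s) after which free ligand is removed (E-selectin tether).
    """

    name: str
    sigma_L: float              # TRAIL surface density, molecules/cm^2
    sigma_R: float              # death-receptor surface density, molecules/cm^2
    k_plus: float               # association, cm^2/(molecule s)
    k_minus: float              # dissociation, 1/s
    exposure: Optional[float] = None

    def __post_init__(self) -> None:
        for f in ("sigma_L", "sigma_R", "k_plus", "k_minus"):
            if not (getattr(self, f) > 0):
                raise ValueError(f"{self.name}: {f} must be > 0")
        if self.exposure is not None and not (self.exposure > 0):
            raise ValueError(f"{self.name}: finite exposure must be > 0")


@dataclass(frozen=True, eq=False)
class ConfiguredModel:
    """A network with one scenario's receptor module substituted in."""

    model: NetworkModel
    scenario: ScenarioConfig
    overrides: dict = field(default_factory=dict)


def build_apoptosis_network(
    trail: float = 3000.0, dr: float = 200.0
) -> NetworkModel:
    """Construct the full extrinsic-apoptosis network in code.

    This is the authoritative builder for the shipped fixture file; the
    default receptor-module amounts and rates are the source model's own
    (50 ng/mL soluble-TRAIL conditions) and are replaced per scenario by
    :func:`configure_scenario`.  Amounts are molecules per cell.
    """
    v = MITO_VOLUME_FRACTION

    def sp(name, initial=0.0, compartment="cytosol", role="intracellular"):
        return SpeciesDef(name=name, compartment=compartment, initial=initial, role=role)

    species = [
        # receptor module (surface)
        sp("TRAIL", trail, "surface", "ligand"),
        sp("DR", dr, "surface", "receptor"),
        sp("TRAIL:DR", 0.0, "surface"),
        sp("DR*", 0.0, "surface"),
        sp("flip", 1e2),
        sp("flip:DR*"),
        # initiator caspase module
        sp("C8", 2e4),
        sp("DR*:C8", 0.0, "surface"),
        sp("C8*"),
        sp("BAR", 1e3),
        sp("BAR:C8*"),
        # executioner caspase / XIAP / PARP module
        sp("C3", 1e4),
        sp("C8*:C3"),
        sp("C3*"),
        sp("C6", 1e4),
        sp("C3*:C6"),
        sp("C6*"),
        sp("C6*:C8"),
        sp("XIAP", 1e5),
        sp("XIAP:C3*"),
        sp("C3Ub*"),
        sp("PARP", 1e6),
        sp("C3*:PARP"),
        sp("cPARP"),
        # Bcl-2 family / MOMP module
        sp("Bid", 4e4),
        sp("C8*:Bid"),
        sp("tBid"),
        sp("Bcl2c", 2e4),
        sp("tBid:Bcl2c"),
        sp("Bax", 1e5),
        sp("tBid:Bax"),
        sp("Bax*"),
        sp("MBax", 0.0, "mitochondria"),
        sp("Bcl2", 2e4, "mitochondria"),
        sp("MBax:Bcl2", 0.0, "mitochondria"),
        sp("Bax2", 0.0, "mitochondria"),
        sp("Bax2:Bcl2", 0.0, "mitochondria"),
        sp("Bax4", 0.0, "mitochondria"),
        sp("Bax4:Bcl2", 0.0, "mitochondria"),
        sp("M", 5e5, "mitochondria"),
        sp("Bax4:M", 0.0, "mitochondria"),
        sp("M*", 0.0, "mitochondria"),
        # mitochondria-to-cytosol messengers
        sp("mCyC", 5e5, "mitochondria"),
        sp("M*:mCyC", 0.0, "mitochondria"),
        sp("CyC_r", 0.0, "mitochondria"),
        sp("CyC"),
        sp("mSmac", 1e5, "mitochondria"),
        sp("M*:mSmac", 0.0, "mitochondria"),
        sp("Smac_r", 0.0, "mitochondria"),
        sp("Smac"),
        # apoptosome module
        sp("Apaf", 1e5),
        sp("CyC:Apaf"),
        sp("Apaf*"),
        sp("C9", 1e5),
        sp("Apop"),
        sp("Apop:C3"),
        sp("Apop:XIAP"),
        sp("Smac:XIAP"),
    ]

    def cat(label, E, S, ES, P, kf, kr=1e-3, kc=1.0):
        return ReactionDef(label=label, paradigm=1, enzyme=E, substrate=S,
                           complex=ES, product=P, k_plus=kf, k_minus=kr, k_cat=kc)

    def conv(label, E, S, ES, P, kf, kr, kc):
        return ReactionDef(label=label, paradigm=2, enzyme=E, substrate=S,
                           complex=ES, product=P, k_plus=kf, k_minus=kr, k_cat=kc)

    def bind(label, E, S, ES, kf, kr=1e-3):
        return ReactionDef(label=label, paradigm=3, enzyme=E, substrate=S,
                           complex=ES, k_plus=kf, k_minus=kr)

    def transloc(label, src, dst, kf=1e-2, kr=1e-2):
        return ReactionDef(label=label, paradigm=4, substrate=src, product=dst,
                           k_plus=kf, k_minus=kr)

    reactions = [
        # ligand binding and DISC activation; ligand is consumed into DR*
        conv(BINDING_REACTION, "TRAIL", "DR", "TRAIL:DR", "DR*",
             kf=4e-7, kr=1e-3, kc=1e-5),
        bind("inhibit_DR_flip", "flip", "DR*", "flip:DR*", kf=1e-6),
        cat("activate_C8", "DR*", "C8", "DR*:C8", "C8*", kf=1e-6),
        bind("inhibit_C8_BAR", "BAR", "C8*", "BAR:C8*", kf=1e-6),
        # executioner caspase activation and feedback
        cat("activate_C3", "C8*", "C3", "C8*:C3", "C3*", kf=1e-7),
        cat("activate_C6", "C3*", "C6", "C3*:C6", "C6*", kf=1e-7),
        cat("feedback_C8_via_C6", "C6*", "C8", "C6*:C8", "C8*", kf=3e-8),
        # XIAP sequesters active C3 and routes it to irreversible degradation
        cat("ubiquitinate_C3", "XIAP", "C3*", "XIAP:C3*", "C3Ub*",
            kf=2e-6, kr=1e-3, kc=1e-1),
        # PARP cleavage, the death readout
        cat("cleave_PARP", "C3*", "PARP", "C3*:PARP", "cPARP", kf=1e-6, kr=1e-2),
        # Bcl-2 family and MOMP
        cat("truncate_Bid", "C8*", "Bid", "C8*:Bid", "tBid", kf=1e-7),
        bind("inhibit_tBid_Bcl2c", "tBid", "Bcl2c", "tBid:Bcl2c", kf=1e-6),
        cat("activate_Bax", "tBid", "Bax", "tBid:Bax", "Bax*", kf=1e-7),
        transloc("translocate_Bax", "Bax*", "MBax"),
        bind("inhibit_MBax_Bcl2", "MBax", "Bcl2", "MBax:Bcl2", kf=1e-6 / v),
        bind("dimerize_Bax", "MBax", "MBax", "Bax2", kf=1e-6 / v),
        bind("inhibit_Bax2_Bcl2", "Bax2", "Bcl2", "Bax2:Bcl2", kf=1e-6 / v),
        bind("tetramerize_Bax", "Bax2", "Bax2", "Bax4", kf=1e-6 / v),
        bind("inhibit_Bax4_Bcl2", "Bax4", "Bcl2", "Bax4:Bcl2", kf=1e-6 / v),
        conv("open_pore", "Bax4", "M", "Bax4:M", "M*", kf=1e-6 / v, kr=1e-3, kc=1.0),
        # messenger release through the permeabilized membrane
        cat("release_CyC", "M*", "mCyC", "M*:mCyC", "CyC_r", kf=2e-6 / v, kc=10.0),
        cat("release_Smac", "M*", "mSmac", "M*:mSmac", "Smac_r", kf=2e-6 / v, kc=10.0),
        transloc("translocate_CyC", "CyC_r", "CyC"),
        transloc("translocate_Smac", "Smac_r", "Smac"),
        # apoptosome assembly and action
        cat("activate_Apaf", "CyC", "Apaf", "CyC:Apaf", "Apaf*", kf=5e-7),
        bind("assemble_Apop", "Apaf*", "C9", "Apop", kf=5e-8),
        cat("activate_C3_by_Apop", "Apop", "C3", "Apop:C3", "C3*", kf=5e-9),
        bind("inhibit_Apop_XIAP", "Apop", "XIAP", "Apop:XIAP", kf=2e-6),
        bind("inhibit_XIAP_Smac", "Smac", "XIAP", "Smac:XIAP", kf=7e-6),
    ]
    return build_network(species, reactions)


_FIXTURE_HEADER = (
    "Extrinsic apoptosis network: TRAIL/death-receptor DISC, caspase-8,\n"
    "C3/C6/XIAP/PARP module, Bcl-2 family / MOMP, Smac and cytochrome-c\n"
    "translocation, apoptosome.  Transcribed from the per-cell mass-action\n"
    "model of Albeck et al. (EARM); amounts in molecules per cell, k_plus in\n"
    "1/(molecule s), k_minus and k_cat in 1/s.  Bimolecular rate constants\n"
    "of mitochondrial reactions carry the compartment volume-fraction\n"
    "scaling 1/v with v = 0.07 (e.g. 1e-6/0.07).  The receptor-module row\n"
    "bind_TRAIL_DR and the TRAIL/DR initial amounts are placeholders that\n"
    "each treatment scenario overrides.\n"
    "Regenerate with: python -m trailkin.apoptosis"
)


def fixture_path():
    """Path of the shipped network fixture."""
    return importlib.resources.files("trailkin").joinpath("data/apoptosis_network.tsv")


def load_apoptosis_network(path=None) -> NetworkModel:
    """Load and validate the apoptosis network fixture.

    Raises :class:`~trailkin.network.NetworkValidationError` if the file is
    structurally invalid or lacks any species the analyses require.
    """
    model = read_network_tsv(path if path is not None else fixture_path())
    missing = [s for s in REQUIRED_SPECIES if s not in model.names]
    if missing:
        raise NetworkValidationError(f"fixture lacks required species: {missing}")
    return model


def builtin_scenarios() -> list[ScenarioConfig]:
    """The four treatment conditions, in the order they are tabulated."""
    return [
        ScenarioConfig("soluble", sigma_L=3.8e9,
                       sigma_R=SOLUBLE_RECEPTOR_PRESETS["table"],
                       k_plus=1.94e-12, k_minus=1e-3, exposure=None),
        ScenarioConfig("liposomal_static", sigma_L=2e11, sigma_R=2e9,
                       k_plus=9.1e-9, k_minus=320.0, exposure=None),
        ScenarioConfig("liposomal_shear_adhesion", sigma_L=2e11, sigma_R=2e9,
                       k_plus=1e-5, k_minus=320.0, exposure=1e-3),
        ScenarioConfig("liposomal_shear_no_adhesion", sigma_L=2e11, sigma_R=2e9,
                       k_plus=1e-5, k_minus=2.4e5, exposure=None),
    ]


def get_scenario(name: str) -> ScenarioConfig:
    for sc in builtin_scenarios():
        if sc.name == name:
            return sc
    known = [sc.name for sc in builtin_scenarios()]
    raise KeyError(f"unknown scenario {name!r}; built-ins are {known}")


def configure_scenario(
    network: NetworkModel, scenario: ScenarioConfig
) -> ConfiguredModel:
    """Substitute one scenario's receptor module into the network.

    Exactly the TRAIL and DR initial amounts and the ``bind_TRAIL_DR``
    forward/backward rate constants change; every downstream parameter is
    untouched.  The scenario's surface densities and 2D rate constants are
    applied number-for-number as the amounts and per-amount rates the ODE
    system integrates, which is the convention of the source simulations
    (see docs/methods.md for the unit discussion).
    """
    overrides = {
        "initials": {"TRAIL": scenario.sigma_L, "DR": scenario.sigma_R},
        "reaction_rates": {BINDING_REACTION: {"k_plus": scenario.k_plus,
                                              "k_minus": scenario.k_minus}},
    }
    model = network.with_overrides(**overrides)
    return ConfiguredModel(model=model, scenario=scenario, overrides=overrides)


def _main() -> None:
    """Regenerate the shipped fixture file (deterministic, byte-identical)."""
    import pathlib

    out = pathlib.Path(__file__).parent / "data" / "apoptosis_network.tsv"
    write_network_tsv(build_apoptosis_network(), out, header_comment=_FIXTURE_HEADER)
    print(f"wrote {out}")


if __name__ == "__main__":
    _main()
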