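"""Shared fixtures: the physiological encounter geometry and the apoptosis
network, loaded once per session."""

import pytest

import trailkin as tk


@pytest.fixture(scope="session")
def geometry():
    """Encounter geometry of the liposome--CTC collision: D = 1e-9 cm^2/s,
    a = 5e-6 cm, b = 10e-6 cm, S = 1000 1/s, d = 10 um, k_in = 1e9 1/s."""
    return tk.EncounterGeometry(
        diffusivity=1e-9,
        reactive_radius=5e-6,
        half_spacing=10e-6,
        shear_rate=1000.0,
        center_distance=10e-4,
        intrinsic_rate=1e9,
    )


@pytest.fixture(scope="session")
def apoptosis_network():
    return tk.load_apoptosis_network()


@pytest.fixture(scope="session")
def scenario_runs(apoptosis_network):
    """Time course + death statistic for each built-in scenario (24 h)."""
    out = {}
    for sc in tk.builtin_scenarios():
        cm = tk.configure_scenario(apoptosis_network, sc)
        tc = tk.run_protocol(cm, tk.protocol_for_scenario(sc))
        out[sc.name] = (tc, tk.time_to_death(tc))
    return out
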