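"""Derive 2D TRAIL--death-receptor binding rate constants for the three
transport regimes of a liposome--CTC encounter.

The sheared regime models two cell surfaces sliding past each other in
blood flow (slip velocity V = S*d); the unsheared regime models a static
contact; Bell's construction is an independent diffusion-limited check.
"""

import trailkin as tk

geom = tk.EncounterGeometry(
    diffusivity=1e-9,        # lateral diffusivity sum, cm^2/s
    reactive_radius=5e-6,    # cm
    half_spacing=10e-6,      # half the mean ligand-receptor spacing, cm
    shear_rate=1000.0,       # typical blood shear, 1/s
    center_distance=10e-4,   # sum of the two cell radii, cm
    intrinsic_rate=1e9,      # intrinsic reaction rate of the apposed pair, 1/s
)

regimes = [tk.derive_sheared_regime(geom),
           tk.derive_unsheared_regime(geom),
           tk.derive_bell_regime(geom)]

print(f"{'regime':<10} {'Pe':>8} {'Nu':>8} {'k_o [cm2/s]':>12} "
      f"{'P':>8} {'k_f [cm2/s]':>12} {'k_off [1/s]':>12}")
for r in regimes:
    print(f"{r.regime:<10} {r.peclet:>8.0f} "
          f"{r.nusselt if r.nusselt is not None else float('nan'):>8.3g} "
          f"{r.k_o:>12.3g} "
          f"{r.binding_probability if r.binding_probability is not None else float('nan'):>8.4f} "
          f"{r.k_f if r.k_f is not None else float('nan'):>12.4g} {r.k_off:>12.3g}")

print()
print("Shear raises the on-rate k_o about 1000-fold (advection replenishes")
print("reactants during the encounter) but also raises the off-rate k_off")
print("from ~320 to ~2.4e5 1/s; E-selectin adhesion recovers the low")
print("unsheared off-rate while keeping the sheared on-rate.")
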