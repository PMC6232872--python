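# trailkin

Mass-action kinetics of TRAIL-induced apoptosis in circulating tumor cells
(CTCs), with closed-form two-dimensional receptor–ligand collision kinetics
under shear.

## The problem

Tumor cells traveling in the bloodstream can be killed by presenting them
with TRAIL (TNF-related apoptosis-inducing ligand), either dissolved in
plasma (sTRAIL) or tethered to the surface of liposome-functionalized
leukocytes together with E-selectin (memTRAIL). The two presentations differ
in three kinetic respects: the surface density of ligand a CTC sees, the
binding on-rate (shear flow advects fresh ligand through the contact zone),
and the binding off-rate (E-selectin tethering briefly abolishes the slip
velocity between the surfaces). `trailkin` lets you ask how those
receptor-level differences propagate through the full extrinsic apoptosis
cascade to the time a cell actually dies.

The package has two halves:

1. **Binding theory** (`trailkin.binding`) — closed forms for the 2D
   association/dissociation rate constants of two apposed membranes. For a
   slip velocity **V** = S·d the Péclet number Pe = V·a/D sets the Nusselt
   number (Nu = 2Pe/π for Pe ≫ 1, Nu = 2/ln(b/a) at Pe = 0), the
   encounter-limited on-rate k_o = πD·Nu, and the encounter duration
   τ (8a/(3|V|π) sheared, a²/8D unsheared). With the dimensionless duration
   Λ = τD/a² and Damköhler number δ = a²k_in/D, the probability that an
   encounter bonds is P = Λδ/(1+Λδ), the overall forward rate is
   k_f = k_o·P, and the off-rate follows from k_f = k_o·k_in/(k_in+k_off).
   Bell's diffusion-limited construction (k_o = 2πD, k_off = 2D/a²) is
   included as an independent check.

2. **Reaction network** (`trailkin.network`, `trailkin.apoptosis`,
   `trailkin.simulate`, `trailkin.sweep`) — a generic mass-action engine
   (four reaction paradigms: catalysis with enzyme recycling,
   bind-and-convert, reversible binding, compartment translocation) driving
   a transcription of the Albeck et al. extrinsic-apoptosis model: DISC
   formation, caspase-8, the caspase-3/XIAP/PARP module, Bcl-2-family
   control of mitochondrial outer-membrane permeabilization, Smac and
   cytochrome-c release, and the apoptosome. Treatment scenarios replace
   only the TRAIL/death-receptor module; death is scored as T_d, the first
   time cleaved PARP crosses half its maximum.

## Worked example

```python
import trailkin as tk

geom = tk.EncounterGeometry(diffusivity=1e-9, reactive_radius=5e-6,
                            half_spacing=10e-6, shear_rate=1000.0,
                            center_distance=10e-4, intrinsic_rate=1e9)
sheared = tk.derive_sheared_regime(geom)
print(sheared.peclet, sheared.k_o, sheared.k_off)
# 5000.0 1.0000000000000002e-05 235617.87727728986

network = tk.load_apoptosis_network()
scenario = tk.get_scenario("liposomal_shear_adhesion")
tc = tk.run_protocol(tk.configure_scenario(network, scenario),
                     tk.protocol_for_scenario(scenario))
death = tk.time_to_death(tc)
print(f"{death.hours:.2f} h", f"{death.cparp_max:.3g}")
# 1.23 h 9.96e+05
```

The first block derives the sheared-encounter kinetics: at blood-flow shear
(S = 1000 s⁻¹, 10 µm center spacing) advection drives Pe = 5000, boosting
the 2D on-rate to 1.0×10⁻⁵ cm²/s — about three orders of magnitude above
the static value of 9.1×10⁻⁹ cm²/s — while the off-rate rises to
≈2.4×10⁵ s⁻¹ (vs 320 s⁻¹ unsheared). The second block simulates a CTC hit
by a TRAIL-bearing liposome that stays E-selectin-tethered for 1 ms
(sheared on-rate, unsheared off-rate, then free ligand removed): the cell
commits to apoptosis at T_d = 1.23 h, with nearly the whole PARP pool
(~10⁶ molecules) cleaved.

Runnable narrative scripts live in `examples/` (one per capability:
binding regimes, the four treatment scenarios, profile transforms,
death-time maps), and a thin CLI mirrors them:

```
trailkin derive-kinetics
trailkin scenario list
trailkin simulate soluble -o out/
trailkin sweep soluble trail dr -o out/
trailkin export-sbml
```

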