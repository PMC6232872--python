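# Methods

## Scope and model structure

`trailkin` couples two models. The *binding module* derives the rate
constants with which TRAIL on one membrane engages death receptors on an
apposed membrane, as closed forms in the encounter geometry and flow. The
*network module* integrates a deterministic mass-action ODE model of the
extrinsic apoptosis cascade, from ligand–receptor engagement to PARP
cleavage, and reduces trajectories to a single time-to-event statistic,
T_d.

The cascade is a transcription of the Albeck et al. extrinsic-apoptosis
model (EARM): 58 species and 28 reactions covering DISC formation and
caspase-8 activation (with FLIP and BAR as brakes), the executioner module
(caspase-3, caspase-6 feedback, XIAP sequestration and ubiquitination of
active C3, PARP cleavage), Bcl-2-family control of mitochondrial
outer-membrane permeabilization (Bid truncation, Bax activation,
dimerization to Bax₄, pore formation against Bcl-2 inhibition), release and
translocation of Smac and cytochrome c, and apoptosome
assembly/anti-XIAP action. The fixture
(`src/trailkin/data/apoptosis_network.tsv`) is plain text, regenerated
deterministically by `python -m trailkin.apoptosis`; bimolecular rate
constants of mitochondrial reactions carry the compartment volume-fraction
scaling 1/v with v = 0.07, and translocation steps run at 0.01 s⁻¹ in both
directions.

Every reaction is one of four paradigms: (1) catalysis with the enzyme
recycled, E + S ⇌ E:S → E + P; (2) bind-and-convert, E + S ⇌ E:S → P,
used where the complex itself becomes the product (receptor activation,
pore formation) — implemented with d[P]/dt = +K₊[E:S] so both the E- and
S-moieties are conserved, the only mass-consistent reading of this variant;
(3) reversible binding; (4) first-order reversible translocation.
Homodimerization (Bax) is paradigm 3 with E = S: the forward flux is
k₊[E]², consuming two copies per event, matching the original model's ODEs
(no statistical factor of ½).

## Binding kinetics: parameters and defaults

| parameter | symbol | default | units | meaning |
|---|---|---|---|---|
| diffusivity | D | 1×10⁻⁹ | cm²/s | sum of lateral diffusivities of ligand and receptor |
| reactive radius | a | 5×10⁻⁶ | cm | capture radius of the apposed pair |
| half spacing | b | 10×10⁻⁶ | cm | half the mean ligand–receptor distance (unsheared only; b > a) |
| shear rate | S | 1000 | 1/s | typical blood-flow shear |
| center distance | d | 10×10⁻⁴ | cm | sum of the colliding cells' radii; V = S·d |
| intrinsic rate | k_in | 1×10⁹ | 1/s | reaction rate of a perfectly apposed pair |

Derived quantities at the defaults: Pe = 5000, Nu = 2Pe/π ≈ 3183,
k_o = πD·Nu ≈ 1.0×10⁻⁵ cm²/s, τ = 8a/(3|V|π) ≈ 4.24×10⁻⁶ s,
Λ = τD/a² ≈ 1.70×10⁻⁴, δ = a²k_in/D = 2.5×10⁷, P = Λδ/(1+Λδ) ≈ 0.99976,
k_f = k_o·P, k_off = k_in(1/P − 1) ≈ 2.36×10⁵ s⁻¹; unsheared:
Nu = 2/ln(b/a) = 2/ln 2 ≈ 2.885 (natural logarithm — the base-10 reading
is numerically inconsistent with the rest of the closed forms),
k_o ≈ 9.07×10⁻⁹ cm²/s, τ = a²/8D, k_off = k_in/(Λδ) = 320 s⁻¹ exactly;
Bell: k_o = 2πD ≈ 6.28×10⁻⁹ cm²/s, k_off = 2D/a² = 80 s⁻¹. The sheared
asymptote Nu = 2Pe/π is refused below Pe = 100, where it is meaningless.
All intermediates are carried at full double precision; printed-style
rounding happens only in reporting code.

Surface-density bookkeeping: ~65 TRAIL per 100 nm liposome gives
σ_L = 65/(πd²) ≈ 2.1×10¹¹ cm⁻²; 10⁴ receptors on a sphere-equivalent cell
of volume 10⁻⁹ cm³ (area 4.84×10⁻⁶ cm²) give σ_R ≈ 2.1×10⁹ cm⁻²; 1 µg/mL
plasma TRAIL with the default molar mass 3.26×10⁴ g/mol maps to
1.85×10⁴ molecules per cell volume, i.e. ≈3.8×10⁹ cm⁻². The molar mass is
not independently constrained here; it is fixed so that the mass- and
count-based figures above agree, and is exposed as a parameter. The
volumetric constant 2.4×10⁵ M⁻¹s⁻¹ converts to 2D as
(k₃d·10³/N_A)·(area/volume) ≈ 1.91×10⁻¹² cm²/s (commonly quoted rounded to
1.94×10⁻¹²). Avogadro's constant is fixed at 6.02214076×10²³ mol⁻¹.

## Treatment scenarios and the unit convention

Four scenarios, differing **only** in the receptor module
(TRAIL/DR initial amounts, binding k₊/k₋, exposure):

| scenario | σ_L | σ_R | k₊ [cm²/(#·s)] | k₋ [1/s] | exposure |
|---|---|---|---|---|---|
| soluble | 3.8×10⁹ | 2×10⁴ | 1.94×10⁻¹² | 1×10⁻³ | continuous |
| liposomal_static | 2×10¹¹ | 2×10⁹ | 9.1×10⁻⁹ | 320 | continuous |
| liposomal_shear_adhesion | 2×10¹¹ | 2×10⁹ | 1×10⁻⁵ | 320 | 10⁻³ s |
| liposomal_shear_no_adhesion | 2×10¹¹ | 2×10⁹ | 1×10⁻⁵ | 2.4×10⁵ | continuous |

`configure_scenario` applies these numbers verbatim as the amounts and
per-amount rate constants the ODE system integrates, alongside the
downstream per-cell amounts. This was a genuinely open design choice and
deserves an honest account. A dimensionally strict alternative keeps
surface species in molecules/cm² and converts the receptor-module flux to
molecules/cell through the cell area A = 4.8×10⁻⁶ cm² at the
DISC-activation step. Under that strict bookkeeping the 1 ms tether
scenario yields ~4×10⁻⁴ activated receptors per cell — no cell ever dies —
and the soluble row's σ_R corresponds to 0.096 receptors per cell, which is
plainly not the intended physical situation (the same sources quote
2×10⁴ receptors per cell). The verbatim convention, by contrast, delivers
an activated-receptor scale (tens to thousands) commensurate with the
downstream model's calibration, and reproduces the qualitative behavior the
scenarios exist to compare. We therefore treat the tabulated σ values as
the receptor-module state variables themselves. The soluble receptor value
is additionally exposed as two presets (`table`: 2×10⁴; `derived`: 2.1×10⁹,
the areal figure consistent with 10⁴ receptors per cell) because the two
conventions genuinely disagree for that row; the tabulated value is the
default.

**Exposure protocol.** The E-selectin tether is a two-phase protocol:
phase 1 integrates 10⁻³ s with ligand present (sheared on-rate, unsheared
off-rate); phase 2 carries every species over except free TRAIL, which is
*clamped* to zero for the rest of the run (its derivative row is masked).
The clamp, rather than a one-time zeroing, is deliberate: the bound pool
(~2×10⁹ complexes) would otherwise regenerate free ligand within
microseconds and make the pulse indistinguishable from continuous exposure.
Physically, once the tether breaks there is no apposed carrier surface, so
ligand that dissociates leaves the contact zone instead of rebinding. A
corollary used by the tests: during phase 2 the bound complex decays as a
clean exponential exp(−k₋t).

## Time-to-death and profile statistics

T_d is the first time cleaved PARP reaches 0.5×cPARP_max, linearly
interpolated between grid points, with cPARP_max taken over the horizon.
If cPARP_max stays below 1% of the total PARP pool the run is scored
non-apoptotic (censored) instead of being assigned the half-max time of an
essentially flat curve. Profile transforms: per-species normalization by
each trajectory's own maximum (idempotent; all-zero species stay zero);
re-centering time on T_d; scaling by a reference run's per-species maxima
(ratios may exceed 1; a zero-reference/nonzero-run species is emitted as
NaN). A species' transition fraction at time t is
(value(t) − initial)/(extreme − initial) clipped to [0, 1], with "begins to
transition" at fraction 0.05 and "completed" at 0.95 — documented,
configurable operationalizations of qualitative notions.

## Numerics

The system spans rate scales from 10⁻³ to 10⁹ s⁻¹, so integration uses the
BDF stiff multistep method with the analytic mass-action Jacobian,
relative tolerance 10⁻⁸ and per-species absolute tolerance
10⁻⁶·max(initial, 1). Output grids are log-spaced (2000 points for single
runs) so the millisecond tether and the 10-hour transitions are resolved
simultaneously; sweeps use 500–600 points per cell. Single runs use a 24 h
horizon; sweeps 30 h, with non-crossing cells censored (empty cell plus
flag in exports, never a sentinel). Solver outputs are clipped at zero for
reporting only; a state more negative than 10⁻⁶ times the largest initial
amount, or conserved-moiety drift beyond 0.1% within a phase, raises a
quality error. Conserved moieties are the exact integer left null space of
the stoichiometry matrix (computed symbolically once per network
structure); moieties passing through the clamped ligand are exempt from the
drift check during clamped phases, where they are deliberately open.
Halving both tolerances moves T_d by well under 0.5%. Everything is
deterministic; there is no randomness anywhere in the package.

## Toy networks

`toy_fixture_generator` emits the three smallest networks with known
solutions — reversible/irreversible binding (second-order closed form),
a single catalytic step, and first-order translocation — so the engine,
the stiff solver, the two-phase protocol and the statistics can each be
checked against analytic oracles. These toys exercise every code path the
apoptosis fixture uses, but they do not emulate its stiffness ratio or its
conservation structure; passing them shows the machinery is correct, not
that the large model is well-conditioned, which is why the production runs
carry their own drift and negativity guards.

## Known limitations

- **Scenario discrimination is weaker than the kinetic inputs suggest.**
  The static and shear-without-adhesion scenarios share both surface
  densities and continuous exposure, and their affinity ratios
  (k₊σ_L)/k₋ are 5.7 and 8.3: both receptor modules equilibrate within
  milliseconds to 85–89% occupancy, so any mass-action implementation of
  these two parameter rows produces near-identical trajectories and death
  times. Claims that these two conditions differ several-fold in T_d
  cannot be recovered from this model structure; distinguishing them would
  require kinetics beyond occupancy (e.g. explicit encounter statistics or
  receptor turnover) that are outside scope. Likewise, in the probed
  parameter ranges the death response of this transcription is monotone
  and saturating in the receptor-module stimulus — the XIAP-mediated C3
  drain loses the race against mitochondrial permeabilization — so no
  interior T_d minimum appears along the soluble-ligand axis.
- Cell-population heterogeneity, partial-death phenotypes, protein
  synthesis/turnover and ligand clearance are not modeled; E-selectin
  enters only through the tether-lifetime exposure window and the choice
  of off-rate regime, not as explicit bond mechanics.
- No stochastic (SSA) simulation, delays, or spatial transport; the SBML
  export is one-way.
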