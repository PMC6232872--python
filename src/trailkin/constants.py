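"""Physical constants and canonical cell geometry shared across modules."""

#: Avogadro constant (molecules / mol), CODATA 2018 exact value.
AVOGADRO = 6.02214076e23

#: Volume of a circulating tumor cell (cm^3).
CTC_VOLUME = 1e-9

#: Surface area of a sphere-equivalent CTC of volume ``CTC_VOLUME`` (cm^2),
#: rounded to the two significant figures conventionally quoted for it.
#: Full-precision value is available from
#: :func:`trailkin.binding.cell_surface_density`.
CTC_AREA = 4.8e-6

#: Default molar mass of soluble TRAIL used to convert plasma mass
#: concentration to molecule counts (g/mol).  Chosen so that 1 ug/mL of
#: sTRAIL corresponds to 1.85e4 molecules per 1e-9 cm^3 cell volume
#: (equivalently 3.8e9 molecules/cm^2 of cell surface); exposed as a
#: parameter everywhere it is consumed.
TRAIL_MOLAR_MASS = 3.26e4
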