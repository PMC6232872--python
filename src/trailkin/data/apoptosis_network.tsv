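# Extrinsic apoptosis network: TRAIL/death-receptor DISC, caspase-8,
# C3/C6/XIAP/PARP module, Bcl-2 family / MOMP, Smac and cytochrome-c
# translocation, apoptosome.  Transcribed from the per-cell mass-action
# model of Albeck et al. (EARM); amounts in molecules per cell, k_plus in
# 1/(molecule s), k_minus and k_cat in 1/s.  Bimolecular rate constants
# of mitochondrial reactions carry the compartment volume-fraction
# scaling 1/v with v = 0.07 (e.g. 1e-6/0.07).  The receptor-module row
# bind_TRAIL_DR and the TRAIL/DR initial amounts are placeholders that
# each treatment scenario overrides.
# Regenerate with: python -m trailkin.apoptosis
[species]
name	compartment	role	initial
TRAIL	surface	ligand	3000.0
DR	surface	receptor	200.0
TRAIL:DR	surface	intracellular	0.0
DR*	surface	intracellular	0.0
flip	cytosol	intracellular	100.0
flip:DR*	cytosol	intracellular	0.0
C8	cytosol	intracellular	20000.0
DR*:C8	surface	intracellular	0.0
C8*	cytosol	intracellular	0.0
BAR	cytosol	intracellular	1000.0
BAR:C8*	cytosol	intracellular	0.0
C3	cytosol	intracellular	10000.0
C8*:C3	cytosol	intracellular	0.0
C3*	cytosol	intracellular	0.0
C6	cytosol	intracellular	10000.0
C3*:C6	cytosol	intracellular	0.0
C6*	cytosol	intracellular	0.0
C6*:C8	cytosol	intracellular	0.0
XIAP	cytosol	intracellular	100000.0
XIAP:C3*	cytosol	intracellular	0.0
C3Ub*	cytosol	intracellular	0.0
PARP	cytosol	intracellular	1000000.0
C3*:PARP	cytosol	intracellular	0.0
cPARP	cytosol	intracellular	0.0
Bid	cytosol	intracellular	40000.0
C8*:Bid	cytosol	intracellular	0.0
tBid	cytosol	intracellular	0.0
Bcl2c	cytosol	intracellular	20000.0
tBid:Bcl2c	cytosol	intracellular	0.0
Bax	cytosol	intracellular	100000.0
tBid:Bax	cytosol	intracellular	0.0
Bax*	cytosol	intracellular	0.0
MBax	mitochondria	intracellular	0.0
Bcl2	mitochondria	intracellular	20000.0
MBax:Bcl2	mitochondria	intracellular	0.0
Bax2	mitochondria	intracellular	0.0
Bax2:Bcl2	mitochondria	intracellular	0.0
Bax4	mitochondria	intracellular	0.0
Bax4:Bcl2	mitochondria	intracellular	0.0
M	mitochondria	intracellular	500000.0
Bax4:M	mitochondria	intracellular	0.0
M*	mitochondria	intracellular	0.0
mCyC	mitochondria	intracellular	500000.0
M*:mCyC	mitochondria	intracellular	0.0
CyC_r	mitochondria	intracellular	0.0
CyC	cytosol	intracellular	0.0
mSmac	mitochondria	intracellular	100000.0
M*:mSmac	mitochondria	intracellular	0.0
Smac_r	mitochondria	intracellular	0.0
Smac	cytosol	intracellular	0.0
Apaf	cytosol	intracellular	100000.0
CyC:Apaf	cytosol	intracellular	0.0
Apaf*	cytosol	intracellular	0.0
C9	cytosol	intracellular	100000.0
Apop	cytosol	intracellular	0.0
Apop:C3	cytosol	intracellular	0.0
Apop:XIAP	cytosol	intracellular	0.0
Smac:XIAP	cytosol	intracellular	0.0
[reactions]
label	paradigm	enzyme	substrate	complex	product	k_plus	k_minus	k_cat
bind_TRAIL_DR	2	TRAIL	DR	TRAIL:DR	DR*	4e-07	0.001	1e-05
inhibit_DR_flip	3	flip	DR*	flip:DR*	-	1e-06	0.001	0.0
activate_C8	1	DR*	C8	DR*:C8	C8*	1e-06	0.001	1.0
inhibit_C8_BAR	3	BAR	C8*	BAR:C8*	-	1e-06	0.001	0.0
activate_C3	1	C8*	C3	C8*:C3	C3*	1e-07	0.001	1.0
activate_C6	1	C3*	C6	C3*:C6	C6*	1e-07	0.001	1.0
feedback_C8_via_C6	1	C6*	C8	C6*:C8	C8*	3e-08	0.001	1.0
ubiquitinate_C3	1	XIAP	C3*	XIAP:C3*	C3Ub*	2e-06	0.001	0.1
cleave_PARP	1	C3*	PARP	C3*:PARP	cPARP	1e-06	0.01	1.0
truncate_Bid	1	C8*	Bid	C8*:Bid	tBid	1e-07	0.001	1.0
inhibit_tBid_Bcl2c	3	tBid	Bcl2c	tBid:Bcl2c	-	1e-06	0.001	0.0
activate_Bax	1	tBid	Bax	tBid:Bax	Bax*	1e-07	0.001	1.0
translocate_Bax	4	-	Bax*	-	MBax	0.01	0.01	0.0
inhibit_MBax_Bcl2	3	MBax	Bcl2	MBax:Bcl2	-	1.4285714285714284e-05	0.001	0.0
dimerize_Bax	3	MBax	MBax	Bax2	-	1.4285714285714284e-05	0.001	0.0
inhibit_Bax2_Bcl2	3	Bax2	Bcl2	Bax2:Bcl2	-	1.4285714285714284e-05	0.001	0.0
tetramerize_Bax	3	Bax2	Bax2	Bax4	-	1.4285714285714284e-05	0.001	0.0
inhibit_Bax4_Bcl2	3	Bax4	Bcl2	Bax4:Bcl2	-	1.4285714285714284e-05	0.001	0.0
open_pore	2	Bax4	M	Bax4:M	M*	1.4285714285714284e-05	0.001	1.0
release_CyC	1	M*	mCyC	M*:mCyC	CyC_r	2.8571428571428567e-05	0.001	10.0
release_Smac	1	M*	mSmac	M*:mSmac	Smac_r	2.8571428571428567e-05	0.001	10.0
translocate_CyC	4	-	CyC_r	-	CyC	0.01	0.01	0.0
translocate_Smac	4	-	Smac_r	-	Smac	0.01	0.01	0.0
activate_Apaf	1	CyC	Apaf	CyC:Apaf	Apaf*	5e-07	0.001	1.0
assemble_Apop	3	Apaf*	C9	Apop	-	5e-08	0.001	0.0
activate_C3_by_Apop	1	Apop	C3	Apop:C3	C3*	5e-09	0.001	1.0
inhibit_Apop_XIAP	3	Apop	XIAP	Apop:XIAP	-	2e-06	0.001	0.0
inhibit_XIAP_Smac	3	Smac	XIAP	Smac:XIAP	-	7e-06	0.001	0.0
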