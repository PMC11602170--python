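# Nearest-neighbor RNA free-energy parameters, dG37 in kcal/mol.
# Turner-2004-style values at 37 C, 1 M NaCl, no Mg.
# stack records: 5'XY3' paired with 3'WZ5' (X pairs W, Y pairs Z).
# Only one member of each rotational pair (XY/WZ == ZW/YX) is listed;
# the loader fills in the rotations.
# version: 1
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	UA/AU	-1.33
stack	CU/GA	-2.08
stack	CA/GU	-2.11
stack	GU/CA	-2.24
stack	GA/CU	-2.35
stack	CG/GC	-2.36
stack	GG/CC	-3.26
stack	GC/CG	-3.42
stack	AG/UU	-0.55
stack	AU/UG	-1.36
stack	CG/GU	-1.41
stack	CU/GG	-2.11
stack	GG/CU	-1.53
stack	GU/CG	-2.51
stack	UG/AU	-1.27
stack	UU/AG	-1.00
stack	GG/UU	-0.50
stack	GU/UG	1.29
stack	UG/GU	0.30
# hairpin-loop initiation penalties by loop size (nt); sizes beyond 9 are
# extrapolated logarithmically by the loader.
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
# per-helix-end penalty for a terminal A-U or G-U closing pair
terminal_au	.	0.45
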