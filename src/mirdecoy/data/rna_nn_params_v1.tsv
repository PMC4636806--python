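# mirdecoy RNA:RNA hybridization nearest-neighbor parameters, version 1
# Stacking free energies (dG37, kcal/mol) from the published Turner 2004
# nearest-neighbor tables, including G.U wobble pairs.
# stack  <top doublet 5'->3'>  <bottom doublet 3'->5'>  <dG37>
stack	AA	UU	-0.90
stack	AC	UG	-2.20
stack	AG	UC	-2.10
stack	AG	UU	-0.60
stack	AU	UA	-1.10
stack	AU	UG	-1.40
stack	CA	GU	-2.10
stack	CC	GG	-3.30
stack	CG	GC	-2.40
stack	CG	GU	-1.40
stack	CU	GA	-2.10
stack	CU	GG	-2.10
stack	GA	CU	-2.40
stack	GA	UU	-1.30
stack	GC	CG	-3.40
stack	GC	UG	-2.50
stack	GG	CC	-3.30
stack	GG	CU	-1.50
stack	GG	UC	-2.10
stack	GG	UU	-0.50
stack	GU	CA	-2.20
stack	GU	CG	-2.50
stack	GU	UA	-1.40
stack	GU	UG	1.30
stack	UA	AU	-1.30
stack	UA	GU	-1.00
stack	UC	AG	-2.40
stack	UC	GG	-1.50
stack	UG	AC	-2.10
stack	UG	AU	-1.00
stack	UG	GC	-1.40
stack	UG	GU	0.30
stack	UU	AA	-0.90
stack	UU	AG	-1.30
stack	UU	GA	-0.60
stack	UU	GG	-0.50
# Loop model: affine penalties, capped at max_loop unpaired nt per strand.
# interior(s1,s2) = interior_init + interior_slope*(s1+s2) + interior_asym*|s1-s2|
# bulge(n) = bulge_init + bulge_slope*n
param	duplex_initiation	0.00
param	terminal_au_penalty	0.45
param	bulge_init	3.50
param	bulge_slope	0.35
param	interior_init	0.55
param	interior_slope	0.27
param	interior_asym	0.60
param	max_loop	15
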