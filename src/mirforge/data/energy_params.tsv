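# Reduced nearest-neighbor free-energy table (kcal/mol, 37 C).
# stack keys are "outer,inner": outer pair (i,j), inner pair (i+1,j-1),
# each written 5'-base then 3'-base.  Watson-Crick/Watson-Crick values follow
# the Turner nearest-neighbor set; wobble-containing stacks use a uniform
# mild stabilization.  The table is symmetric under helix rotation:
# value(X Y, Z W) == value(W Z, Y X).
# hairpin/internal rows are loop penalties by unpaired length; lengths past
# the last row are extrapolated with coef * ln(len/last_len).
stack	AU,AU	-0.93
stack	AU,UA	-1.10
stack	AU,CG	-2.24
stack	AU,GC	-2.08
stack	AU,GU	-0.50
stack	AU,UG	-0.50
stack	UA,AU	-1.33
stack	UA,UA	-0.93
stack	UA,CG	-2.35
stack	UA,GC	-2.11
stack	UA,GU	-0.50
stack	UA,UG	-0.50
stack	CG,AU	-2.11
stack	CG,UA	-2.08
stack	CG,CG	-3.26
stack	CG,GC	-2.36
stack	CG,GU	-0.50
stack	CG,UG	-0.50
stack	GC,AU	-2.35
stack	GC,UA	-2.24
stack	GC,CG	-3.42
stack	GC,GC	-3.26
stack	GC,GU	-0.50
stack	GC,UG	-0.50
stack	GU,AU	-0.50
stack	GU,UA	-0.50
stack	GU,CG	-0.50
stack	GU,GC	-0.50
stack	GU,GU	-0.50
stack	GU,UG	-0.50
stack	UG,AU	-0.50
stack	UG,UA	-0.50
stack	UG,CG	-0.50
stack	UG,GC	-0.50
stack	UG,GU	-0.50
stack	UG,UG	-0.50
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
internal	1	3.90
internal	2	3.10
internal	3	3.50
internal	4	4.20
internal	5	4.80
internal	6	5.00
multiloop	closing	3.40
multiloop	branch	0.40
multiloop	unpaired	0.00
extrapolate	coef	1.078
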