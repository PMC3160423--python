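# Simplified nearest-neighbour RNA energy parameters (kcal/mol, 37 C scale).
# Stack rows: kind=stack, key=P1:P2 where P1 is the outer pair 5'W/3'Z and P2
# the inner pair 5'X/3'Y of the dinucleotide step 5'WX3'/3'ZY5'.
# Loop rows give length-dependent penalties; lengths beyond the last tabulated
# value are extrapolated as E(last) + 1.1*ln(n/last).
kind	key	value
stack	AU:AU	-0.9
stack	AU:UA	-1.1
stack	AU:GC	-2.1
stack	AU:CG	-2.2
stack	AU:GU	-0.6
stack	AU:UG	-1.4
stack	UA:AU	-1.3
stack	UA:UA	-0.9
stack	UA:GC	-2.1
stack	UA:CG	-2.4
stack	UA:GU	-1.0
stack	UA:UG	-1.3
stack	GC:AU	-2.4
stack	GC:UA	-2.2
stack	GC:GC	-3.3
stack	GC:CG	-3.4
stack	GC:GU	-1.5
stack	GC:UG	-2.5
stack	CG:AU	-2.1
stack	CG:UA	-2.1
stack	CG:GC	-2.4
stack	CG:CG	-3.3
stack	CG:GU	-1.4
stack	CG:UG	-2.1
stack	GU:AU	-1.3
stack	GU:UA	-1.4
stack	GU:GC	-2.1
stack	GU:CG	-2.5
stack	GU:GU	-0.5
stack	GU:UG	-0.6
stack	UG:AU	-1.0
stack	UG:UA	-0.6
stack	UG:GC	-1.4
stack	UG:CG	-1.5
stack	UG:GU	-0.3
stack	UG:UG	-0.5
hairpin	3	5.4
hairpin	4	5.6
hairpin	5	5.7
hairpin	6	5.4
hairpin	7	6.0
hairpin	8	5.5
hairpin	9	6.4
hairpin	10	6.5
bulge	1	3.8
bulge	2	2.8
bulge	3	3.2
bulge	4	3.6
bulge	5	4.0
bulge	6	4.4
internal	2	1.5
internal	3	1.6
internal	4	1.7
internal	5	2.0
internal	6	2.0
multiloop	a	3.4
multiloop	b	0.4
multiloop	c	0.0
terminal	AU	0.5
terminal	UA	0.5
terminal	GU	0.5
terminal	UG	0.5
terminal	GC	0.0
terminal	CG	0.0
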