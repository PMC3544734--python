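# RNA nearest-neighbor duplex stacking free energies, dG37 (kcal/mol),
# Watson-Crick stacks keyed by the 5'->3' sense-strand dinucleotide
# (U written as T). Values: Xia et al. 1998 thermodynamic parameter set.
# The "init" row is the duplex initiation penalty.
stack	dG
AA	-0.93
AC	-2.24
AG	-2.08
AT	-1.10
CA	-2.11
CC	-3.26
CG	-2.36
CT	-2.08
GA	-2.35
GC	-3.42
GG	-3.26
GT	-2.24
TA	-1.33
TC	-2.35
TG	-2.11
TT	-0.93
init	4.09
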