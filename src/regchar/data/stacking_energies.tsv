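# Dinucleotide base-stacking energies, kcal/mol (stacked-dimer values,
# Ornstein et al. 1978 scale). Lower (more negative) = more stable stacking.
# dinucleotide	energy_kcal_mol
AA	-5.37
AC	-10.51
AG	-6.78
AT	-6.57
CA	-6.57
CC	-8.26
CG	-9.69
CT	-6.78
GA	-9.81
GC	-14.59
GG	-8.26
GT	-10.51
TA	-3.82
TC	-9.81
TG	-6.57
TT	-5.37
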