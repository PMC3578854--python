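# Unified nearest-neighbor parameters for DNA/DNA duplex steps (SantaLucia 1998).
# step: sense-strand dinucleotide 5'->3', paired with its complement.
# dH kcal/mol; dS cal/(mol K); dG37 kcal/mol (published free energy at 310.15 K).
# dS is stored at two decimals, consistent with dH and dG37: dS = (dH - dG37)/310.15.
step	dH	dS	dG37
AA	-7.9	-22.25	-1.00
AC	-8.4	-22.44	-1.44
AG	-7.8	-21.02	-1.28
AT	-7.2	-20.38	-0.88
CA	-8.5	-22.73	-1.45
CC	-8.0	-19.86	-1.84
CG	-10.6	-27.18	-2.17
CT	-7.8	-21.02	-1.28
GA	-8.2	-22.25	-1.30
GC	-9.8	-24.38	-2.24
GG	-8.0	-19.86	-1.84
GT	-8.4	-22.44	-1.44
TA	-7.2	-21.35	-0.58
TC	-8.2	-22.25	-1.30
TG	-8.5	-22.73	-1.45
TT	-7.9	-22.25	-1.00
init_GC	0.1	-2.84	0.98
init_AT	2.3	4.09	1.03
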