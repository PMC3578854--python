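# Nearest-neighbor parameters for RNA/DNA hybrid duplex steps (Sugimoto et al. 1995).
# step: RNA-strand dinucleotide 5'->3', paired with its complementary DNA.
# dH kcal/mol; dS cal/(mol K); dG37 kcal/mol (published free energy at 310.15 K).
# dS is stored at two decimals, consistent with dH and dG37: dS = (dH - dG37)/310.15.
step	dH	dS	dG37
AA	-7.8	-21.93	-1.0
AC	-5.9	-12.25	-2.1
AG	-9.1	-23.54	-1.8
AU	-8.3	-23.86	-0.9
CA	-9.0	-26.12	-0.9
CC	-9.3	-23.21	-2.1
CG	-16.3	-47.07	-1.7
CU	-7.0	-19.67	-0.9
GA	-5.5	-13.54	-1.3
GC	-8.0	-17.09	-2.7
GG	-12.8	-31.92	-2.9
GU	-7.8	-21.60	-1.1
UA	-7.8	-23.21	-0.6
UC	-8.6	-22.89	-1.5
UG	-10.4	-28.37	-1.6
UU	-11.5	-36.43	-0.2
init	1.9	-3.87	3.1
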