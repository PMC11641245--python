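gene	log2fc	pvalue	fdr
alphaTub67C	-0.952490176	0.000867	0.00578
Apc2	-0.639416425	3.91e-10	8.498e-9
barr	-0.869589586	1.83e-27	1.24e-25
BubR1	-1.07030746	5.28e-27	3.47e-25
Cdk2	-0.858035426	4.32e-11	1.03e-9
Cenp-C	-1.051992964	7.11e-28	4.84e-26
cid	-0.55623802	2.40e-5	0.000242
cmet	-0.692319454	1.33e-17	5.41e-16
glu	-1.110534588	1.31e-37	1.28e-35
IncenP	-0.922209804	1.90e-21	9.85e-20
Klp61F	-0.554131891	8.16e-10	1.71e-8
mei-S332	-0.883435396	3.81e-18	1.61e-16
neb	-0.973540901	5.11e-23	2.87e-21
pav	-0.968485941	5.44e-36	5.05e-34
pim	-1.289603484	8.26e-22	4.35e-20
Rx	-3.294594189	6.71e-92	2.39e-89
scra	-1.042234664	4.60e-17	1.82e-15
SMC2	-1.095214765	2.59e-22	1.41e-20
sti	-1.291936939	2.90e-60	5.52e-58
thr	-0.679554768	2.06e-10	4.63e-9
tum	-1.221556643	1.20e-55	1.94e-53
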