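substitution	source_table	allele	maf_eur	combination_with	cis_group	agwt_antigen	agv_antigen	minus_flag
Cys77Phe	T1_null	KEL*02N.28						0
Cys82Arg	T1_null	KEL*01N.02		Thr193Met				0
Cys100Ser	T1_null	KEL*02N.42						0
Leu133Pro	T1_null	KEL*02N.35	1.80e-06					0
Tyr152Cys	T1_null	KEL*02N.32	8.99e-07					0
Ile161Phe	T1_null	KEL*02N.48	8.99e-07					0
Ala313ThrArg358Thr	T1_null	KEL*02N.45			KEL*02N.45			0
Trp316Cys	T1_null	KEL*02N.66	1.98e-05					0
Leu377Pro	T1_null	KEL*02N.62	8.99e-07					0
Phe418Ser	T1_null	KEL*02N.37	5.08e-06					0
Gly555Glu	T1_null	KEL*02N.29						0
Pro560Ala	T1_null	KEL*01N.01		Thr193Met				0
Pro560Ala	T1_null	KEL*02N.18						0
Val570Met	T1_null	KEL*02N.59	1.78e-05					0
Gly576Arg	T1_null	KEL*02N.33	4.24e-06					0
Leu611Arg	T1_null	KEL*02N.38	8.99e-07					0
Ser676Asn	T1_null	KEL*02N.05	3.63e-06					0
Arg700Gln	T1_null	KEL*02N.34		Arg281Trp				0
Arg86Gln	T1_mod	KEL*02M.13		Arg281Trp				0
Asp102GluPro433Leu	T1_mod	KEL*02M.06			KEL*02M.06			0
Arg192Pro	T1_mod	KEL*02M.15						0
Arg192Gln	T1_mod	KEL*02M.19	1.61e-05					0
Thr193Arg	T1_mod	KEL*01M.01						0
Leu196Val	T1_mod	KEL*02M.17	1.02e-04					0
Gly263Arg	T1_mod	KEL*02M.10	4.50e-06					0
Gly263Glu	T1_mod	KEL*02M.16						0
Pro326Leu	T1_mod	KEL*01M.02		Thr193Met				0
Leu329Pro	T1_mod	KEL*02M.03	4.50e-06					0
Gln362Lys	T1_mod	KEL*02M.14	3.14e-05					0
Gly555Val	T1_mod	KEL*02M.18						0
Ser363Asn	T1_mod	KEL*02M.01	3.54e-04					0
Ala423Val	T1_mod	KEL*02M.11	8.31e-05					0
Arg447Trp	T1_mod	KEL*01M.03		Thr193Met				0
Asp497Val	T1_mod	KEL*02M.08						0
Ile586Ser	T1_mod	KEL*02M.09						0
Tyr588Cys	T1_mod	KEL*02M.07	8.99e-07					0
Gly641Arg	T1_mod	KEL*01M.04		Thr193Met				0
Ala645Val	T1_mod	KEL*01M.05		Thr193Met				0
Tyr677Cys	T1_mod	KEL*02M.02	6.08e-05					0
Gly703Arg	T1_mod	KEL*01M.06		Thr193Met				0
Gly703Arg	T1_mod	KEL*02M.04	2.37e-05					0
Pro704His	T1_mod	KEL*02M.12	1.86e-05					0
Thr193Met	T2	KEL*01.01	4.17e-02			KEL:2	KEL:1	0
Thr193Ser	T2	KEL*01.02	8.99e-07			KEL:2	KEL:1weak	0
Arg281Trp	T2	KEL*02.03	1.07e-02			KEL:4	KEL:3	0
Arg281Gln	T2	KEL*02.21	1.02e-05			KEL:4	KEL:21	0
Leu597Pro	T2	KEL*02.06	3.58e-04			KEL:7	KEL:6	0
Glu494Val	T2	KEL*02.10	7.12e-05				KEL:10	0
Val302Ala	T2	KEL*02.17	1.88e-03			KEL:11	KEL:17	0
His548Arg	T2	KEL*02.-12	2.55e-04			KEL:12		1
Leu329Pro	T2	KEL*02.-13	4.50e-06			KEL:13		1
Arg180Cys	T2	KEL*02.-14.1	1.61e-05			KEL:14		1
Arg180His	T2	KEL*02.-14.2	1.36e-05			KEL:14		1
Arg180Pro	T2	KEL*02.24	2.70e-06			KEL:14	KEL:24	0
Arg130Trp	T2	KEL*02.-18.1	4.15e-05			KEL:18		1
Arg130Gln	T2	KEL*02.-18.2	2.37e-05			KEL:18		1
Arg492Gln	T2	KEL*02.-19	3.44e-04			KEL:19		1
Ala322Val	T2	KEL*02.-22	2.03e-05			KEL:22		1
Gln382Arg	T2	KEL*02.23					KEL:23	0
Arg248Gln	T2	KEL*02.25	1.61e-05				KEL:25	0
Arg406Gln	T2	KEL*02.-26	8.48e-06			KEL:26		1
Glu249Lys	T2	KEL*02.-27	8.99e-07			KEL:27		1
Arg248Trp	T2	KEL*02.28	8.47e-06				KEL:28	0
Arg623Lys	T2	KEL*02.-29	8.99e-07			KEL:29		1
Asp305Asn	T2	KEL*02.-30	3.14e-05			KEL:30		1
Ala424Val	T2	KEL*02.-32	5.08e-06			KEL:32		1
Arg428Leu	T2	KEL*02.-33				KEL:33		1
Tyr253Cys	T2	KEL*02.-34				KEL:34		1
Leu260PheArg675Gln	T2	KEL*02.-35			KEL*02.-35	KEL:35		1
Thr464Ile	T2	KEL*02.-36	2.47e-04			KEL:36		1
Arg293Trp	T2	KEL*02.39	1.53e-05			KEL:37	KEL:39	0
Arg292Gln	T2	KEL*02.31	1.09e-04			KEL:38	KEL:31	0
Arg513Gln	T2	KEL*02.41	2.12e-05			KEL:40	KEL:41	0
Asp692Asn	T3		5.02e-04					0
Ile278Leu	T3		4.58e-04					0
Arg492Gln	T3	KEL*02.-19	3.44e-04					0
Asp689Tyr	T3		2.40e-04					0
Tyr714Phe	T3		2.13e-04					0
Ala598Thr	T3		1.42e-04					0
Asp315Asn	T3		1.41e-04					0
Glu606Gln	T3		1.03e-04					0
Ala445Val	T3		9.58e-05					0
Thr421Met	T3		9.49e-05					0
Lys112Glu	T3		9.41e-05					0
His691Gln	T3		9.26e-05					0
Arg716His	T3		8.98e-05					0
Met156Val	T3		7.20e-05					0
Pro402Thr	T3		6.87e-05					0
Ile278Val	T3		6.10e-05					0
Ala645Thr	T3		5.76e-05					0
Ile242Met	T3		5.68e-05					0
Ala574Thr	T3		5.68e-05					0
Glu634Asp	T3		4.83e-05					0
Ala423Ser	T3		4.32e-05					0
Asn456Lys	T3		4.23e-05					0
Arg130Trp	T3	KEL*02.-18.1	4.15e-05					0
Phe431Ser	T3		4.14e-05					0
Ala645Glu	T3		3.47e-05					0
Val340Met	T3		3.39e-05					0
Asp305Asn	T3	KEL*02.-30	3.14e-05					0
Glu146Lys	T3		3.30e-05					0
Val268Leu	T3		3.22e-05					0
Glu413Lys	T3		3.05e-05					0
Ala712Thr	T3		3.05e-05					0
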