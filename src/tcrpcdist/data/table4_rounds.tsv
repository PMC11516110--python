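# Orphan / reference TCR pairs from the four experimental deorphanization
# rounds, transcribed row-for-row as printed (43 rows). 'specificity' is the
# printed label: 'orphan' for the query rows, otherwise the cognate peptide
# (or 'EBV-reactive'). 'distance' and 'ef' are the printed values where given.
id	round	patient	trav	traj	cdr3a	trbv	trbj	cdr3b	specificity	distance	ef
r1_01	1	Mel#2	TRAV12-2	TRAJ52	CAVTTGGTSYGKLTF	TRBV11-2	TRBJ2-7	CASKGAPTIYYEQYF	orphan	0.13	1.4
r1_02	1	Mel#2	TRAV12-2	TRAJ52	CAVKGSGTSYGKLTF	TRBV9	TRBJ2-1	CASSLTGYEQFF	GLYDGMEHL
r1_03	1	Mel#2	TRAV1-2	TRAJ26	CAVRFRDNYGQNFVF	TRBV5-1	TRBJ2-1	CASSLSWTSGNEQFF	orphan	0.09	2.3
r1_04	1	Mel#2	TRAV1-2	TRAJ28	CAVRTGYSGAGSYQLTF	TRBV5-1	TRBJ2-1	CASSYGNEQFFG	TADFDITEL
r1_05	1	Mel#4	TRAV17	TRAJ12	CATVVRMDSSYKLIF	TRBV7-9	TRBJ2-1	CASSLIGVSSYNEQFF	orphan	0.11	4.5
r1_06	1	Mel#2	TRAV17	TRAJ12	CATVVRMDSSYKLIF	TRBV7-9	TRBJ2-1	CASSLVGEGWSDEQFF	TPRVTGGGAM
r1_07	1	Mel#2	TRAV12-2	TRAJ49	CAGSTGNQFYF	TRBV27	TRBJ2-3	CASSPWGASDTQYF	orphan	0.10	1.6
r1_08	1	Mel#2	TRAV12-2	TRAJ49	CAVNAGNQFYF	TRBV4-1	TRBJ2-3	CASSPDRSADTQYF	ELAGIGILTV
r1_09	1	Mel#2	TRAV12-1	TRAJ42	CVVNSYGGSQGNLIF	TRBV9	TRBJ1-2	CASSVVSGGTYGYTF	orphan	0.11	2.1
r1_10	1	Mel#2	TRAV12-2	TRAJ37	CAVKDGNTGKLIF	TRBV9	TRBJ1-2	CASSLTGYGYTF	GLYDGMEHL
r1_11	1	Mel#4	TRAV14/DV4	TRAJ4	CVSGGYNKLIF	TRBV12-4	TRBJ1-6	CASGSGNSPLHF	orphan	0.11	4.5
r1_12	1	Mel#1	TRAV14/DV4	TRAJ4	CAMRAGGYNKLIF	TRBV14	TRBJ2-5	CASSHWTSGSGETQYF	ILRGSVAHK
r1_13	1	Mel#1	TRAV13-1	TRAJ3	CAAGLGRYSSASKIIF	TRBV20-1	TRBJ2-5	CSAKRTSGHQETQYF	orphan	0.13	2.3
r1_14	1	Mel#1	TRAV13-1	TRAJ3	CAASDSSASKIIF	TRBV9	TRBJ2-5	CASSVGKETQYF	FAFGEPREL
r1_15	1	Mel#1	TRAV26-2	TRAJ30	CILRDVGRDDKIIF	TRBV9	TRBJ2-5	CASSARQGRGETQYF	orphan	0.14	2.3
r1_16	1	Mel#1	TRAV13-1	TRAJ3	CAASDSSASKIIF	TRBV9	TRBJ2-5	CASSVGKETQYF	FAFGEPREL
r1_17	1	Mel#1	TRAV35	TRAJ30	CAGQVVMDDKIIF	TRBV9	TRBJ2-5	CASSPPVGETQYF	orphan	0.14	2.3
r1_18	1	Mel#1	TRAV13-1	TRAJ3	CAASDSSASKIIF	TRBV9	TRBJ2-5	CASSVGKETQYF	FAFGEPREL
r1_19	1	Mel#4	TRAV17	TRAJ12	CATVARMDSSYKLIF	TRBV7-9	TRBJ2-3	CASSLIGQGITDTQYF	orphan	0.14	4.5
r1_20	1	Mel#2	TRAV17	TRAJ12	CATVVRMDSSYKLIF	TRBV7-9	TRBJ2-1	CASSLVGEGWSDEQFF	TPRVTGGGAM
r1_21	1	Mel#2	TRAV13-1	TRAJ4	CAVPGVLSGGYNKLIF	TRBV9	TRBJ1-1	CASSVASPNTEAFF	orphan	0.15	1.5
r1_22	1	Mel#2	TRAV13-1	TRAJ37	CASYSGNTGKLIF	TRBV9	TRBJ2-5	CASSVTSGTLYF	TADFDITEL
r2_01	2	Mel#5	TRAV12-1	TRAJ12	CVVNGEDSSYKLIF	TRBV2	TRBJ2-2	CASSEGQVAPGELFF	EBV-reactive		7.6
r2_02	2	Mel#5	TRAV12-1	TRAJ12	CVVNGMDSSYKLIF	TRBV2	TRBJ2-2	CASSAGQVAPGELFF	EBV-reactive	0.00
r2_03	2	10X	TRAV12-1	TRAJ12	CVVNGGDSSYKLIF	TRBV2	TRBJ2-2	CASSEGQVSPGELFF	GLCTLVAML	0.06
r2_04	2	GI#1	TRAV5	TRAJ31	CAEDNNARLMF	TRBV20-1	TRBJ1-2	CSARDRTGNGYTF	orphan		28.0
r2_05	2	10X	TRAV5	TRAJ31	CAEDNNARLMF	TRBV20-1	TRBJ1-2	CSARDSTGNGYTF	GLCTLVAML	0.02
r3_01	3	Lung#1	TRAV26-2	TRAJ53	CILSDGGSNYKLTF	TRBV2	TRBJ2-7	CASSEPGYEQYF	orphan	0.00
r3_02	3	Lung#1	TRAV26-2	TRAJ53	CILSDGGSNYKLTF	TRBV2	TRBJ2-7	CASSDPGYEQYF	DSNDYHILR
r3_03	3	Lung#1	TRAV26-2	TRAJ53	CIPSDGGSNYKLTF	TRBV2	TRBJ2-1	CASSVPGYEQFF	orphan	0.00
r3_04	3	Lung#1	TRAV26-2	TRAJ53	CILSDGGSNYKLTF	TRBV2	TRBJ2-7	CASSDPGYEQYF	DSNDYHILR
r3_05	3	Lung#1	TRAV3	TRAJ40	CAVRDISTTSGTYKYIF	TRBV28	TRBJ1-2	CASSPPGDPIYGYTF	orphan	0.06
r3_06	3	Lung#1	TRAV3	TRAJ40	CAVRDISTTSGTYKYIF	TRBV28	TRBJ1-6	CASSSPGDSYNSPLHF	DSNDYHILR
r4_01	4	Mel#6	TRAV14/DV4	TRAJ26	CAMEEYGQNFVF	TRBV27	TRBJ2-4	CASSLSGGLYNEQFF	orphan	0.02
r4_02	4	Mel#6	TRAV14/DV4	TRAJ26	CAIINYGQNFVF	TRBV27	TRBJ2-4	CASSLSASGRVNIQYF	SLKLHYQL
r4_03	4	Mel#6	TRAV12-2	TRAJ52	CALGSAGGTSYGKLTF	TRBV6-5	TRBJ1-2	CASSPSGAPANYGYTF	orphan	0.05
r4_04	4	10X	TRAV12-2	TRAJ52	CAVNLGLTAGGTSYGKLTF	TRBV6-4	TRBJ1-2	CASRAGTEISGYGYTF	ELAGIGILTV
r4_05	4	Mel#6	TRAV12-2	TRAJ49	CAVNTGNQFYF	TRBV6-1	TRBJ1-5	CASSEAGVGQPQHF	orphan	0.06
r4_06	4	10X	TRAV12-2	TRAJ49	CAVPGSTGNQFYF	TRBV6-3	TRBJ1-5	CASSFGFGQPQHF	ELAGIGILTV
r4_07	4	Mel#6	TRAV12-2	TRAJ47	CAVTLTKYGNKLVF	TRBV11-2	TRBJ1-2	CASSLGGGPIGYTF	orphan	0.06
r4_08	4	10X	TRAV12-2	TRAJ39	CAANAGNMLTF	TRBV11-2	TRBJ1-2	CASSLGGGTEAFF	ELAGIGILTV
r4_09	4	Mel#6	TRAV12-2	TRAJ45	CAVNPGGGADGLTF	TRBV28	TRBJ2-1	CASTPPGTSGKSSYNEQFF	orphan	0.07
r4_10	4	10X	TRAV12-2	TRAJ32	CAVNGGGATNKLIF	TRBV28	TRBJ1-1	CAIPGPSNTEAFF	ELAGIGILTV
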