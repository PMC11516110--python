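# SYNTHETIC stand-in V-gene -> CDR1/CDR2 lookup (human TRAV/TRBV).
# IMGT-style germline CDR1/CDR2 loop sequences; curated from memory as a
# convenience default and NOT an authoritative IMGT export. Boundary
# convention: IMGT positions 27-38 (CDR1) and 56-65 (CDR2), gaps removed.
# Override with a verified IMGT-derived table for production analyses via
# read_vgene_lookup(path). Nothing in this package's tests depends on the
# biological correctness of these sequences.
# species: human
gene	cdr1	cdr2
TRAV1-2	TSGFNG	NVLDGL
TRAV3	VSGLRG	LYSAGEE
TRAV5	DSSSTY	IFSNMD
TRAV12-1	NSAFQY	TYSSGN
TRAV12-2	DRGSQS	IYSNGD
TRAV13-1	DSASNY	IRSNVGE
TRAV14/DV4	TSDQSYG	QGSYDEQN
TRAV17	TSINN	IRSNERE
TRAV26-2	TISGNEY	GLKNN
TRAV35	SIFNT	LYKAGEL
TRBV2	SNHLY	FYNNEI
TRBV4-1	MGHRA	YSYEKL
TRBV5-1	SGHRS	YFSETQ
TRBV6-1	MNHEY	SVGAGI
TRBV6-3	MNHEY	SVGAGI
TRBV6-4	MRHNA	SNTAGT
TRBV6-5	MNHEY	SVGAGI
TRBV7-9	SGHDY	FNNNVP
TRBV9	SGDLS	YYNGEE
TRBV11-2	SGHAT	FQNNGV
TRBV12-4	SGHDT	YYEEEE
TRBV14	SGHDN	FVKESK
TRBV20-1	DFQATT	SNEGSKA
TRBV27	MNHEY	SMNVEV
TRBV28	MDHEN	SYDVKM
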