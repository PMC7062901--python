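# Per-tumor census of the 12-tumor colorectal study (11 carcinomas + 1 adenoma, K).
# Phenotype tallies (pheno_s / pheno_i / pheno_si) cover primary-tumor subclones only;
# metastasis-only subclones (tumors C, J, H carry metastatic samples) are excluded
# from them, which is why e.g. tumor C has 9 subclones but an 8/0/0 tally.
# Tumor K's published subclone count is internally ambiguous (a count of 9 next to a
# 10/0/0 phenotype tally); it is encoded here with 10 subclones so that the per-tumor
# phenotype tallies and the study-wide phenotype totals (26/9/29) reconcile.
# n_invasion_events is empty (NA) for the non-invasive adenoma K.
tumor_id	n_spots	n_loci	n_subclones	pheno_s	pheno_i	pheno_si	monophyletic_inv	early_inv	multiclonal_inv	n_invasion_events	is_carcinoma
C	16	57	9	8	0	0	yes	yes	no	1	true
D	33	57	5	3	0	2	no	yes	yes	2	true
E	27	110	6	2	2	2	no	yes	yes	3	true
F	31	53	5	1	1	3	no	yes	yes	4	true
H	39	30	3	0	1	2	yes	yes	yes	3	true
J	27	28	1	0	0	1	yes	yes	no	1	true
K	29	41	10	10	0	0	NA	NA	NA		false
M	29	13	7	0	2	5	yes	yes	yes	7	true
R	15	58	3	0	1	2	yes	yes	yes	3	true
T	26	35	5	0	1	4	yes	yes	yes	5	true
U	23	29	4	1	1	2	no	yes	yes	3	true
W	30	68	7	1	0	6	no	yes	yes	6	true
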