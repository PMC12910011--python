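# geneburden 0.1.0
# config-digest 54a764ad0a35
# seed None
# n_genes_tested 1 bonferroni 0.05 sidak 0.05
gene	chrom	pos	dominant_stringent_case_carriers	dominant_stringent_control_carriers	dominant_stringent_p	dominant_relaxed_case_carriers	dominant_relaxed_control_carriers	dominant_relaxed_p	recessive_stringent_case_carriers	recessive_stringent_control_carriers	recessive_stringent_p	recessive_relaxed_case_carriers	recessive_relaxed_control_carriers	recessive_relaxed_p	recessive_cnv_case_carriers	recessive_cnv_control_carriers	recessive_cnv_p	min_p	best_model	tested	significant	suggestive
G0002	1	1100020	0	0	1.0	1	0	0.2727272727272727	0	0	1.0	0	0	1.0	0	0	1.0	1.0	dominant_stringent	False	False	False
G0001	X	1000000	0	0	1.0	0	0	1.0	0	2	1.0	0	2	1.0	0	2	1.0	1.0	dominant_stringent	False	False	False
RISK1	X	150000000	8	0	2.664312560246142e-05	8	0	2.664312560246142e-05	8	0	2.664312560246142e-05	8	0	2.664312560246142e-05	8	0	2.664312560246142e-05	2.664312560246142e-05	dominant_stringent	True	True	True
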