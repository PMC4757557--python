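# n_ref=2504
# Carrier frequencies (percent) of the 15 screen-significant genes in a 25-patient
# APL targeted-resequencing cohort and in the 1000-genomes reference population.
gene	cohort_frequency_pct	reference_frequency_pct	category
HERC1	44	3	ubiquitination
CACNA2D3	12	0.9	transmembrane protein
CACNA1E	16	0.6	protein kinase
MYCBP2	20	2	ubiquitination
KIAA0317	12	0.4	ubiquitination
SMC1A	12	0	cohesin complex
USP9X	12	0.09	spliceosome
TOP3B	12	0.9	transcription factor/regulator
PRICKLE2	8	0.1	other cell functions
IKZF1	8	0	transcription factor/regulator
LYN	8	0	tyrosine-protein kinase
STAG2	8	0.01	cohesin complex
PTPN11	8	0.01	transmembrane protein
U2AF1	8	0	spliceosome
TMEM56	8	0	transcription factor/regulator
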