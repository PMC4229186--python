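# Protein-altering variants found in the TSHZ3 gene by Sanger sequencing
# of a long-lived follow-up cohort (99 nonagenarians/centenarians),
# with carrier counts per age class and the reference-panel MAF
# (empty = novel, i.e. absent from the panel).
# Reference-cohort allele summary for the enrichment test:
#meta n_longlived=99
#meta control_carrier_alleles=213
#meta control_total_alleles=8600
#chrom	pos	ref	alt	aa_pos	aa_ref	aa_alt	supercentenarian_carriers	centenarian_carriers	nonagenarian_carriers	panel_maf
chr19	31769738	G	A	321	R	W	0	1	0	
chr19	31769366	C	T	445	V	M	1	0	0	0.0013
chr19	31769293	T	C	469	E	G	1	2	1	0.01
chr19	31769021	T	C	560	M	V	0	1	0	
chr19	31768639	G	A	687	P	L	1	0	0	
chr19	31768594	A	C	702	L	W	0	0	1	
chr19	31768267	G	A	811	T	M	0	1	0	
chr19	31768178	C	T	841	E	K	1	0	0	
chr19	31767599	C	T	1034	E	K	0	1	0	
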