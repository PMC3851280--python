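sample_id	chrom	start	end	gene	consequence	nucleotide_desc	protein_change	zygosity	reads_pct	depth	af_dbsnp	af_evs	af_tgp	af_inhouse	dbsnp_id	provean	sift	mutation_assessor	condel	polyphen2	known_neutral	splice_distance
1	Chr3	193171979	193171979	ATP13A4	nonsynonymous	g.1938A>T	p.Glu646Asp	heterozygous	60.47	43	NA	0.0886	0.05576	NA	rs35424709	neutral	neutral	damaging	damaging	damaging	false	NA
1	Chr6	24588884	24588884	KIAA0319	nonsynonymous	c.931G>A	p.Ala311Thr	heterozygous	52.08	96	NA	0.427	0.234	NA	rs4504469	damaging	damaging	damaging	damaging	damaging	false	NA
2	Chr3	193171979	193171979	ATP13A4	nonsynonymous	g.1938A>T	p.Glu646Asp	heterozygous	45.76	59	NA	0.0886	0.05576	NA	rs35424709	neutral	neutral	damaging	damaging	damaging	false	NA
4	Chr7	148106475	148106477	CNTNAP2	near_splice	c.3714-7insTTG		heterozygous	74.36	39	NA	NA	NA	NA	NA	unknown	unknown	unknown	unknown	unknown	false	7
4	Chr3	193171979	193171979	ATP13A4	nonsynonymous	g.1938A>T	p.Glu646Asp	heterozygous	53.97	63	NA	0.0886	0.05576	NA	rs35424709	neutral	neutral	damaging	damaging	damaging	false	NA
6	Chr7	146372040	146372040	CNTNAP2	nonsynonymous	c.511C>T	p.Arg171Cys	heterozygous	38.46	52	NA	NA	NA	NA	NA	damaging	damaging	damaging	damaging	damaging	false	NA
7	Chr17	38101263	38101263	CNTNAP1	nonsynonymous	c.3191G>A	p.Arg1064Gln	heterozygous	40	10	NA	NA	NA	NA	NA	damaging	damaging	damaging	damaging	damaging	false	NA
8	Chr3	71185577	71185577	FOXP1	nonsynonymous	c.320T>C	p.Ile107Thr	heterozygous	93.33	15	NA	NA	NA	NA	NA	damaging	damaging	damaging	damaging	damaging	false	NA
9	Chr6	24588884	24588884	KIAA0319	nonsynonymous	c.931G>A	p.Ala311Thr	heterozygous	41.96	112	NA	0.427	0.234	NA	rs4504469	damaging	damaging	damaging	damaging	damaging	false	NA
9	Chr9	135204010	135204010	SETX	nonsynonymous	g.2975A>G	p.Lys992Arg	heterozygous	48.17	191	NA	0.0009	0.0096	NA	NA	damaging	damaging	damaging	damaging	damaging	false	NA
10	Chr7	148106475	148106477	CNTNAP2	near_splice	c.3714-7insTTG		heterozygous	74.36	39	NA	NA	NA	NA	NA	unknown	unknown	unknown	unknown	unknown	false	7
10	Chr6	24588884	24588884	KIAA0319	nonsynonymous	c.931G>A	p.Ala311Thr	heterozygous	57.5	80	NA	0.427	0.234	NA	rs4504469	damaging	damaging	damaging	damaging	damaging	false	NA
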