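site_id	gene	beneficial_allele	alternate_allele	ihs	ihs_pop	xpehh	freq_AFR	freq_EAS	freq_EUR	freq_SAS
rs10000545	SEC24B	G	C	-2.96	EUR	3.59	0.172	0.882	0.874	0.819
rs28580356	SEC24B	T	C	3.06	AFR	3.87	0.492	0.000	0.002	0.000
rs28541279	SEC24B	G	T	3.04	AFR	3.85	0.494	0.000	0.002	0.000
rs28460762	SEC24B	C	A	4.07	AFR	3.85	0.492	0.000	0.002	0.000
rs423469	CTNNA1	G	C	-3.22	AFR	3.30	0.334	0.877	0.734	0.738
rs10043722	CTNNA1	A	G	-3.16	AFR	3.26	0.339	0.824	0.653	0.641
rs10112498	NCOA2	G	T	4.32	AFR	2.93	0.106	0.294	0.544	0.338
rs1870649	NCOA2	C	G	-3.50	AFR	3.21	0.111	0.294	0.677	0.370
rs8069478	ALDH3A2	T	G	3.00	AFR	-3.23	0.521	0.016	0.438	0.275
rs4925036	ALDH3A2	G	A	3.00	AFR	-3.21	0.521	0.016	0.449	0.276
rs962800	ALDH3A2	G	A	-3.07	AFR	-2.99	0.479	0.984	0.551	0.722
rs2386145	ALDH3A2	C	G	-2.93	AFR	-3.06	0.521	0.016	0.449	0.278
rs2108971	ALDH3A2	G	A	-2.81	AFR	-3.20	0.521	0.016	0.449	0.276
rs59755039	ALDH3A2	CT	C	-2.85	AFR	-3.41	0.521	0.016	0.449	0.276
rs8069576	ALDH3A2	A	G	-3.07	AFR	-3.11	0.521	0.016	0.449	0.276
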