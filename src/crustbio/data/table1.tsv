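genome_id	genome_type	isolation_source	assembly_size_mbp	gc_content_pct	n_contigs	max_contig_kbp	n50_bases	gene_count	completeness_pct	contamination_pct
AC-334-K11	SAG	U1362B	0.92	50.9	33	179	59108	1129	43.2	0.0
AC-708-L17	SAG	U1362A	1.26	50.7	39	191	70385	1499	69.5	1.6
AC-335-L21	SAG	U1362B	0.73	51.0	23	125	64756	877	48.8	0.8
AC-335-G21	SAG	U1362B	0.63	50.5	24	129	68317	763	39.2	0.0
AC-708-N22	SAG	U1362A	0.47	50.3	23	70.6	34461	543	22.9	0.0
JdFR-16	MAG	U1362B	1.35	49.7	24	45.2	6267	1715	31.1	7.3
JdFR-17	MAG	U1362A	2.18	49.6	133	39.6	7687	2771	53.9	25.2
JdFR-18	MAG	U1362A	2.06	39.1	422	364	149032	2320	96.8	2.4
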