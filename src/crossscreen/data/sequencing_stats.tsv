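sample	total_reads	unaligned_reads	unaligned_pct	uniquely_aligned_reads	uniquely_aligned_pct	clean_paired_reads	gc_pct	q30_pct
B311	73,532,158	7,269,362	9.88596	63,142,228	85.8702	36,787,767	42%	95.67%
B314	72,163,278	6,729,461	9.32533	62,789,055	87.0097	36,081,639	42%	95.68%
B316	73,688,664	6,925,219	9.39794	63,955,897	86.792	36,844,332	42%	95.66%
B319	73,511,268	6,445,136	8.76755	64,116,644	87.2202	36,755,634	42%	96.24%
B320	73,829,012	6,502,035	8.80688	64,631,140	87.5417	36,914,506	42%	95.57%
C401	73,517,946	6,853,528	9.32225	63,752,893	86.7175	36,758,973	42%	96.40%
C402	73,428,654	7,519,679	10.2408	62,603,346	85.2574	36,714,327	42%	96.79%
C407	73,539,408	6,771,803	9.2084	63,947,268	86.9565	36,769,704	42%	96.35%
C411	65,064,624	6,636,293	10.1995	55,704,018	85.6134	32,532,312	42%	91.20%
C412	73,430,222	6,913,259	9.41473	63,126,236	85.9676	36,715,111	42%	96.10%
O1102	73,749,910	6,707,802	9.09534	64,160,474	86.9974	36,874,955	42%	95.32%
O1112	73,671,940	6,572,557	8.92138	64,163,844	87.094	36,835,970	42%	95.45%
O1114	73,888,590	6,678,570	9.0387	64,367,737	87.1146	36,944,295	42%	95.67%
O1116	73,820,700	6,682,537	9.05239	64,336,901	87.1529	36,910,350	42%	95.52%
O1125	73,684,588	6,743,275	9.15154	64,208,342	87.1394	36,842,294	42%	95.68%
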