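snp_id	chrom	pos	gene_id	transcript_id	coding_change	protein_change
SNP 1	NW_013185657.1	483,398	106040530	XM_013188477.1	c.479G > A	Arg160Gln
SNP 2	NW_013185677.1	5,511,334	106033575	XM_013177200.1	c.3523C > A	Gln1175Lys
SNP 3	NW_013185696.1	595	106035773	XM_013180816.1	c.912G > A	Met304Ile
SNP 4	NW_013185696.1	615	106035773	XM_013180816.1	c.892T > G	Phe298Val
SNP 5	NW_013185720.1	3,081,938	106038401	XM_013184886.1	c.977G > A	Cys326Tyr
SNP 6	NW_013185720.1	3,082,790	106038401	XM_013184889.1	c.245G > A	Arg82Gln
SNP 7	NW_013185721.1	2,609,554	106038498	XM_013185039.1	c.1637A > G	Gln546Arg
SNP 8	NW_013185748.1	3,578,791	106040672	XM_013188695.1	c.522C > G	Phe174Leu
SNP 9	NW_013185750.1	69,680	106040872	XM_013189032.1	c.1442T > G	Ile481Ser
SNP 10	NW_013185760.1	14,289	106041536	XM_013190069.1	c.3349G > T	Val1117Phe
SNP 11	NW_013185766.1	956,541	106041864	XM_013190505.1	c.652A > G	Thr218Ala
SNP 12	NW_013185766.1	956,750	106041864	XM_013190505.1	c.861A > G	Ter287Ter
SNP 13	NW_013185800.1	639,495	106043465	XM_013192926.1	c.290G > A	Arg97Lys
SNP 14	NW_013185811.1	2,202,032	106043881	XM_013193607.1	c.509G > C	Arg170Thr
SNP 15	NW_013185811.1	2,202,034	106043881	XM_013193607.1	c.507G > C	Glu169Asp
SNP 16	NW_013185864.1	1,205,891	106045958	XM_013196755.1	c.298C > T	Leu100Phe
SNP 17	NW_013185870.1	1,328,057	106046235	XM_013197144.1	c.353C > T	Ala118Val
SNP 18	NW_013185914.1	62,943	106047476	XM_013198970.1	c.561A > C	Arg187Ser
SNP 19	NW_013185914.1	63,115	106047476	XM_013198970.1	c.389A > G	Glu130Gly
SNP 20	NW_013185915.1	942,834	106047517	XM_013199056.1	c.163A > G	Met55Val
SNP 21	NW_013185915.1	942,936	106047517	XM_013199056.1	c.265A > G	Thr89Ala
SNP 22	NW_013185925.1	822,558	106047720	XM_013199342.1	c.512G > A	Arg171His
SNP 23	NW_013186010.1	166,638	106049132	XM_013201311.1	c.92G > C	Gly31Ala
SNP 24	NW_013186010.1	166,674	106049132	XM_013201311.1	c.56G > A	Arg19His
SNP 25	NW_013186010.1	261,219	106049145	XM_013201321.1	c.25G > A	Ala9Thr
SNP 26	NW_013186017.1	261,566	106049239	XM_013201442.1	c.95A > C	Tyr32Ser
SNP 27	NW_013186061.1	144,964	106049600	XM_013201966.1	c.134A > C	Asn45Thr
SNP 28	NW_013186074.1	48,559	106049689	XM_013202086.1	c.620G > A	Arg207His
SNP 29	NW_013186089.1	144,070	106049779	XM_013202193.1	c.13A > T	Thr5Ser
SNP 30	NW_013186111.1	71,554	106049894	XM_013202325.1	c.422C > A	Thr141Asn
SNP 31	NW_013186111.1	71,555	106049894	XM_013202325.1	c.421A > C	Thr141Pro
SNP 32	NW_013186150.1	35,471	106029399	XM_013170682.1	c.397G > A	Ala133Thr
SNP 33	NW_013186231.1	6,643	106029521	XM_013170813.1	c.349G>T	Ala117Ser
SNP 34	NW_013186264.1	9,000	106029548	XM_013170832.1	c.303G > C	Leu101Phe
SNP 35	NW_013186857.1	861	106029642	XM_013170927.1	c.680T > C	Ile227Thr
SNP 36	NW_013187000.1	470	106029654	XM_013170934.1	c.200T > C	Ile67Thr
SNP 37	NW_013187000.1	667	106029654	XM_013170934.1	c.397A > G	Ile133Val
SNP 38	NW_013187000.1	1,090	106029654	XM_013170934.1	c.820G > A	Val274Ile
SNP 39	NW_013188772.1	217	106029704	XM_013170974.1	c.341G > A	Gly114Asp
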