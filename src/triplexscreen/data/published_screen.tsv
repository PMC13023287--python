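gene	chrom	lncrna_gene_id	lncrna_transcript_id	lncrna	distance_bp	target	shuffled_lncrna	shuffled_target	control	cpg_hits	accessible_hits	snp_inside
ERCC1	10	ENSECAG00000057790	ENSECAT00000129946	lnc129946	1194	35	4	2	14	4	35	True
ERCC1	10	ENSECAG00000047155	ENSECAT00000085946	lnc85946	5844	3	9	1	3	0	1	False
ERCC1	10	ENSECAG00000054326	ENSECAT00000134182	lnc134182	10607	9	2	1	2	0	9	False
ERCC1	10	ENSECAG00000047096	ENSECAT00000090102	lnc90102	17024	3	1	1	0	0	2	False
HTRA3	3	ENSECAG00000053540	ENSECAT00000117842	lnc117842	7260	14	8	1	1	14	14	True
HTRA3	3	ENSECAG00000051529	ENSECAT00000092675	lnc92675	38239	8	2	1	1	7	0	False
HTRA3	3	ENSECAG00000050690	ENSECAT00000082066	lnc82066	43648	25	11	2	1	24	25	False
PRSS21	13	ENSECAG00000046808	ENSECAT00000140240	lnc140240	10203	22	1	2	5	15	22	True
PRSS21	13	ENSECAG00000052223	ENSECAT00000086008	lnc86008	10786	2	2	1	1	0	0	False
PRSS21	13	ENSECAG00000051868	ENSECAT00000143931	lnc143931	49817	17	2	1	2	5	17	False
FOXA3	10	ENSECAG00000056523	ENSECAT00000122996	lnc122996	39064	6	2	2	3	5	6	False
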