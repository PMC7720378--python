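chrom	n_loci	n_in_exons	n_with_probes	n_in_exons_with_probes
chr1	5344	107	4882	107
chr2A	4989	54	3946	54
chr2B	8403	65	6711	64
chr3	7120	72	5802	69
chr4	7090	56	5707	56
chr5	6948	55	5417	52
chr6	6655	59	5553	58
chr7	6024	58	4697	58
chr8	7199	47	5323	47
chr9	8111	66	6442	66
chr10	4992	66	4617	65
chr11	3566	50	3168	50
chr12	6049	60	4517	60
chr13	6695	22	4978	22
chr14	2835	35	2434	35
chr15	5829	46	4762	44
chr16	12784	104	11080	104
chr17	22994	127	18399	124
chr18	8720	22	7444	22
chr19	5976	71	4488	71
chr20	9660	50	8342	50
chr21	3610	27	3019	27
chr22	3751	32	3035	32
chrX	9782	16	6334	15
chrM	1	0	0	0
chrUn	59	8	59	8
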