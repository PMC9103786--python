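# Published regulatory-divergence category counts of W-linked chicken genes,
# per tissue and reciprocal-cross group (group 1: Cor dam; group 2: WL dam).
tissue	group	cis_dominant	trans_dominant	trans_additive	trans_overdominant	trans_underdominant	conserved
brain	1	11	0	4	0	1	1
brain	2	0	10	3	1	1	2
liver	1	8	6	6	1	0	0
liver	2	7	6	1	3	1	3
muscle	1	11	6	2	5	8	0
muscle	2	7	10	7	4	2	2
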