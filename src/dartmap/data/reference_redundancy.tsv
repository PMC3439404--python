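preset	word_length	index_word_length	mismatch_pct	ambiguities	gap_pct	gap_size_bp	n_singletons	n_redundant_members	n_clusters
A1	18	13	10	4	10	1	3209	3709	1374
A2	14	12	15	4	15	2	2607	4311	1537
A3	12	11	20	16	20	5	2381	4537	1587
A4	10	10	20	16	20	5	2276	4642	1588
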