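lineage	n_cells	is_epithelial
BT	4226	1
CAF	1149	0
CYC	1223	1
LEC	1254	1
LP	3574	1
LT	7514	1
MEC	2382	1
PVL	1487	0
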