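patient	treatment	n_cells
318	UT	2007
318	NDexo	2384
318	T2Dexo	2562
377	UT	5396
377	NDexo	6915
377	T2Dexo	4953
409	UT	164
409	NDexo	124
409	T2Dexo	94
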