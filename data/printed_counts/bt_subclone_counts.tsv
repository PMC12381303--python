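subclone	n_cells
BT1	4084
BT2	142
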