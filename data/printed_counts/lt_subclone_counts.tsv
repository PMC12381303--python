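subclone	n_cells
LT1	3397
LT2	2669
LT3	925
LT4	398
LT5	125
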