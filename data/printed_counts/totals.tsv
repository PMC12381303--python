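quantity	n_cells
total_cells	24599
epithelial_cells	20173
lt_cells	7514
bt_cells	4226
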