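# Single 4-hole cell, horizontal voltage drive, standard error sweep.
model: a
holes: four
injection: horizontal
N_list: [32, 64, 128, 256]
sigma0: 1.0
sigmaA: 0.001
tol: 1.0e-6
N_fine: 1536
bc_style: voltage
# output_dir: results/model_a
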