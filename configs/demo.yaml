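# Demo pipeline config: fully synthetic study, all stages.
outdir: scratch/demo_run
seed: 1
synthetic: true
n_sims: 1000
n_shuffles: 1000
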