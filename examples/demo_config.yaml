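# Full-pipeline configuration for the synthetic demo study.
# First generate the inputs:   anole-admix synth --seed 1 --out demo_data
# Then run:                    anole-admix run --config examples/demo_config.yaml
genepop: demo_data/genotypes.gen
mtdna_alignment: demo_data/mtdna_hybrid.fasta
mtdna_references: demo_data/mtdna_refs.fasta
annotations: demo_data/annotations.csv
out_dir: demo_out
seed: 3
abc_sims: 2000
abc_keep: 100
ppc_draws: 50
hwe_reps: 2000
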