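# Packaged ChIP peak scenario mirroring the study's sequencing design:
# 3 pools x 4 ChIP replicates (12 ChIP libraries), 15 planted target genes
# on a 200-gene synthetic genome, with per-replicate background peaks.
seed: 92942
n_chromosomes: 3
chrom_length: 20000000
n_genes: 200
gene_length_mean: 20000
gene_length_sd: 8000
planted_targets: [g0001, g0002, g0003, g0004, g0005, g0006, g0007, g0008,
                  g0009, g0010, g0011, g0012, g0013, g0014, g0015]
n_pools: 3
replicates_per_pool: 4
peaks_per_target_per_replicate: 1
background_peaks_per_replicate: 25
peak_width_mean: 400
peak_width_sd: 150
jitter_sd: 300
target_dropout: 0.1
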