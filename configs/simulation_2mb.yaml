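# The shipped simulation fixture: a 2-Mb two-chromosome genome with
# study-like conditions (3 replicates per condition, 14x mean coverage,
# CHH-dominant cytosine densities) and 100 injected 500-bp CHH DMRs at
# -30 pp, of which 40 sit in gene promoters and drive expression.
seed: 2020
n_chroms: 2
chrom_length: 1000000
n_coupled: 40
n_uncoupled: 60
delta: -30.0
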