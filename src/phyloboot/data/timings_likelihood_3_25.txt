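# Elapsed wall-clock seconds for a 1,000-replicate bootstrapped protein
# maximum-likelihood run on a 25-sequence x 1139-site three-gene alignment
# (MPI-parallel PHYLIP proml, SGI Altix, one chunk of replicates per core).
# processors seconds
4 143130
8 72456
16 35863
32 18938
64 9968
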