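# Elapsed wall-clock seconds for a 1,000-replicate bootstrapped protein
# parsimony run on a 121-sequence x 356-site alignment (MPI-parallel PHYLIP
# protpars, SGI Altix, one chunk of replicates per core).
# processors seconds
4 33518
8 17105
16 8815
32 5115
64 3040
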