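# Elapsed wall-clock seconds for a 1,000-replicate bootstrapped protein
# distance run on a 121-sequence x 356-site alignment (MPI-parallel PHYLIP
# protdist, SGI Altix, one chunk of replicates per core).
# processors seconds
4 42416
8 21233
16 11806
32 5507
64 2941
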