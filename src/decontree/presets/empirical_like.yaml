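# Structure of a real contaminated nematode assembly: most contaminants are
# low-coverage bacteria spanning a wide GC range; a second component has
# target-like coverage but high GC. Labels carry a little noise (database
# contamination) and a fraction of scaffolds has no BLAST hit.
name: empirical_like
target_genus: Caenorhabditis
target_taxon: Caenorhabditis remanei
contaminant_taxa:
  - Chryseobacterium sp.
  - Stenotrophomonas maltophilia
  - Rhodococcus erythropolis
label_noise: 0.01
unknown_fraction: 0.08
n_target: 3000
n_contam: 1000
target:
  - weight: 1.0
    gc_range: [0.30, 0.50]
    dna_depth_mean: 60.0
    dna_depth_sd: 15.0
    rna_breadth_mean: 0.35
    rna_breadth_conc: 30.0
    rna_expr_mean: 30.0
    length_meanlog: 8.8
    length_sdlog: 1.1
contaminant:
  - weight: 0.65
    gc_range: [0.35, 0.70]
    dna_depth_mean: 5.0
    dna_depth_sd: 3.0
    rna_breadth_mean: 0.75
    rna_breadth_conc: 25.0
    rna_expr_mean: 20.0
    length_meanlog: 7.8
    length_sdlog: 1.0
  - weight: 0.35
    gc_range: [0.60, 0.70]
    dna_depth_mean: 60.0
    dna_depth_sd: 15.0
    rna_breadth_mean: 0.80
    rna_breadth_conc: 25.0
    rna_expr_mean: 20.0
    length_meanlog: 7.8
    length_sdlog: 1.0
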