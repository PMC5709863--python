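# GC-rich microbial contamination of a metazoan assembly: contaminant and
# target separate jointly in GC and DNA depth, and differ strongly in
# coding density (RNA breadth). Editable; loaded by decontree.simulate.
name: separable
target_genus: Caenorhabditis
target_taxon: Caenorhabditis elegans
contaminant_taxa:
  - Escherichia coli K-12
  - Pseudomonas aeruginosa PAO1
  - Agrobacterium radiobacter
label_noise: 0.0
unknown_fraction: 0.05
n_target: 1000
n_contam: 1000
target:
  - weight: 1.0
    gc_range: [0.24, 0.48]
    dna_depth_mean: 100.0
    dna_depth_sd: 20.0
    rna_breadth_mean: 0.25
    rna_breadth_conc: 40.0
    rna_expr_mean: 30.0
    length_meanlog: 9.0
    length_sdlog: 1.0
contaminant:
  - weight: 1.0
    gc_range: [0.50, 0.69]
    dna_depth_mean: 20.0
    dna_depth_sd: 6.0
    rna_breadth_mean: 0.85
    rna_breadth_conc: 40.0
    rna_expr_mean: 30.0
    length_meanlog: 8.0
    length_sdlog: 0.9
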