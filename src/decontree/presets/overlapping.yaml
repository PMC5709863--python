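# Fungal (yeast-like) contamination: contaminant GC range sits inside the
# target's and DNA depth distributions coincide, so GC + depth alone cannot
# discriminate. Most contaminant scaffolds betray themselves through the
# RNA-derived predictors (gene-dense contaminant vs gene-sparse metazoan
# target); a minority component transcribes at host-like levels and is
# separable only by its patchy DNA breadth (fragmented, under-assembled
# contaminant sequence), so full discrimination needs several predictors.
name: overlapping
target_genus: Takifugu
target_taxon: Takifugu rubripes
contaminant_taxa:
  - Candida albicans SC5314
label_noise: 0.0
unknown_fraction: 0.05
n_target: 1000
n_contam: 1000
target:
  - weight: 1.0
    gc_range: [0.24, 0.72]
    dna_depth_mean: 100.0
    dna_depth_sd: 20.0
    rna_breadth_mean: 0.22
    rna_breadth_conc: 40.0
    rna_expr_mean: 30.0
    length_meanlog: 9.0
    length_sdlog: 1.0
contaminant:
  - weight: 0.75
    gc_range: [0.23, 0.53]
    dna_depth_mean: 100.0
    dna_depth_sd: 20.0
    rna_breadth_mean: 0.70
    rna_breadth_conc: 40.0
    rna_expr_mean: 30.0
    length_meanlog: 8.4
    length_sdlog: 1.0
  - weight: 0.25
    gc_range: [0.23, 0.53]
    dna_depth_mean: 100.0
    dna_depth_sd: 20.0
    rna_breadth_mean: 0.25
    rna_breadth_conc: 40.0
    rna_expr_mean: 30.0
    length_meanlog: 8.4
    length_sdlog: 1.0
    dna_align_mean: 0.60
    dna_align_conc: 20.0
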