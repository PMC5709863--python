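# decontree

Decision-tree decontamination of *de novo* genome assemblies.

Draft assemblies of non-model eukaryotes routinely contain scaffolds that do
not belong to the sequenced organism — bacteria from the culture or gut,
fungi, reagent contaminants. Removing them by BLAST alone fails for the many
scaffolds with no database match. `decontree` instead treats decontamination
as supervised classification: BLAST labels the scaffolds it can, a tree
model learns what target and contaminant scaffolds look like in terms of
measurable sequence features, and every scaffold — including those with no
BLAST hit — is then classified and the predicted-target subset written out
as the cleaned assembly.

Eight per-scaffold predictor variables are used: (1) length, (2) GC
content, (3) mean DNA sequencing depth, (4) mean RNA sequencing depth,
(5) breadth of DNA coverage, (6) breadth of RNA coverage (a gene-density
proxy), (7) GC of aligned DNA reads and (8) GC of aligned RNA reads.

## The model

Binary CART trees are grown by exhaustive threshold search over the
predictors, scoring candidate splits with Gini's diversity index
*G* = Σᵢ *pᵢ*(1 − *pᵢ*) (or, optionally, information gain
*IG*(*A*,*S*) = *H*(*S*) − Σₜ *p*(*t*)*H*(*t*) with entropy
*H*(*S*) = −Σₓ *pₓ* log₂ *pₓ*). A leaf classifies by minimizing expected
misclassification cost, *ŷ* = argmin_y Σₖ *P̂*(*k*|*x*) *C*(*y*|*k*); with
the default 0/1 costs this is the majority class. On top of the single
tree:

* **bagging** (the default model): *B* = 100 trees on bootstrap resamples,
  averaged as *f̂*_bag(*x*) = (1/*B*) Σ_b *f̂*\*ᵇ(*x*);
* **random forest**: per-split sampling of *m* = 4 of the *p* = 8
  predictors, 5000 trees (equivalent to bagging at *m* = *p*);
* **boosting**: 10 shallow trees (2 splits each) fit to residuals of the
  0/1 target indicator with shrinkage 0.01.

Variable importance is the (node-size weighted) Gini impurity decrease
summed over each predictor's splits and averaged over trees.

## Worked example

Synthetic regimes ship with the package. The `overlapping` preset emulates
a fungal contaminant whose GC range and DNA depth match the target's, so
discrimination must come from RNA evidence and coverage breadth:

```python
import pandas as pd
from decontree import (BaggedTrees, simulate_predictor_table,
                       simulate_blast_labels, split_training,
                       confusion, metrics)

table, truth = simulate_predictor_table("overlapping", seed=1)
labels = simulate_blast_labels(truth, unknown_fraction=0.05,
                               mislabel_rate=0.0, seed=1)
split = split_training(labels, fraction=0.5, seed=1)
lab = pd.Series(labels.entries)

res = BaggedTrees(table.loc[list(split.train_ids)],
                  lab.loc[list(split.train_ids)], B=100, seed=1).fit()
print(res.summary())
m = metrics(confusion(res.predict(table.loc[list(split.test_ids)]),
                      lab.loc[list(split.test_ids)]))
print(f"accuracy={m.accuracy:.4f} sensitivity={m.sensitivity:.4f} "
      f"specificity={m.specificity:.4f}")
```

prints

```
Bagging model
  trees: 100
  training scaffolds: 949
  predictors: length, gc, dna_mean_depth, rna_mean_depth, dna_breadth, rna_breadth, dna_read_gc, rna_read_gc
  decision threshold: 0.5
  Gini importances:
    rna_breadth     0.5676
    dna_breadth     0.4291
    gc              0.0017
    length          0.0014
    dna_mean_depth  0.0002
    rna_read_gc     0.0000
    rna_mean_depth  0.0000
    dna_read_gc     0.0000
accuracy=0.9916 sensitivity=0.9875 specificity=0.9957
```

The importances say what the model discovered: in this regime GC and DNA
depth carry almost no signal, and classification rests on RNA breadth
(gene density) and DNA breadth. A single tree restricted to `gc` and
`dna_mean_depth` leaves >10% held-out error on the same data; the
eight-predictor bagged model recovers >99% accuracy.

## Command line

```sh
decontree simulate separable --seed 1 --out-dir bundle   # toy fixture
decontree predictors bundle/assembly.fasta --dna bundle/dna.depth.tsv \
    --rna bundle/rna.depth.tsv --out pred.tsv
decontree label bundle/hits.tsv --target-genus Caenorhabditis \
    --table pred.tsv --out labels.tsv
decontree train --table pred.tsv --labels labels.tsv --param B=100 \
    --out model.json
decontree run --config run.yaml            # end-to-end: kept.fasta + report
```

Real inputs are an assembly FASTA, DNA/RNA alignments (SAM/BAM, or
pre-computed depth TSVs) and BLAST outfmt-6 hits; alignment and BLAST are
run upstream with your tools of choice.

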