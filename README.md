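# crevip

Cell-class-specific **gapped k-mer SVM** (gkm-SVM) models of chromatin
accessibility, and **deltaSVM-style Variant Impact Prediction (VIP)** for
single-nucleotide variants and indels in candidate cis-regulatory elements
(CREs).

## Who this is for

Regulatory genomicists who have per-cell-class accessibility peak calls
(e.g. pseudobulked snATAC-seq narrowPeak files) and want to

1. train one sequence classifier per cell class that separates that class's
   accessible regions from GC-matched genomic background,
2. ask which transcription-factor vocabulary drives each model (top-ranked
   k-mers, motif counts, cross-model enrichment z-scores),
3. predict the cell-class-specific impact of any variant — in-silico
   saturation mutagenesis, per-base VIP tracks, motif-centred disruption
   profiles, and scoring of external variant tables — and
4. validate predictions against massively parallel reporter assay (MPRA)
   expression changes.

The package also ships a first-class synthetic-data generator
(`crevip.simulate`) that builds multi-class peak sets with planted motif
grammars and a simulated reporter assay, so the entire workflow can be
exercised and benchmarked with known ground truth.

## The model

A sequence *s* is represented by its **gapped k-mers**: length-*l* words with
*k* informative positions (defaults *l* = 11, *k* = 7). The kernel between two
sequences is the inner product of their gapped k-mer count vectors, computed
without enumerating features: every pair of l-mers (u, v) with Hamming
distance *m* shares

&nbsp;&nbsp;&nbsp;&nbsp;C(l − m, k)  gapped k-mers  (0 when l − m < k),

summed over all l-mer pairs, with the second sequence contributing both
strands, and normalised K(x,y)/√(K(x,x)K(y,y)). A soft-margin SVM is fitted
per cell class on the precomputed kernel matrix (positives: top-scoring,
non-universal, fixed-width peak regions; negatives: GC-matched background).

From a trained model the package extracts a weight for **every possible
l-mer** — its decision value minus the bias. The additive score of a sequence
is the sum of its sliding l-mer weights, and the VIP of a variant is the
deltaSVM difference

&nbsp;&nbsp;&nbsp;&nbsp;VIP = score_additive(alt sequence) − score_additive(ref sequence),

which for an SNV reduces exactly to the ≤ l windows covering the edited base.
Negative VIP predicts loss of accessibility-like sequence under that class's
model.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/01_kernel_and_training.py
training accuracy : 1.000
pooled 5-fold AUROC: 0.990
score(motif-bearing) = +0.423
score(background)    = -1.000
```

A 30-vs-30 toy with the word GATTACA planted in positives is almost perfectly
separated by a 5-mer/3-informative model; positive decision values mean
"accessible-like". `02_synthetic_study.py` runs the full curation + training
on three synthetic cell classes and prints the cross-class score matrix (the
diagonal is the row maximum — each model recognises its own class best);
`03_variant_impact.py` shows saturation-mutagenesis VIP concentrating at a
planted motif (mean summed VIP −11.4 inside the motif vs −0.96 outside);
`04_mpra_comparison.py` correlates VIP with a simulated reporter assay
(r ≈ +0.69 in the expressing class vs ≈ +0.07 in a non-expressing one).

The same workflow is scriptable from a shell via the thin CLI:

```bash
crevip simulate --outdir work           # synthetic genome + peaks + motifs
crevip prepare  --outdir work           # curated train/outgroup/negatives
crevip train    --outdir work           # models, CV, cross-class matrix
crevip vip      --outdir work           # vocabulary, profiles, VIP tracks
```

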