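# Methods

## The gapped k-mer kernel and its implementation

The kernel treats a sequence as the multiset of its length-*l* words and
counts shared *gapped k-mers* — subwords on *k* of the *l* positions. Two
l-mers at Hamming distance *m* agree on a k-subset of positions in exactly
C(l − m, k) ways, so the raw kernel is

    K_raw(x, y) = Σ_{u ∈ x} Σ_{v ∈ y±} C(l − ham(u, v), k),

where y± is y's l-mers from both strands when both-strand counting is on
(the default). Both-strand counting makes the kernel — and therefore
decision values, k-mer weights and VIP scores — invariant to reverse
complementation of any input. The kernel used for training is the
cosine-normalised K_raw/√(K_xx·K_yy). A truncated variant (max_mismatch
< l − k) is supported but not the default.

Implementation: l-mers are packed into 32-bit integers (2 bits per base);
the Hamming distance of a pair is the popcount of
`(x XOR y) OR ((x XOR y) >> 1)` on the even bit positions, via a 16-bit
lookup table inside a numba loop, with an early exit once the low half of the
popcount already exceeds the mismatch cutoff. A 720 × 720 kernel matrix over
301 bp sequences (l = 11) costs ≈ 85 s on one CPU. Exactness is asserted
against an independent brute-force oracle that enumerates explicit gapped
k-mer count vectors (integers, zero tolerance).

## Training, cross-validation, cross-class scoring

One binary SVM per cell class (scikit-learn SVC, precomputed kernel,
C = 1.0 by default) on equal numbers of positives and GC-matched negatives.
A 1e-8 diagonal jitter guards conditioning; a Cholesky check rejects
non-PSD matrices. Hyperparameters l = 11, k = 7, untruncated mismatch
profile and C = 1.0 are the conventional defaults of gkm-SVM tooling; all
are exposed in `GkmParams`/`PipelineConfig`.

Five-fold stratified cross-validation reuses the one precomputed kernel
matrix; ROC and precision-recall curves are reported per fold, AUROC by the
trapezoidal rule, both per fold and pooled over out-of-fold decision values.
The cross-class matrix scores every class's cross-filtered outgroup peak set
with every model (mean decision value) and orders rows by average-linkage
hierarchical clustering on correlation distance.

A degenerate note: if the same sequences appear as positives and negatives,
the symmetric problem has no signal and all decision values collapse to ~0;
the 0/1 training-accuracy number is then ill-defined (tie-breaking and the
diagonal jitter decide it) and should be ignored.

## The complete l-mer weight table

The weight of an l-mer u is the model's decision value on the bare word u
minus the bias, so weights are centred and summable. Computing all 4^11 =
4,194,304 weights word-by-word would require an all-pairs scan against every
support-vector l-mer; instead the table uses the identity

    C(l − m, k) = #{k-position subsets on which u and v agree},

which factorises the support-vector contribution into one 4^k-entry table
per position subset (330 subsets at l = 11, k = 7): scatter the weighted
support l-mers into each table, then gather per subset over all 4^l words.
The per-word normalisation √K(u,u) (which depends on ham(u, rc(u)) under
both-strand counting) is applied vectorised. The full table costs ≈ 20 s per
model and is asserted equal (atol 1e-9) to the direct decision-value
definition on small alphabets. Truncated-mismatch models fall back to the
direct path (restricted to l ≤ 8).

## deltaSVM / VIP

The additive score of a sequence is the sum of its sliding l-mer weights
(forward strand only — the weights are already strand-symmetric). A
variant's VIP is the additive score difference alt − ref; for SNVs only the
≤ l covering windows change, and the windowed sum is exactly equal to the
full rescore (asserted to 1e-9 on 1000 random variants). Indels and
multi-site deletions are scored by rescoring the whole edited context; no
window alignment is attempted, so single and combinatorial deletions are
each evaluated independently. VIP is local: it depends only on sequence
within l − 1 bp of the edit, so any context ≥ l − 1 bp per side (default
150) gives identical scores.

Saturation mutagenesis emits 3 alternates × width entries per region
(positions containing N are skipped and logged); the summed track adds the
three alternate VIPs per position and is written as single-base bedGraph.
Motif-centred profiles average VIP over all occurrences of a motif (PWM
scan at ≥ 80% of the maximum log-odds score by default, palindromic
double-hits collapsed to the forward strand) at each offset in a ±30 bp
window (±25 also available), flipping minus-strand occurrences into motif
orientation.

## Peak curation

Summits are extended ±150 bp (width 301); windows clipped at contig ends are
dropped, keeping widths uniform for the kernel. A region is "universally
accessible" when it overlaps (≥ 1 bp by default) a region of every other
class; universal regions are removed before the top-N (25,000) selection by
peak score (ties broken by coordinate), then an 80/20 seeded split produces
train/outgroup sets, and outgroup regions overlapping any class's training
regions are removed so no model is evaluated on sequence any model saw.
Negatives are width-matched genomic tiles (step width/2) excluding all raw
peak territory and N-containing windows, sampled without replacement to
match the positives' GC histogram bin-for-bin (bin width 0.05); a bin that
cannot be filled is an error naming the bin. The negative:positive ratio is
1:1.

## PWM scanning and vocabulary enrichment

PFMs are JASPAR text matrices; scanning scores log2 odds against a uniform
background with a pseudocount of 1% of the column sum. A hit is a placement
reaching `threshold_frac` (default 0.8) of the scored window's maximum
attainable score; both strands are scanned. When a word is shorter than the
PWM the word slides within the PWM and is thresholded against each
sub-window's own maximum. Per model, the full l-mer vocabulary is ranked by
weight (ties lexicographic) and the top 1% scanned; counts are hit counts
(a k-mer can contribute several), optionally restricted to an
expressed-TF whitelist, and enrichment is the per-motif (row-wise) z-score
across model columns with sample (n−1) standard deviation; constant rows
get z = 0.

## The synthetic benchmark

The generator emulates the statistical structure of multi-class ATAC peak
sets with known ground truth. Defaults (the study conditions used by the
tests and the acceptance script): 3 classes × 500 peaks, region width
301 bp, a 2 Mb i.i.d. background genome at GC 0.41 (human-like), two motifs
per class with classes 0 and 1 sharing one motif (so related "grammars"
exist for the clustering analyses), a 10% universally accessible fraction
carrying a housekeeping motif and identical coordinates in every class, 1–3
motif instances per peak at random offsets/strands, sampled from the PFM,
and peak scores decreasing with index. Motif PFMs are generated with
per-column consensus probability U(0.80, 0.97) (mean information content
> 1 bit/position) and pairwise consensus Hamming distance ≥ length/2.

Planted motifs are 10 bp. The length matters for the reporter simulation:
the best chance match of an 8-bp PWM in a ~230 bp construct reaches ~0.8 of
the maximum log-odds score, which would let "absent" motifs carry signal;
at 10 bp the chance best-hit stays near 0.5, cleanly below the signal floor.

The simulated MPRA defines a class's expression as Σ_motifs β ·
h(best-hit fraction), where h is a continuous hinge: 0 below a floor of 0.6
(chance-level matches), rising linearly to 1 at a perfect match. Gaussian
noise (SD 0.15) is added per replicate (3 replicates averaged), and the
expression change is variant minus reference. The hinge makes expression
strictly decreasing in planted-motif damage until a hit decays to background
level, gives exactly zero signal for classes whose motifs are absent, and
makes the deletion of a consensus instance change expression by exactly −β.
The generative model is additive across motifs by construction; the VIP
predictor is under no such constraint.

What the generator does *not* emulate: higher-order background sequence
structure (it is i.i.d.), overlapping/cooperative motif grammar, chromatin
state, fragment-level ATAC signal or barcode-level MPRA counts. Passing the
benchmark therefore demonstrates that the machinery recovers planted
sequence signal under clean conditions, not that real peak sets reach any
particular accuracy.

## Problem sizes and numerical choices

The benchmark sizes (500 peaks/class → ~720-sequence training sets, 90
outgroup regions/class, a 200-variant reporter panel, one 4^11 weight table
per model) were chosen so the whole study runs end-to-end in minutes on a
single CPU while leaving each qualitative behaviour (AUROC ≥ 0.9, diagonal
dominance, motif-profile and vocabulary specificity, the expressing /
non-expressing MPRA contrast) comfortably reproducible. Ties are always
broken deterministically (coordinate order for peaks, lexicographic for
k-mers); every stochastic step takes an explicit seed, and a fixed-seed
end-to-end rerun is byte-identical — provenance headers record the seed and
a hash of the scientific parameters (input paths excluded so the hash is
location-independent).

## Known limitations

- The O(n²) precomputed kernel limits training to a few thousand sequences
  per class; the large-scale tricks of production gkm-SVM tools (k-mer
  trees, sampled support vectors) are out of scope.
- Weight tables are materialised densely, so l ≤ 13 in practice (l = 11
  default).
- Cross-model VIP scores are not calibrated to a common scale; compare
  variants within a model, as the downstream analyses here do.
- Indel VIP compares additive scores of whole edited constructs; there is
  no alignment-aware window matching.
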