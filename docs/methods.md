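# Methods

`dasv` detects genomic deletions (structural variants, i.e. events of at
least 50 bp) in long-read alignments. The pipeline converts per-read CIGAR
evidence into fixed-size multi-modal window encodings and classifies each
window with a dual-attention convolutional network; positive windows are
merged back into base-resolution deletion calls.

## Pipeline

1. **Quality control.** Alignments with mapping quality below 20 are
   removed, as are unmapped (FLAG bit 4), secondary (256), duplicate (1024)
   and supplementary (2048) records. The filter is order-preserving and
   idempotent. Duplicate removal is configurable (`drop_flags`).
2. **Candidate framing.** Every CIGAR `D` operation of at least
   `min_del_len` = 30 bp becomes one piece of deletion evidence (30 bp
   admits fragmented evidence of true >= 50 bp events while excluding the
   pervasive small-indel noise of noisy long reads). Evidence on a
   chromosome is merged by single-linkage clustering with a 50 bp gap
   allowance — one stride, chosen because sequencing errors fragment a
   single deletion into nearby `D` ops. Clusters are kept when their read
   support reaches `max(2, ceil(0.2 x mean depth))`: a fifth of the mean
   depth admits heterozygous events (roughly half-depth support) with
   margin for a 15% base error rate, while the floor of 2 suppresses
   singleton noise. Retained regions are padded by 50 bp per side and tiled
   into 100 bp windows with a 50 bp stride, so every interior base is seen
   by two windows and breakpoints near region edges land mid-window.
3. **Window encoding.** Each window yields three inputs:
   * `S`: a length-100 integer consensus track. A column is coded 9 when at
     least half the covering reads place a deletion there; otherwise the
     plurality base is coded A=2, C=3, T=4, G=5 (ties break to the lowest
     code); uncovered columns are 0, which is also the pad value for
     windows truncated at a contig end. `S` is a per-window consensus
     rather than a per-read matrix: a single track matches the fixed
     zero-padded length of 100 and is the main interpretive choice of the
     encoding (see Limitations).
   * `I1`: a 100x100 RGB image on white, one read per pixel row (top to
     bottom by alignment start), one reference offset per column. Matches
     paint green (0,255,0), deletions red (255,0,0), soft clips blue
     (0,0,255) outward from the alignment ends (clips consume no reference,
     so their footprint is drawn into the adjacent columns, truncated at
     the window edge), and insertions a single black (0,0,0) column at
     their anchor. More than 100 overlapping reads are row-compressed by
     uniform rank subsampling, which preserves the visual depth structure
     without colour blending; fewer than 100 leave the remaining rows
     white.
   * `I2`: the binary attention image — white exactly where `I1` is red,
     black elsewhere. It carries no independent information; it exists to
     steer spatial attention toward deletion evidence.
4. **Classification.** See "Model" below; the output is a per-window
   deletion probability.
5. **Call assembly.** Windows with probability at or above the threshold
   (default 0.5) are grouped by the evidence cluster they overlap. Each
   cluster with at least one positive window produces one call whose
   breakpoints are the median per-read evidence start and end — read
   evidence is base-resolution whereas windows are 50 bp-grained — whose
   score is the mean probability of its supporting windows, and whose
   support is the cluster's read count. Calls shorter than 50 bp are
   discarded. VCF 4.2 output uses symbolic `<DEL>` alleles with POS the
   base before the event, `END`, negative `SVLEN`, `SUPPORT`, and
   QUAL = -10 log10(1 - score) capped at 60.

## Model

Two branches process each window, with three scales each (100, 50, 25
positions; 2x2 max pooling between scales; the first scale is not
downsampled):

* **Image branch.** A 3x3 convolutional stem maps `I1` to the first-scale
  channel count. A second stem convolution over `I2` produces the guide
  features; the two are multiplied elementwise and softmax-normalised over
  the spatial positions within each channel (each channel's attention
  weights sum to 1), and the map reweights the `I1` features. The
  normalisation axis is spatial because the mechanism's job is to weight
  *regions*. Three residual stages follow (conv-norm-relu-conv-norm plus
  an additive identity shortcut), each emitting a feature tap.
* **Sequence branch.** The integer codes of `S` are embedded (16
  dimensions) and passed through mirrored 1-D residual stages. At every
  scale, channel attention derived from the image tap gates the sequence
  channels: global average pooling and global max pooling of the image
  features are each recalculated by a learned linear map, summed, passed
  through a sigmoid, and the resulting per-channel weights in (0,1)
  multiply the sequence channels. Applying the gate at every scale (rather
  than once) makes the multi-scale fusion concrete; a single-scale variant
  can be configured by reducing `n_scales`.
* **Head.** Both final feature maps are globally average-pooled,
  concatenated, and passed through a dense layer with a multiplicative
  residual recalculation (`h * sigmoid(Wh) + h`), dropout, and a sigmoid
  output.

The **simple-fusion ablation** keeps the identical backbone and head but
removes both attention mechanisms: `I2` is ignored and branch features are
fused only by the head's concatenation. The two variants therefore differ
in parameter count by exactly the attention sub-modules, which makes the
ablation comparison clean.

### Normalisation choice

Residual blocks use per-sample channel normalisation (each sample's channel
standardised over its own positions, with a learned affine) rather than
batch statistics. The spatial-attention softmax concentrates each channel's
mass to order 1/(H*W), and the variance of the resulting activations swings
widely between batches; running batch statistics then diverge from
per-batch statistics and evaluation-mode outputs saturate. Per-sample
normalisation has no train/eval gap, keeps inference exactly deterministic,
and trains stably here.

### Optimisation

Adam (lr 1e-3, batch 32, up to 30 epochs), binary cross-entropy on logits,
stratified validation split (20%), early stopping on validation F1 with
patience 5, best-validation-F1 weights kept. Windows are labelled positive
when they overlap a truth deletion by at least min(25 bp, truth length):
half a stride, which guarantees every true deletion labels at least one
window positive under the 100/50 geometry. Candidate regions of a
variant-free genome are empty by construction, so the training-set builder
adds background windows sampled away from truth deletions as clean
negatives. All initialisation, shuffling and dropout are seeded;
evaluation-mode inference is bit-deterministic.

The network runs on a small in-package reverse-mode autodiff core
(`dasv.nn`): float32, im2col convolutions backed by batched GEMMs, explicit
graph freeing. Everything trains in minutes on one CPU at the problem sizes
below.

## Synthetic data

The simulator generates a uniform-random ACGT reference, implants
non-overlapping deletions (>= 10 kb apart so a single read rarely spans two
events; >= 5 kb from contig edges) on an alternate haplotype, and draws
reads of Normal(20 kb, 2 kb) length (truncated to [1 kb, 40 kb]) uniformly
over the source haplotype — both haplotypes with probability 1/2 each for
heterozygous runs, alternate only for homozygous. Per-base errors at 15%
total are split 40/30/30 between substitutions, 1 bp insertions and 1 bp
deletions (a CLR-like mix; configurable). Read CIGARs are constructed
directly from the known truth coordinates: a read spanning an implanted
deletion carries a `D` op of the true length, modified only by adjacent
1 bp error operations. A small fraction of reads (2%) receives random
soft-clip decorations to exercise the blue image channel. The read count is
inflated by the expected contig-edge truncation loss (about
mean^2 / 2 span per read) so realised coverage stays on target. Output is
SAM with an @HD/@SQ header, FASTA (+ .fai), truth BED and a JSON manifest;
identical configs (including seed) give byte-identical files.

What this emulation deliberately omits: mapping ambiguity and mismapped
reads, chimeric/supplementary alignments, reference-allele soft-clip
breakpoints, strand and base-quality structure, and non-uniform genome
composition. Passing end-to-end tests on this data therefore demonstrates
that the encoding, model and call assembly recover implanted signals under
realistic noise and coverage — not that the caller matches its measured
accuracy on real aligner output.

## Problem sizes and defaults

Default model channels are [16, 32, 64] per scale; the end-to-end test and
acceptance runs use [8, 16, 32] with up to 8 training epochs — the smallest
configuration that exercises every component and, on this near-separable
synthetic task, converges within the first few epochs. End-to-end runs use
500 kb references: training on 30 homozygous 50-1000 bp deletions at 45x
(plus background negatives), the low-coverage protocol on mixed 45x
homozygous + 20x heterozygous data with 50-5000 bp deletions (20 windows
per region, evenly subsampled, so very long events do not dominate the
training set), and held-out evaluation against 30 implanted events per
condition. Matching for evaluation uses the community-standard criterion:
same chromosome, both breakpoints within 500 bp, reciprocal overlap >= 0.5,
one-to-one greedy assignment by descending overlap.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere internally; conversion
  happens only at the SAM (1-based POS) and VCF (POS = base before the
  event) boundaries.
* Consensus ties break to the lowest base code; deletion wins at exactly
  half the covering reads.
* A window with no overlapping reads encodes as an all-white image and an
  all-zero track; a variant-free input produces an empty (but valid) call
  set and VCF.
* Precision is defined as 0 (with a warning) when there are no calls.
* `N` bases vote for no code; hard clips and `N` CIGAR ops draw nothing.
* Deletions anchored at the first reference base cannot be represented in
  the VCF convention and raise an error (the simulator keeps events away
  from contig edges).

## Known limitations

* The caller detects deletions only; genotyping, insertions and other SV
  classes are out of scope.
* Split-read/supplementary-alignment evidence is not used, so deletions
  expressed only as clipped alignments (rather than intra-read `D` ops)
  are invisible.
* The consensus form of `S` discards per-read haplotype structure; a
  per-read sequence matrix is a plausible alternative encoding that was
  not pursued.
* Very high coverage (> 100 reads per window) is subsampled, not blended;
  extreme depth variation within one window is only partially represented.
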