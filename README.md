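# dasv — deletion calling in long reads with dual attention

`dasv` is a deletion structural-variant caller for third-generation
(long-read) sequencing alignments. Deletions of 50 bp and more are a major
class of disease-relevant genomic variation; noisy long reads (~20 kb,
~15% base error) can span whole events but bury them in indel noise.
`dasv` frames candidate regions from CIGAR deletion evidence, renders each
100 bp window of a candidate region into three aligned encodings, and
classifies windows with a dual-attention network before assembling calls:

* **S** — a length-100 integer consensus track (A=2, C=3, T=4, G=5,
  deletion=9, pad/uncovered=0);
* **I1** — a 100x100 RGB pileup image (one read per row: match green,
  deletion red, soft clip blue, insertion black, background white);
* **I2** — a binary attention mask, white exactly where I1 is red.

The model fuses the modalities with two attention mechanisms over a
residual multi-scale backbone: **spatial attention**, where features of I1
and I2 are multiplied and softmax-normalised over positions within each
channel (A<sub>c</sub> with Σ<sub>x</sub> A<sub>c,x</sub> = 1) to reweight
the image features toward deletion evidence, and **channel attention**,
where w = σ(W<sub>a</sub>·GAP(F) + W<sub>m</sub>·GMP(F)) ∈ (0,1)<sup>C</sup>
gates the sequence channels at every scale. Positive windows
(p ≥ 0.5) are grouped by their evidence cluster; breakpoints come from the
median per-read evidence, and calls are emitted as VCF 4.2 `<DEL>` records.
Precision, recall and F1 = 2PR/(P+R) are computed by one-to-one matching
(breakpoints within 500 bp, reciprocal overlap ≥ 0.5).

A truth-aware simulator (reference + implanted deletions + noisy reads with
CIGARs derived from the known truth) makes the whole pipeline trainable and
testable on one CPU with no external data or aligner. See
`docs/methods.md` for the full model and simulation description.

## Worked example

Simulate a 200 kb genome with eight homozygous deletions at 30x, train,
call on the same data, and evaluate against the implanted truth:

```bash
cat > sim.yaml <<EOF
ref_length: 200000
n_deletions: 8
size_ranges: [[50, 1000]]
zygosity: homozygous
depth: 30
EOF

dasv simulate --config sim.yaml --out simdata --seed 7
# simulated 316 reads, 8 deletions -> simdata

dasv train --bam simdata/reads.sam --truth simdata/truth.bed \
           --out model.ckpt --epochs 4 --seed 7
# records after QC: 316
# windows: 300 (86 positive / 214 negative)
# epoch 1: loss 0.4628, val F1 0.692
# ...
# epoch 4: loss 0.1142, val F1 0.786

dasv call --bam simdata/reads.sam --ckpt model.ckpt \
          --reference simdata/reference.fa --vcf calls.vcf
# 7 deletion calls -> calls.vcf

dasv evaluate --calls calls.vcf --truth simdata/truth.bed
# metric      value
# tp          7
# fp          0
# fn          1
# precision   1.0000
# recall      0.8750
# f1          0.9333
```

Reading the output: 316 of 316 reads survive quality control (the
simulator emits MAPQ 60 primary alignments); the eight implanted deletions
produce eight high-frequency candidate regions, tiled into 300 labelled
windows. After only four epochs the classifier recovers seven of the eight
implanted deletions with no false calls (precision 1.0, recall 0.875,
F1 = 2PR/(P+R) = 0.9333). The VCF records carry `SVTYPE=DEL`, `END`,
negative `SVLEN` and the supporting read count.

## Library use

```python
from dasv import (SimConfig, simulate, qc_filter, build_training_dataset,
                  train, call_from_records, match_calls)

res = simulate(SimConfig(ref_length=200_000, n_deletions=8, depth=30, seed=7))
records = list(qc_filter(res.records))
dataset = build_training_dataset(records, 200_000, res.truth, seed=7)
model, metrics = train(dataset)
calls = call_from_records(records, 200_000, model)
print(match_calls(calls, res.truth).as_dict())
```
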