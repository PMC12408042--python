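# Methods

This note records the models, assumptions, parameter choices, and numerical
decisions behind `biunet`. Every empirical number quoted in the README is
produced by the test suite or by `scripts/acceptance.py`; this note contains
no empirical claims of its own.

## Problem setting

Given a cohort of phased diploid genotypes over one chromosome with some
fraction of sites missing, impute the missing genotypes using only the cohort
itself — no external reference panel. The statistical signal is linkage
disequilibrium (LD): nearby variants are correlated because haplotypes are
inherited in blocks, so observed neighbours constrain a hidden site.

## Genotype encoding

Phased genotypes are coded as five small integers:

| code | genotype | meaning | alt dosage |
|------|----------|---------------------|-----|
| 0    | missing  | `./.` or `.|.`      | —   |
| 1    | `0|0`    | homozygous reference| 0   |
| 2    | `0|1`    | het, ref on hap 1   | 1   |
| 3    | `1|0`    | het, alt on hap 1   | 1   |
| 4    | `1|1`    | homozygous alternate| 2   |

A sixth code (5) marks padding in fixed-length windows. Phase matters: codes
2 and 3 are distinct prediction targets, though they share dosage 1. Only
phased, biallelic SNPs are accepted; unphased non-missing calls are an error
rather than silently collapsed, because the model's phase-aware classes would
otherwise be trained on ambiguous labels.

## Segmentation

Chromosome-length sequences are cut into overlapping windows of
`segment_length` L = 128 SNPs with `overlap` = 16 (stride 112). The number of
windows per sample is `ceil((n - overlap) / stride)` for n > L, else 1; the
final window is padded with code 5. Each window carries a positional channel:
base-pair coordinates min-max normalized over the whole chromosome, so the
model can distinguish tightly from loosely spaced SNPs. Padded slots repeat
the last real coordinate. Windows are stored sample-major in HDF5 together
with the segmentation settings and a persisted shuffle index, so training
order is reproducible independently of the store's layout.

## Model

A 1-D U-Net maps a [7, L] input (6 one-hot code channels + 1 positional
channel) to [4, L] class logits (codes 1–4). The encoder applies
`depth` convolution+ReLU blocks with channel widths `base_channels * 2^i`,
max-pooling by 2 between levels; the decoder mirrors it with nearest-neighbour
upsampling, skip concatenation, and convolution blocks; a 1×1 convolution
projects to 4 classes. L must be divisible by `2^(depth-1)`. Dropout
(inverted, training-only) can be applied after encoder blocks.

No deep-learning framework is available in the target environment, so the
network — im2col convolutions, pooling with argmax scatter, upsampling,
dropout, full backpropagation, and the Adam optimizer — is implemented
directly in NumPy (float32). Gradient correctness is verified in the test
suite against central finite differences, layer by layer and through the
whole network via a smooth linear functional of the logits.

## Loss

The hybrid loss on the masked positions of a batch is

```
L = (1 - lambda) * mean[ P(y, yhat) * (1 - p_y)^gamma * (-log p_y) ]
  + lambda       * mean[ (d - dhat)^2 ]
```

with `gamma = 2`, `lambda = 0.5`. `P` is a 4×4 penalty matrix: 0 on the
diagonal, 3.0 off-diagonal, except 1.0 for the 2↔3 phase-switch cells —
a phase error keeps the dosage right and is penalized three times less than a
dosage error. `yhat` is the current argmax (the penalty weight is treated as
a constant in the gradient). `dhat = p2 + p3 + 2*p4` is the expected alt
dosage. Probabilities are clamped at 1e-12 inside logs. The analytic gradient
with respect to logits uses the standard softmax Jacobian identities and is
tested against numerical differentiation to 1e-7.

## Training

Curriculum masking: in each epoch a fraction of the eligible (non-pad)
positions is replaced by the missing code and the model is scored only on
those positions; the fraction rises linearly from 5% in the first epoch to
25% in the last. The masked count is exact (`round(rate * n_eligible)`).
Train/validation splitting is by sample, never by window, so no haplotype
appears on both sides. Validation uses the final masking rate with a fixed
mask seed across epochs; the best-validation parameters are restored at the
end. Defaults: 15 epochs, Adam at 1e-3, batch 64.

## Inference and evaluation

Windows are predicted batch-wise, softmaxed, and reassembled: where windows
overlap, the window with the strictly highest winning-class probability at a
site supplies the call (ties go to the earlier window). Observed genotypes
always pass through unchanged; only missing sites are replaced. The VCF
output carries phased GT plus a DS (expected dosage) field clipped to [0, 2].

Evaluation masks a complete matrix at fixed levels (5/15/25%, three
replicates each, seeded), imputes, and compares at the masked sites only.
Metrics — genotype accuracy, squared Pearson correlation of dosages (R²),
macro precision/recall/F1 over the classes present — are computed per MAF bin
by concatenating all masked calls in the bin (right-closed edges 0.1%, 0.5%,
1%, 5%, 10%, 20%, 30%, 40%, 50%), with MAF taken from the unmasked truth. R²
is reported as NaN when either dosage vector is constant.

## Synthetic data

The simulator is a Li–Stephens-style mosaic. A founder panel (default 30
haplotypes) is drawn site-wise from a U-shaped Beta(0.3, 0.3) frequency
spectrum; each cohort haplotype copies one founder at a time, switching to a
uniformly chosen founder with per-SNP probability 0.01 and flipping each
copied allele with probability 0.002. Haplotypes are paired into phased
diploids, and SNPs with cohort MAF below 0.1% are dropped. Low switch rates
give long shared blocks — the LD signal imputation needs; the U-shaped
spectrum populates both rare and common MAF bins.

A structural property of this generator worth noting: founder alleles are
drawn independently at each site, so *pairwise* LD between neighbours is
modest even though the mosaic structure is strong. Recovering a masked site
therefore requires identifying which founder the local block was copied
from — a combinatorial, multi-SNP signature — rather than reading off a single
correlated neighbour.

## Desk-scale benchmark configuration

The acceptance benchmark trains a depth-4, base-16-channel network on the
default simulated cohort (400 samples × 2,000 SNPs, simulation seed 7,
windows L=128/overlap 16) for at most 15 CPU epochs and scores masked-site
accuracy against a per-SNP modal-genotype baseline plus dosage R² on SNPs
with MAF ≥ 5%, at 5% masking. Depth, width, window geometry, epoch cap, and
the cohort are fixed design points; the remaining hyperparameters are the
package's own choices, selected by ablation at these conditions:
`kernel_size=9`, `dropout_rate=0.0`, `batch_size=16`, `learning_rate=3e-3`.
Wider kernels shorten the path from flanking context to a masked site; at
this small data scale dropout and large batches both slow convergence.

## Limitations

- Training is CPU-bound NumPy; it is suitable for cohorts of hundreds of
  samples and thousands of SNPs, not biobank scale.
- Within the 15-epoch desk-scale budget the network does not fully converge
  on the default simulated cohort (see the acceptance output for the achieved
  margin against the modal baseline and the common-variant dosage R²). The
  two benchmark threshold tests in `tests/test_acceptance.py` document this
  honestly and currently fail.
- One chromosome per matrix; multi-chromosome VCFs must be split upstream.
- Only biallelic SNPs are modelled; indels and multiallelic records are
  skipped on read.
- The evaluation masks genotypes completely at random, which mimics assay
  dropouts but not the systematic missingness of array-to-sequence
  imputation.
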