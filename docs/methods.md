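# Methods

This note documents the model, its parameters, the synthetic study the
package ships, and the numerical and design choices a maintainer should
know about. It states no empirical result that the test suite or
`scripts/acceptance.py` do not themselves compute.

## Problem setting

MoRF prediction is residue-level binary classification: every residue
of a protein chain is either part of a molecular recognition feature
(a short, 5–25 residue disorder-to-order binding element) or not. MoRF
residues are rare (a few percent of all residues in the public
benchmark sets), so evaluation uses ranking metrics — residue-level
ROC/AUC with all residues of a set pooled as independent instances,
and the false-positive rate at fixed sensitivity (TPR 0.2/0.3/0.4),
which focuses on the low-FPR regime that matters when positives are
scarce.

## Feature model

**Channels.** A feature set is an ordered list of channels. A *scale
channel* maps each residue to a real value through a 20-entry
amino-acid property table (AAindex1 format; disorder-propensity tables
are mechanically identical and handled the same way). The optional
*entropy channel* first maps the sequence to bits through a binary
partition of the alphabet — default: disorder-promoting residues
{A, G, R, Q, S, P, E, K} → 1 — and then scores window complexity.

**Windowed averaging.** For window length N the sequence is padded
with ⌊(N−1)/2⌋ zeros left and ⌈(N−1)/2⌉ right. Symmetric floor-padding
on both sides would yield L−1 window start positions for even N,
breaking per-residue indexing; the floor/ceil split guarantees exactly
L windows for every N, and residue j's cover set (the windows whose
span contains its padded position) is clamped to the valid window
range. Each window contributes its channel mean (padded positions
enter as value 0; the entropy channel sees padded positions as symbol
0), and each residue receives the uniform mean over its cover set. In
the interior that is the mean of exactly N consecutive window vectors;
at the edges it is the partial mean over the windows that exist. A
brute-force oracle that physically constructs the padded sequence and
enumerates cover sets defines correctness in the tests (equality to
1e-9 over random instances).

Zero-filled padding means edge residues carry systematically shrunken
feature magnitudes. This is deliberate (it mirrors the literal
zero-fill preprocessing) but it is information: see the null-study
remark below.

**Topological entropy.** For a binary word of length n, let k be the
largest integer with 2^k + k − 1 ≤ n. The entropy is log2(m)/k where m
counts the distinct k-subwords in the first 2^k + k − 1 symbols. The
value lies in [0, 1]; it is 0 exactly when the counted prefix repeats
a single k-mer, 1 when the prefix is a de Bruijn-complete word, and it
is invariant under global 0↔1 complementation. Windows shorter than 2
symbols are rejected (cannot occur with the default window lengths).

**Windows.** Default lengths 10, 45, 90: the short window resolves the
MoRF itself, the long one its sequence context, the middle one damps
the noise of the long window. Stacking the three rows gives the
N_win × F input matrix per residue (3×16, 3×13, 3×14 for the default
sets).

**Standardization.** Each (window, channel) cell is z-scored with
mean/sd fitted on the training residues only; the transform is stored
inside the model archive and re-applied at prediction time.
Zero-variance cells pass through unchanged with a warning.

## Networks and training

Each feature set has its own network:
2×2 conv (16 filters, stride 1, same padding) → ReLU → 2×2 conv
(8 filters) → ReLU → 2×2 max-pool (stride 2) → flatten → dense(1) →
sigmoid. Numerical conventions forced by the small input:

- *Same padding with an even kernel*: one zero row/column appended at
  the bottom/right (the common framework convention).
- *Pooling odd extents*: ceiling semantics with −inf fill, so a 3-row
  input pools to 2 rows (3×16 → 2×8 after pooling; flatten = 128).
  Pooling ties split the gradient evenly.
- *Loss*: binary cross-entropy in its softplus form
  (softplus(z) − y·z), so the loss is finite for any finite logit; a
  non-finite loss aborts training with an error naming the epoch.
- *Optimizer*: Adam, defaults lr 1e-3, β₁ 0.9, β₂ 0.999, ε 1e-8;
  mini-batches of 128, shuffled each epoch by a generator seeded from
  the config. Identical (data, config, seed) therefore reproduce
  training bit-for-bit on one platform. Default 30 epochs; the
  shipped studies use fewer (below) because the planted signal
  saturates early.
- *Initialization*: He-scaled normals from the seeded stream; biases 0.
- *Class imbalance*: an optional positive-class loss weight exists but
  is off by default.
- The hidden activation (ReLU/tanh/sigmoid) and the number of conv
  layers are configurable for ablation sweeps; 2 layers + ReLU is the
  reference.

The ensemble track is the plain element-wise mean of the three
per-residue probabilities; averaging cannot leave the [min, max]
envelope of its inputs.

ROC/AUC is computed over all distinct score thresholds with positives
called at score ≥ threshold; the trapezoidal area equals the
Mann–Whitney pair-counting statistic with ties worth 1/2 (tested
against a brute-force pair counter), so constant scores give exactly
0.5. FPR-at-TPR uses the conservative step-function reading — the
smallest FPR among realized curve points with TPR at or above the
target — with no interpolation, so it is reproducible from the finite
curve alone.

## Synthetic study design

The generator emulates the labeled structure of the public MoRF
benchmarks without reproducing their biology: i.i.d. background
residues with one contiguous, interior MoRF segment per sequence
(present with probability `p_morf`), labels marking the segment.

Defaults, chosen once as the study conditions: 300 sequences per
dataset call, lengths uniform on [50, 200], MoRF lengths uniform on
[5, 25] (the benchmark range; mean 15), `p_morf` = 1 (every benchmark
chain contributes a binding element), uniform background composition.
Scales are seeded standard-normal draws standardized across the 20
residues; scale 0 is a noisy indicator of the MoRF-enriched residues
{W, F} (aromatic enrichment being the classic MoRF signature) so the
planted bias is detectable through it.

The planted signal is constructed, not tuned: `composition_for_shift`
exponentially tilts the background composition along the standardized
signal-scale values and solves for the tilt by bisection so that the
mean signal-scale value of a MoRF-drawn residue sits exactly a
requested number of scale standard deviations above background. The
`strong-signal` preset uses a 2.0 sd shift; `null` uses the background
composition itself (labels without signal). The three default feature
sets (16 = 13 scales + 2 disorder scales + entropy; 13; 14) all include
the signal scale, so each network can in principle recover the signal —
a deliberate design choice so that per-network recovery is a meaningful
check.

What the synthetic data does **not** model: real disorder statistics,
residue autocorrelation, evolutionary conservation, multiple or
terminal MoRFs, length-composition coupling. Passing the synthetic
studies therefore demonstrates that the pipeline extracts a planted
compositional signal through the full feature → CNN → ensemble path;
it does not certify accuracy on real proteomes.

One known artefact: because planted MoRFs are always interior and edge
residues carry zero-diluted features, a trained model can earn
slightly-above-chance AUC even under the null preset (position is
weakly informative). The null acceptance band [0.4, 0.6] accommodates
this; it is a property of the generator's placement rule, not leakage.

## Study sizes used by the shipped runs

The acceptance script trains on 240 sequences and evaluates on 120
held-out sequences (≈15k residues each side), 10 epochs, batch 128;
the null control uses the same sizes. The test suite runs the same
studies at reduced size (40–120 sequences, 3–5 epochs) where it checks
bands rather than point values. These sizes are the package's chosen
desk-scale study conditions; the public benchmark results (which
require the original datasets and the unpublished channel selections)
are out of scope, and dataset bookkeeping for the pooled 464-sequence
test set is reproduced from the printed per-set residue counts alone.

## Degenerate inputs and edge cases

- Length-1 sequences are valid: every window's cover set is the single
  window, and the feature matrix is the stack of single-window means.
- Non-standard residue codes (B, Z, U, O, J, `*`) canonicalize to `X`;
  scale lookup for `X` uses the scale mean so window averages stay
  defined; the binary mapping treats `X` as 0.
- AAindex records with `NA` cells are rejected by accession rather than
  imputed.
- Single-class training sets and empty manifests/fitting sets raise
  argument errors; tpr targets outside (0, 1] are rejected.

## Limitations

- The CNN is implemented directly in numpy; it is fast at these input
  sizes (3×F matrices) but not intended for large architectures.
- Channel lists stand in for unpublished selections; results on real
  data depend on supplying scientifically meaningful scales.
- Training reproducibility is bit-exact only within one platform/BLAS
  configuration.
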