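# Methods

## The problem and the data model

A developmental-toxicity screen exposes ~32 replicate zebrafish embryos
per chemical and records, at 120 hours post-fertilization, 18 binary
endpoints (mortality plus morphological defects). Only the highest tested
concentration (64 µM) is modelled: each chemical is summarized by one
18-vector of incidence proportions p_e ∈ [0, 1], its *toxicity matrix*.
Missing replicate entries are excluded from both numerator and
denominator; an endpoint with no evaluable replicate is an error, never a
silent zero.

## Aggregate entropy and activity calls

The activity summary must be monotone in incidence — a chemical affecting
every embryo must not score below one affecting half — while staying on
an entropy (bits) scale. Plain Shannon entropy fails this (it peaks at
p = ½), so each pooled incidence q is scored with the folded form

    s(q) = H₂(q)       q ≤ ½
    s(q) = 2 − H₂(q)   q > ½

with H₂ the binary entropy in bits: s is continuous and non-decreasing,
s(0) = 0, s(½) = 1, s(1) = 2. AggE is the sum of s over endpoint groups
(default: 18 singletons, so AggE ∈ [0, 36]; coarser partitions pool
correlated endpoints by max before scoring, so grouped AggE never exceeds
the singleton value). The published activity threshold for these screen
conditions, AggE ≥ 9.35 (≥, not >), is the default and is configurable
because it is concentration-dependent. The exact aggregate used by the
original screen analysis is defined in prior work we could not consult in
detail; the folded-entropy form above is this package's explicit stand-in,
isolated in `toxdata.entropy_score` so an alternative can be swapped in
without touching callers.

## Views: the 3D vectorization

A molecule is a weighted set of views. Per center atom: all atoms are
listed as rows `[period, group, x, y, z]` in a canonical frame (center at
origin, designated nearest neighbour on +x, nearest non-collinear atom in
the y > 0 half-plane), sorted by distance, truncated/zero-padded to
`max_atoms_per_view` rows (period = group = 0 sentinel). Element identity
enters only through the IUPAC (period, group) position, which keeps the
input dimension fixed across chemistries.

Numerical choices:

- **Tie splitting** happens only at the nearest-neighbour (axis-defining)
  position: a k-way tie within `tie_tol` (default 10⁻³ Å) yields k views
  sharing the center's unit weight. This reproduces the canonical
  worked example — methyl isothiocyanate with all-atom centers gives
  exactly nine views (3 from the methyl carbon's tied hydrogens + 1 from
  each of the other six atoms). Residual ties beyond the nearest position
  are broken deterministically by (distance group, period, group, rounded
  coordinates) without further splitting, bounding view-count blow-up.
  Increasing `tie_tol` can only create more views, never fewer.
- **Weights** are the center's base weight 1 divided over its splits,
  then globally normalized to Σw = 1 per molecule, so the pooled feature
  s = Σ f(vᵢ)·wᵢ is scale-free across molecules of different atom counts.
- **Reflection** is quotiented out: when the reference choice is
  ambiguous (symmetric substituent pairs), every tied candidate frame is
  built in both mirror images and the lexicographically smallest rounded
  row matrix wins. Consequence: enantiomers vectorize identically — a
  known representational limit, accepted deliberately.
- **Degenerate inputs**: a single-atom molecule yields one center-only
  view of weight 1; fully collinear molecules get y = z = 0 for all rows.
- `carbon_only` center mode falls back to all atoms for carbon-free
  molecules.

Invariance to rigid motion (10⁻⁶ on rows) and to atom order in the input
file is property-tested over random molecules.

## Generators

**Go-ZT** (regression): feature net f (3 hidden layers) applied to each
flattened view, pooling s = Σ f(vᵢ)·wᵢ, toxicity net g (11 hidden layers)
emitting 18 values. Swish on hidden *and* output layers, batch
normalization between layers (statistics frozen at evaluation), Gaussian
weight init scaled by fan-in, no dropout; mini-batch SGD (batch 32) on
mean squared error for 75 epochs. Raw outputs are the regression targets;
clipping to [0, 1] happens only at the AggE interface.

**GAN-ZT** (conditional least-squares GAN): generator identical in shape
to Go-ZT (equal parameter count for equal configs). The discriminator is
a fully connected net on [s ∥ toxicity matrix] with a linear score;
targets 1 (real) / 0 (generated) under MSE. Alternating updates — one
Adam discriminator step, one SGD generator step per batch; the generator
gradient flows through both the generated matrix and the shared
conditioning vector s. The conditioning signal is s itself; a one-hot
chemical-identifier variant is config-gated (`onehot_condition`) for
comparison. Default 2000 epochs; divergence (loss > 10⁶ or non-finite)
aborts with a diagnostic.

Hyperparameters that matter, with defaults: layer widths 128 (hidden),
feature dimension D = 16, learning rate 0.2 (SGD, no momentum),
discriminator Adam rate 10⁻³, `max_atoms_per_view` = 16. The layer counts
and optimizer/loss/activation choices are the fixed architecture; widths,
D, learning rates and the per-view atom budget were set by hyperparameter
search with Cohen's κ as the objective — the same tuning procedure the
evaluation module exposes (`evalx.random_search`). Two of these deserve
comment: `max_atoms_per_view` = 16 lets views span whole molecules at the
synthetic problem's size (truncating at 10 rows hides molecular size and
remote substituents and costs roughly half the held-out κ), and the
narrow D = 16 bottleneck regularizes the pooled representation.

All training is plain-numpy with hand-written backprop (`zebratox._mlp`)
and is bit-deterministic given the config seed.

## The synthetic data generator

The generator emulates the *statistical shape* of the empirical screen,
not its chemistry: random acyclic heavy-atom skeletons (zigzag carbon
backbones, 4–9 carbons, with F/Cl/O/N/S substituents at idealized bond
lengths and exact tetrahedral angles), 18 endpoints × 32 replicates, and
~16% active prevalence mirroring the screen's class imbalance. F and Cl
never co-occur in one molecule so every generated structure stays inside
the domain-of-applicability filter.

The planted signal runs only through 3D-derivable descriptors — atom
count, heteroatom count, S presence, Cl presence, mean coordination — so
the views representation can in principle recover it: per endpoint,
p_e = logistic(α_e + α₀ + β·d(mol) + ε), with fixed per-endpoint offsets
α_e spread over ±1, per-chemical Gaussian noise ε (SD 0.6), and default
effect sizes β = (0.8, 0.6, 2.0, 1.5, 0.5). The global intercept α₀ is
calibrated by bisection on each chemical's critical intercept so that the
expected-incidence active rate equals the configured prevalence (0.16);
realized rates then fluctuate by binomial draw noise. Incidences are
Binomial(32, p_e) draws.

What passing tests on these data do **not** show: the generator has no
rings, stereochemistry, tautomers, conformational flexibility or
realistic pharmacophores, and its signal is low-dimensional by
construction. Signal recovery here demonstrates that the pipeline is
wired correctly end-to-end and can extract structure-borne signal through
the views bottleneck — not that it matches any empirical screen's
performance.

## Evaluation

SE, SP, PPV in percent; Cohen's κ from the standard chance-agreement
marginals; AUROC reported as balanced accuracy (SE + SP)/2 — the ROC area
of the single operating point that thresholded AggE calls admit. A
score-sweep ROC is deliberately not offered for the generators.
Undefined ratios (empty margins, single-class truth) are NaN, never 0.

Split validation is k = 10 repeats of a randomized 80:20
train/validation subsample (reported as mean ± SD per metric) rather than
disjoint 10-fold partitions, matching the 80:20 ratio of the modelled
protocol; splits are stratified by activity class by default (at 16%
prevalence an unstratified 20% draw leaves the validation active count
highly variable), with an unstratified switch. The label-shuffle null
permutes truth labels n = 1000 times against fixed predictions; its κ
centers on 0 and its balanced accuracy on ½.

The screening-prioritization arithmetic multiplies a registry size by the
screened active fraction (rounded to the nearest 10) and divides by a
model's PPV to size the list that must be tested to capture the expected
actives.

## Problem sizes used in the standard runs

The bundled studies (tests and `scripts/acceptance.py`) use 200 synthetic
chemicals with an 80:20 stratified split, 75 Go-ZT epochs, 200 GAN-ZT
epochs, 3 seeds for the signal-recovery means, and n = 1000 shuffle
permutations. At these sizes held-out κ for Go-ZT on the default planted
signal averages ≈ 0.48 (SD ≈ 0.15 across seeds) and the planted-null κ
averages ≈ 0.

## Known limitations

- Enantiomers are indistinguishable by construction.
- Bond order, charge and protonation state are not represented.
- The AggE form is a documented stand-in (see above); the 18 endpoint
  labels are configurable, not asserted.
- GAN-ZT is trained for stability, not tuned for accuracy; on the
  synthetic data its predictive κ is weak, consistent with adversarial
  training's small-data behaviour.
- Heavy-atom-only structures are accepted with a warning; models trained
  on H-explicit structures should not be applied to heavy-atom-only
  inputs.
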