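# Methods

## Model

The generative engine is an adversarial autoencoder over 166-bit MACCS
fingerprints conditioned on assay concentration. The encoder input is the
fingerprint concatenated with one LCONC neuron (167 inputs); two hidden
layers of 128 and 64 leaky-rectifier units feed a 5-neuron linear latent
layer. The first latent neuron is the growth-inhibition (GI) head; the
remaining four form the molecular representation that the adversarial game
pushes toward a 4-D standard normal. The decoder mirrors the encoder
(5 → 64 → 128 → 167) with logistic outputs on the 166 fingerprint
positions and a linear LCONC output. The discriminator is a 4 → 64 → 64 → 1
network with logistic output; it never sees the GI neuron.

Assumptions worth stating explicitly:

* **Bit independence at decode time.** The decoder emits independent
  per-bit Bernoulli probabilities; correlations between substructure keys
  are captured only through the latent code, and the screening likelihood
  treats bits as independent given the profile.
* **GI on the raw percent scale.** The GI latent neuron is regressed onto
  raw GI (no standardization), and LCONC enters and leaves the model on
  the raw log10-molar scale. This makes the generation-time concentration
  filter (LCONC < −5.0, i.e. below 10 µM) directly interpretable. Optional
  z-scoring was considered and rejected as the default for exactly that
  reason. A consequence the user must keep in mind: the GI value targeted
  at generation time (default N(5, 1), i.e. near-complete growth
  suppression on the percent scale) must be meaningful for the dataset the
  model was trained on.
* **Dose-invariant representation.** The manifold cost assumes a
  molecule's identity should not depend on the dose at which it was
  assayed; the representation is explicitly trained toward that
  invariance, and dose information is carried by the latent GI head and
  the decoder's LCONC output.

## Training procedure

Five plain-SGD updates per minibatch, in order: (a) discriminator
(prior = 1, encoded = 0), (b) encoder confusion, (c) joint
encoder–decoder reconstruction (summed bit logloss + squared LCONC
error, averaged over the minibatch), (d) encoder GI regression (MSE),
(e) encoder manifold cost (1 − mean pairwise cosine similarity among
`manifold_batch` = 8 encodings of each fingerprint at concentrations
drawn from Normal(dataset LCONC mean, dataset LCONC variance)). Each step
has its own learning rate and touches only its own parameter group; there
is no mixed weighted objective. Minibatches are shuffled per epoch from a
seeded generator, so a (data seed, model seed, training seed) triple
reproduces a run exactly.

Numerical choices:

* **Per-step gradient clipping** (global norm ≤ 5 per update). Plain SGD
  on the adversarial steps otherwise diverges within a few iterations
  once the discriminator saturates; clipping bounds the update without
  changing its direction.
* **Probability clamping** at ε = 1e−7 inside every log term (training
  logloss and screening likelihood share the same ε).
* **Learning-rate defaults** (discriminator 2.5e−3, confusion 1.2e−2,
  reconstruction 5e−3, GI 2e−3, manifold 5e−2) were chosen on the
  synthetic study conditions for stable convergence and an adversarial
  equilibrium in which a held-out discriminator stays near chance. The
  manifold rate is deliberately the largest: at initialization an encoder
  reacts only weakly to its single LCONC input, so same-fingerprint
  representations start almost parallel, and a weak manifold step would
  let the adversarial updates *reduce* that alignment during training.
* **Initialization**: fan-in-scaled Gaussian weights, zero biases, seeded.
* **Degenerate inputs**: a zero-norm representation in the manifold step
  contributes similarity 0 with a logged warning; non-finite losses abort
  training naming the offending step; batches of fewer than two rows are
  skipped (the adversarial and manifold terms need pairs).
* **Tie-breaking in screening**: equal log-likelihoods rank by library
  order, first seen first; selection is provably independent of chunk
  size (the streamed top-k keeps score, sequence position and id per
  candidate).

## Synthetic benchmark

The generator emulates a single-cell-line dose-response release at desk
scale. Fingerprints are drawn by picking one of 4 prototype 166-bit
patterns (density 0.3) uniformly and flipping each bit with probability
0.05 — mimicking a screen populated by a few structural families with
analog variation. LCONC ~ Normal(−6.0, 1.4²) on the log10-molar scale,
spanning the usual 10 nM–100 µM dose range. GI is linear: ten designated
bits carry coefficients of ±20 GI points, the dose slope is −15 GI points
per tenfold concentration increase, the baseline intercept of −50 puts
mean GI near +40 (a typical mid-dose growth level, so that strong
inhibition is reachable within the sampled dose range for a minority of
compounds), and Gaussian noise of SD 5 is added. The training runs used
throughout tests and the acceptance script use 500 training compounds,
100 held-out compounds from the same generator, 200 epochs, batch 64 —
sizes chosen so a full study trains in seconds on one CPU while leaving
clear headroom between learned reconstruction accuracy and the
majority-bit baseline.

What the generator does *not* emulate: real MACCS bit correlations
(actual keys are logically nested and strongly correlated), non-linear
dose-response shapes (real GI curves are sigmoidal with compound-specific
GI50s, not linear in LCONC), multiple assay replicates per compound, and
any relation between bit patterns and chemical synthesizability. Passing
tests therefore demonstrate that the architecture, losses, and protocol
work as specified and can recover planted structure — not that the model
generates chemically meaningful profiles from real screening data.

## Generation and screening protocol

640 latent codes are sampled with GI ~ N(5, 1) and representation
~ N(0, I₄); the decoder maps them to probability profiles with LCONC
values; profiles with decoded LCONC < −5.0 (strict inequality, boundary
excluded) are kept. The count of survivors is highly run-dependent — it
depends on where the decoder's potency region lands in latent space —
and typically ranges from zero to a few dozen out of 640 across seeds.
An empty survivor set is a valid outcome: the pipeline then emits empty
hit tables with a warning rather than failing. Surviving profiles are
screened in a single streamed pass over the library; top-10 per profile,
pooled and deduplicated with best score, best rank and multiplicity per
compound.

The GI target N(5, 1) is kept configurable because its scale is only
meaningful relative to the training data's GI convention; the default
targets strong growth suppression on the raw percent scale.

## Design choices that were genuinely open

* **Hidden activation**: leaky rectifiers (slope 0.1), configurable.
* **Discriminator architecture**: unconstrained by the latent-layer
  contract; two hidden layers of 64 chosen as the smallest net that
  reliably distinguishes structured representations from the prior early
  in training.
* **Label convention**: prior = 1, encoded = 0 (fixed, documented).
* **Prior**: standard normal with independent components for the 4-D
  representation.
* **Likelihood normalization**: the screening score is the plain
  log-likelihood sum over 166 bits; dividing by bit count would not
  change any ranking.
* **Backend**: the networks, backpropagation and the five-step loop are
  implemented directly in NumPy. At these sizes (≤ 167-wide layers,
  minibatch 64) a framework would add dependency weight without speed;
  exact gradients are verified against finite differences in the test
  suite.

## Known limitations

* Decoded probability profiles are not molecules; turning a profile into
  a structure requires a library to screen against, and the hit list is
  only as good as the library's coverage.
* The adversarial equilibrium is diagnosed by held-out discriminator
  accuracy at the final epoch; this fluctuates between runs, and
  individual seeds can land outside the near-chance band even when
  training is otherwise healthy.
* Training assumes the full training set fits in memory (the screening
  library does not have to).
* With raw-scale GI regression, datasets whose GI distribution differs
  wildly from the synthetic benchmark may need the GI learning rate
  adjusted; all five rates are exposed in `TrainConfig`.
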