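# Methods

## The model

`torsiongrid` treats backbone-angle prediction as fine-grained
multi-class classification.  Four angles describe a residue's local
backbone conformation: the Ramachandran dihedrals φ (about N–Cα) and ψ
(about Cα–C), and two Cα-trace angles — θ, the planar angle over three
consecutive Cα atoms, and τ, the dihedral over four consecutive Cα
atoms.  Each angle's range is divided into fixed-width bins (5° by
default: 72 bins for each dihedral on [−180°, 180°), 36 for θ on
[0°, 180°]), and a single feedforward network predicts all four
distributions simultaneously through a 252-node output layer split
into four independent softmax blocks.

Predicting distributions rather than point estimates is the point:
the per-bin probabilities feed two downstream consumers.

* **Disorder scoring.**  Residues in intrinsically disordered regions
  sample broad conformational ensembles, so a calibrated predictor
  spreads mass over many bins there.  The score is the normalized
  Shannon entropy H = (−Σᵢ pᵢ ln pᵢ)/ln K ∈ [0, 1], smoothed by a
  centered 21-residue moving average (disorder is segmental).
  Discrimination is measured by ranking AUC, which is invariant to the
  normalization (and log base) by construction.
* **Model quality assessment.**  A candidate structure is scored by
  the pseudo-energy PE = Σᵢ ln(Pᵢ/P⁰ᵢ), where Pᵢ is the predicted
  probability of the bin residue i actually occupies in the model and
  P⁰ᵢ is the background probability of that bin.  PE is zero when the
  prediction equals the background and grows when the model sits in
  bins the predictor deems likely beyond chance.  Evaluation against a
  known native uses Kabsch superposition, the per-residue S-score
  1/(1+(dᵢ/d₀)²) with d₀ = 3 Å, a GDT-style score (mean fraction of
  native residues within {1, 2, 4, 8} Å), and per-target Pearson
  correlation between PE and the GDT-style score.

## Network and training

Hidden layers use sigmoid activations; defaults are three layers of
150 units.  Weights are initialized by greedy layer-wise pretraining
with sparse autoencoders (squared reconstruction error, KL sparsity
penalty toward mean activation 0.05 with weight 0.1, L2 weight decay
1e−4, SGD at learning rate 0.05), then fine-tuned by mini-batch
backpropagation on the summed cross-entropy of the four softmax
blocks, with per-layer learning rates 1.0/0.5/0.2/0.05 for
hidden-1/2/3/output.  Residues with an undefined angle (termini, chain
breaks) contribute zero loss and gradient for that angle's block only.
Epoch counts (30 pretrain, 100 fine-tune) and batch size (64) are
defaults chosen in the classic autoencoder-era regime; all are
configurable.  Every source of randomness — initialization,
pretraining, the per-epoch shuffle, cross-validation splits — draws
from one seeded generator, so a fixed seed reproduces models bit for
bit.  Cross-validation partitions by chain, never by residue.

## Features

* **M1 (sequence only).**  Per residue: 7 physico-chemical amino-acid
  properties (steric parameter, polarizability, volume,
  hydrophobicity, isoelectric point, helix and sheet probability; the
  Meiler 2001 scale, shipped as a versioned table) plus 20 PSSM
  substitution scores, over a 13-residue window → 351 features.
* **M2 (sequence + predicted structure properties).**  Per residue:
  20 PSSM scores plus an 18-column structure-property table (3
  secondary-structure probabilities, RSA, sin/cos of φ/ψ/θ/τ, Cα and
  Cβ contact numbers, four half-sphere exposures), over a 7-residue
  window → 266 features.  The table may come from any external
  structure-property predictor's output or from this package's
  generators; no external tool is ever invoked.

PSSM log-odds scores are squashed by the logistic 1/(1+e⁻ˣ) so all
inputs lie in [0, 1] (raw and z-score modes available).  Windows are
zero-padded past the termini; undefined angles encode sin/cos as
(0, 0), a point off the unit circle that flags missingness.

## Numerical conventions

* Dihedrals follow the IUPAC sign convention on the half-open
  interval [−180°, 180°); exactly +180° wraps to −180° so every angle
  maps to exactly one bin.  Bins are half-open with the final θ bin
  closed at 180°.
* Argmax and top-k ties resolve to the lowest bin index (stable sort).
* Chain breaks (residue-number gap or Cα–Cα distance > 4.5 Å)
  invalidate every angle whose atom quadruple spans the break.
  Degenerate geometry (collinear points) yields an undefined-angle
  NaN, never an exception.
* τ sits between two residues; by default the dihedral over
  Cα_{i−1}..Cα_{i+2} is assigned to residue i (`tau_anchor=1` shifts
  it to i+1).
* The background P⁰ is estimated as Laplace-smoothed bin frequencies
  (pseudocount 1) over a user-supplied corpus of angle tables, so
  every bin is strictly positive.  Predicted probabilities below 1e−8
  are floored under the PE log, with a logged count.
* The two-state φ split treats [0°, 150°] as state A (closed bounds);
  ψ uses [−100°, 60°].

## Synthetic study conditions

The synthetic module generates every input the pipeline needs, so the
package builds and tests without downloads.

* **Fragments** are built from ideal covalent geometry (N–Cα 1.458 Å,
  Cα–C 1.525 Å, C–N 1.329 Å, standard bond angles, ω = 180°) with
  (φ, ψ) = (−57°, −47°) for helix, (−120°, 120°) for strand, and
  seeded random coil.  Recomputing angles from the built coordinates
  recovers the generating values to well within 0.5°, which validates
  the geometry engine by round trip.
* **The training surface** maps each of 8 residue classes
  deterministically to one (φ, ψ, θ, τ) bin quadruple; features are a
  one-hot class indicator in the M1 layout plus Gaussian noise of
  scale 0.05.  Because the mapping is deterministic, a correctly
  implemented network must approach perfect held-out bin accuracy; the
  recovery check uses 2 000 training residues and reaches 1.0 with a
  2×100-unit network in seconds (the full default architecture is not
  needed for this separable task).
* **Disorder profiles** draw ordered rows from a symmetric Dirichlet
  whose concentration interpolates with a separation parameter s from
  the disordered value (α = 20, near-uniform rows) at s = 0 down to
  α = 0.1 (spiky, low-entropy rows) at s = 1, with labels in
  contiguous segments (mean length 30) so the 21-residue smoothing is
  meaningful.  At s = 0 the two classes are identically distributed
  and AUC is 0.5 by construction.
* **Decoys** add iid isotropic Gaussian noise (σ ∈ {0.5, 1, 2, 4, 8} Å)
  to every atom plus a random rigid motion, so superposition is
  genuinely exercised.

What these conditions do *not* emulate: real decoys deform smoothly
rather than atom-by-atom, real profiles come from homology-informed
predictors, and real disorder annotations are noisy.  Passing tests
therefore demonstrate correctness of the machinery and the directional
claims (entropy discriminates broad from peaked distributions;
PE tracks structural quality), not field performance on experimental
data.

A consequence of the iid decoy noise is worth recording: φ and ψ are
so sensitive to independent atomic displacement that they are
effectively randomized already at σ = 0.5 Å (mean |Δφ| ≈ 55°), at
which point their PE carries no quality signal and the residual
−ln P⁰ trend rewards outlandish conformations — the classic
inverse-Boltzmann pathology.  The Cα-trace angles degrade gracefully
(|Δθ| ≈ 11° at σ = 0.5 Å), so the end-to-end ranking experiment scores
PE on θ; this mirrors the empirical finding that Cα-based angles are
the strongest single-angle quality signals.  The idealized profile
used in that experiment spreads mass as a wrapped Gaussian (σ = 20°)
around each true angle: a confident-but-not-needle-sharp predictor,
which is both more realistic and necessary for ranking to work at all.

## Known limitations

* No mmCIF input; first NMR model only; first altloc only.
* The PE reference state is only as good as the supplied corpus; a
  tiny or unrepresentative corpus makes PE rankings unreliable.
* The GDT-style score uses the fixed sequence correspondence and a
  single global superposition, not the cutoff-specific superposition
  search of the official GDT_TS.
* Real-data accuracies and AUCs require experimentally derived
  training corpora and profiles, which are outside the package's
  scope; the synthetic benchmarks are qualitative stand-ins.
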