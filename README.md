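# torsiongrid

Grid-based prediction of protein backbone torsion-angle probabilities,
with two downstream applications: entropy-based scoring of
intrinsically disordered regions and pseudo-energy ranking of candidate
model structures.

## The problem

A residue's backbone conformation is captured by four angles: the
Ramachandran dihedrals φ (about N–Cα) and ψ (about Cα–C), and the
Cα-trace angles θ (planar angle over Cα_{i−1}, Cα_i, Cα_{i+1}) and τ
(dihedral over four consecutive Cα atoms).  Most predictors output a
single real value per angle, which says nothing about confidence or
conformational ambiguity.  `torsiongrid` instead discretizes each angle
into fine 5° bins — 72 bins for each dihedral, 36 for θ, 252 output
nodes in total — and trains a feedforward network (sigmoid hidden
layers, stacked sparse-autoencoder pretraining, four independent
softmax output blocks) to predict all four per-residue bin
*distributions* simultaneously.

The distributions are useful in their own right:

* **Disorder.**  The normalized Shannon entropy
  H = (−Σᵢ pᵢ ln pᵢ)/ln K of a residue's bin distribution, averaged over
  a 21-residue window, separates disordered from structured regions:
  broad distributions mean the backbone has no single preferred
  conformation.
* **Model quality.**  A candidate structure is scored by the
  pseudo-energy PE = Σᵢ ln(Pᵢ/P⁰ᵢ), comparing the predicted probability
  at each residue's realized bin against a background expectation P⁰
  estimated from an angle corpus.  Higher PE means the model's angles
  are where the predictor expects them beyond chance; PE correlates
  positively with superposition-based quality (S-score
  1/(1+(d/d₀)²) with d₀ = 3 Å, and a GDT-style score).

Everything needed to build, train and evaluate — structures, sequence
profiles, structure-property tables, disorder labels, decoy sets — can
be generated synthetically from a seed, so the package runs end to end
with no external data or tools.

## Worked example

```python
from torsiongrid import *
from torsiongrid.network import NetworkConfig
from torsiongrid.synthetic import make_training_set

X, T, chains = make_training_set(n_chains=10, chain_len=50, seed=7)
cfg = NetworkConfig(hidden=[64, 64], finetune_lrs=[1.0, 0.5, 0.05],
                    pretrain_epochs=5, epochs=20, seed=7)
model = train(X, T, cfg)
pred = predict(model, X)
for k in ANGLE_KINDS:
    print(f"{k}: bin accuracy {bin_accuracy(pred, T, k):.3f}, "
          f"top-5 {topk_accuracy(pred, T, k):.3f}")
```

On this synthetic residue-class → angle-bin task the mapping is
deterministic, so a correct implementation recovers it:

```
phi: bin accuracy 1.000, top-5 1.000
psi: bin accuracy 1.000, top-5 1.000
theta: bin accuracy 1.000, top-5 1.000
tau: bin accuracy 1.000, top-5 1.000
```

Disorder scoring from a probability profile (here synthetic, with
known segment labels):

```python
from torsiongrid.disorder import score_disorder
from torsiongrid.synthetic import make_disorder_profiles

prof, labels = make_disorder_profiles(300, separation=1.0, seed=1)
res = score_disorder(prof, "tau", labels=labels)
print(f"tau-entropy AUC (window 21): {res['auc_smoothed']:.3f}")
# tau-entropy AUC (window 21): 0.992
```

Decoy ranking: PE-score against a noise ladder of decoys tracks the
GDT-style quality —

```
sigma=0.5: PE(theta)=   20.27  GDT-like=0.935
sigma=1.0: PE(theta)=   17.52  GDT-like=0.720
sigma=2.0: PE(theta)=    7.88  GDT-like=0.525
```

The same workflows are available from the shell via the `torsiongrid`
console script (`train`, `predict`, `disorder-scan`, `qa-rank`, and
`synth` to write a complete fixture set).

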