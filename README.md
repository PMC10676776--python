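# oriforge

Prediction and *de novo* design of DNA replication origins (ORIs) from
sequence alone.

Replication in human cells initiates at many origins whose experimental
mapping is incomplete, and whose lengths vary from hundreds to thousands of
base pairs — which breaks classifiers that require fixed-length input.
`oriforge` addresses this with three pieces:

1. **Phase-specific Z-curve encoding.** A sequence of any length is mapped
   to a fixed-dimension feature vector built from the three Z-curve
   composition axes, computed for mono-, di- and trinucleotides, on the
   whole sequence and on its three phase subsequences (bases at positions
   ≡ 1, 2, 3 mod 3). For a context *c* of length *k*−1 and counts *f*:

       x_c = (f(cA)+f(cG)) − (f(cC)+f(cT))     purine vs pyrimidine
       y_c = (f(cA)+f(cC)) − (f(cG)+f(cT))     amino vs keto
       z_c = (f(cA)+f(cT)) − (f(cG)+f(cC))     weak vs strong H-bonding

   Activating mono / di / tri families spans Z-spaces of dimension
   12, 48, 192 alone and 60, 204, 240, 252 combined; counts are normalised
   per window so every component lies in [−1, 1] regardless of length.

2. **An attention-based classifier.** Three stacked structure blocks
   (single-head scaled dot-product self-attention → 1-D convolution with
   ELU → average pooling → nearest-neighbour up-sampling) followed by an
   MLP with a sigmoid head give P(origin | sequence). Training minimises
   binary cross-entropy with Adam (learning rate 2·10⁻⁴, batch size 64),
   early-stopped on validation loss. Implemented in NumPy with explicit
   forward/backward passes. Evaluation: ACC, Matthews correlation
   coefficient, and AUC under stratified 10-fold cross-validation.

3. **A genetic-algorithm designer.** The trained classifier is the fitness
   function; populations of 1000-bp homopolymers (all-A or all-G) evolve
   through point mutation, insertion, deletion and segment reversal under
   elitist truncation selection until every individual's origin
   probability clears a threshold and the elite has stopped improving.

A synthetic benchmark generator supplies labelled data with the composition
structure real origins show (positives GC 50–60% with planted GC-rich
motifs; genome-like negatives around GC 40%), so the whole pipeline is
testable without downloads. Sequence-set analytics (GC-decile histograms,
mean cosine similarity in Z-space, LLE/t-SNE projections) round out the
toolkit.

## Worked example

```python
import oriforge as of

seqs, labels, _ = of.make_labeled_dataset(
    of.FixtureSpec(n_pos=300, n_neg=300, length_range=(300, 1500), seed=1)
)
config = of.ZSpaceConfig(include_di=False, include_tri=False)  # 12-dim demo
X = of.encode_batch(seqs, config)
model = of.train(
    (X[:400], labels[:400]), (X[400:500], labels[400:500]),
    of.ClassifierConfig(input_dim=config.dim),
    of.TrainConfig(seed=0, max_epochs=15, patience=5),
)
print(of.evaluate(labels[500:], model.predict_proba(X[500:])))
```

Running this (`python examples/02_train_classifier.py`) prints

    held-out (41 origins vs 59 background):
      ACC=0.930  MCC=0.856  AUC=0.970

i.e. on the held-out hundred sequences the model ranks a random origin
above a random background sequence 97% of the time. The other scripts in
`examples/` walk through encoding (`01`), cross-validation (`03`),
GA design (`04` — watch mean GC rise from 0.00 toward the origin band as
fitness climbs) and set similarity (`05` — origins cohere with themselves,
are uncorrelated with random sequence, and point *away* from genome-like
background in Z-space).

A thin CLI wraps the same library:

```sh
oriforge simulate --seed 4 --out-pos pos.fa --out-neg neg.fa
oriforge train --pos pos.fa --neg neg.fa --seed 1 --out model.ckpt
oriforge cv --pos pos.fa --neg neg.fa --k 10 --seed 1 --report cv.json
oriforge generate --model model.ckpt --init-base A --seed 2 \
    --out designed.fa --trajectory traj.tsv
```

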