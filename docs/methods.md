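# Methods

## Z-space encoding

The Z-curve represents base composition on three orthogonal axes:
x = (A+G)−(C+T) separates purines from pyrimidines, y = (A+C)−(G+T)
separates amino from keto bases, and z = (A+T)−(G+C) separates weakly from
strongly hydrogen-bonded pairs. `oriforge` computes these as whole-sequence
summaries rather than cumulative per-position trajectories.

A sequence is additionally split into three phase subsequences S₁, S₂, S₃
(1-based positions i, i+3, i+6, …), the codon-like decomposition that makes
the features sensitive to 3-periodic structure. For k ∈ {1, 2, 3} the three
axis differences are computed per (k−1)-base context, phase-free on the
whole sequence and then within each Sᵢ, giving 12 / 48 / 192 parameters for
the mono / di / tri families and 12–252 dimensions for their combinations.
Two conventions required a decision and are frozen for reproducibility:

- **Phase-specific k-mers are counted within each Sᵢ** (pairs of bases
  three apart in the original sequence), the same construction as the
  mononucleotide case applied to the subsequence. The alternative —
  position-phased windows of the original sequence — is a different,
  equally fixed-dimension reading; the within-Sᵢ form was chosen because it
  is literally "the mononucleotide principle applied to Sᵢ".
- **Component order** is mono → di → tri; within a family, phase-free then
  phases 1–3; within a block, contexts lexicographic, axes x, y, z.

Raw count differences grow linearly with sequence length, which would
defeat the point of a length-invariant encoding, so counts are divided by
the number of counted windows per (subsequence, k) by default
(`normalize=True`); every component then lies in [−1, 1] with ±1 attained
by homopolymers. Raw counts remain available and are what the identities
x+y = 2(A−T), x−y = 2(G−C) are tested on.

Degenerate inputs: encoding requires every phase subsequence to admit one
window of the largest active k (so ≥ 9 bp for the trinucleotide family);
shorter sequences are rejected with the family named rather than
zero-padded, because an all-zero block is a valid composition signal
(balanced sequence) and must not be conflated with "too short". Symbols
outside A/C/G/T are rejected at construction — ambiguity codes have no
defined Z-coordinates — with an opt-in `drop` mode at FASTA ingestion.

## Classifier

The model maps a D-dimensional Z-vector (D ∈ {12, 48, 60, 192, 204, 240,
252}) to P(origin). The vector enters as a length-D token sequence with one
channel, preserving per-component locality so attention can weigh
relationships between specific Z-parameters. Three structure blocks follow
(`n_blocks=3`), each:

1. single-head scaled dot-product self-attention, d_k = d_v =
   `conv_channels` (no multi-head structure);
2. 1-D convolution, kernel 3, same-padding, `conv_channels=8` output
   channels, ELU activation (α = 1);
3. average pooling over tokens (`pool_size=2`) and nearest-neighbour
   up-sampling (`upsample_factor=2`), restoring the token count so blocks
   compose and the MLP input size is independent of block count. All
   admissible D are even, which the pool size requires.

The head flattens to D·8 features and applies an MLP (hidden sizes 64, 16,
ELU) ending in one sigmoid unit. Channel widths and MLP geometry are
config-exposed; the defaults are deliberately small for CPU training.

Training: mean binary cross-entropy, computed on logits via the softplus
form for stability (predictions are clamped to [10⁻⁷, 1−10⁻⁷] wherever the
probability-space loss is evaluated directly); Adam with learning rate
0.0002 and batch size 64; `max_epochs=200` with early stopping on
validation loss (patience 10) and restoration of the best-epoch weights.
Inside each cross-validation training fold a stratified 90/10 split
provides the validation set. All arithmetic is float32 with hand-written
backward passes; weight initialisation, batch shuffling and everything
downstream derive from integer seeds, so builds and training runs are
bit-reproducible. An ablation flag (`use_attention=False`) removes the
attention layers, mirroring the with/without-attention comparison.

Metrics: ACC and MCC threshold scores at 0.5 (the sigmoid-symmetric
default); MCC returns 0 when any confusion-matrix margin is empty. AUC is
the Mann–Whitney probability (ties counted ½), delegated to scikit-learn's
`roc_auc_score`; stratified folds come from `StratifiedKFold`. Brute-force
oracles for all three live in the test suite only.

## Genetic-algorithm designer

Populations start as `pop_size=100` homopolymers of 1000 bp (all-A or
all-G, i.e. GC 0 or 1). Four mutation modes fire independently per
offspring: point substitution (`point_rate=1.0`; each firing applies
`point_copies=5` independent single-base substitutions — single-base steps
would make the search time scale with the founders' distance from the
optimum, ≥ 500 generations from a homopolymer), single-base insertion and
deletion (`ins_rate=del_rate=0.1`, skipped with a log message at the
`length_bounds=[500, 2000]`), and structural variation (`sv_rate=0.05`)
realised as in-place reversal of a 50–200 bp segment — length- and
composition-preserving, so it explores arrangement rather than
composition. No crossover. Selection is truncation: the best half
(`survivor_fraction=0.5`, ties broken by population index) survives
unchanged — which subsumes elitism, making max fitness monotone — and
parents the refill.

Termination is two-part: the run stops when **every** individual's fitness
exceeds `fitness_threshold=0.5` **and** the elite's fitness has improved by
less than `stall_tol=1e-6` over the last `stall_generations=10`
generations (a founder population already above threshold returns
immediately; `max_generations=500` caps the run regardless). Stopping at
the bare threshold crossing would freeze the population at the edge of the
acceptable region — under a tent-shaped GC-target fitness peaking at 0.55,
for example, the population would halt with mean GC ≈ 0.43, the point
where the *worst* individual first clears 0.5 — whereas running to
convergence recovers the optimum (measured mean GC 0.550). Setting
`stall_generations=0` restores the bare-threshold rule for users who want
it.

**Known limitation — monotone fitness landscapes.** A classifier trained
on the bundled synthetic benchmark assigns probabilities that increase
monotonically with GC content (measured: 0.001 at GC 0.40, ≈ 0.71 at 0.50,
≈ 0.993 at 0.60, 1.0 at 1.0), because no training negative exceeds the
positives' band from above. Under such a landscape there is no interior
optimum for the GA to settle on: all-A populations overshoot the positives'
GC band (ending near GC 0.62 at the generation cap) and all-G founders are
already at maximal fitness and return unchanged. This is a property of the
synthetic conditions, not of the algorithm; with a fitness that peaks
inside the band (as real-data classifiers can), the designer recovers the
optimum, as the GC-target experiment shows.

## Synthetic benchmark

The generator emulates the composition signals that separate origins from
background: positives draw a per-sequence GC target uniform in
[0.50, 0.60], hit exactly by count construction, with `motif_copies=1`
copies of a GC-rich 9-mer (`GGGCGGGGC`, evocative of GC-box–like motifs; no
claim of biological fidelity) spliced in at random positions with the
background compensated so total GC stays on target. Negatives are either
uniform-random (GC concentrated near 0.50) or, by default, "genome-like":
per-sequence GC from a Beta distribution with mean 0.40 and concentration
80 (sd ≈ 0.054, so ≈ 2 sd spans the 0.30–0.50 band), bases i.i.d. given
that GC — simulated rather than sliced from a real genome to keep the
suite download-free. Lengths are uniform in [300, 3000] bp. Pseudo-cell-
lines are independent draws from one distribution, so classifying
sequences *by line* scores near chance while pooling lines helps — the
premise of a cross-cell-line model.

What passing tests therefore show: the encoder, model, harness and
designer work end-to-end on data whose class signal is composition plus a
planted motif. What they do not show: performance on real origins, which
carry positional, repeat and epigenetic structure the generator does not
emulate, and whose negatives are not this cleanly separated.

## Problem sizes

Unit tests run on 12-dimension encodings and a few hundred sequences with
reduced architectures (2 blocks, 4 channels). The acceptance checks use
the full 252-dimension space: 2000 training / 500 validation sequences and
6 training epochs for the classifier (the separable benchmark saturates
within ~3), 3 epochs for the permuted-label control, 2 for the ablation,
and the default 100-individual / 1000-bp GA configurations. The encoder
and metric oracles run on 200 and 100 random instances respectively.
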