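# Methods

## Model

Protein inference is cast as attribution in a regression model. The training
set has one example per observed peptide: the input is the peptide's binary
positional encoding across all candidate proteins (ones where the peptide
occurs, zeros elsewhere), the target is the peptide's identification
probability in [0, 1]. The network is a stack of per-protein
(1-D valid convolution → ReLU → non-overlapping max-pool) blocks with weights
shared across proteins, followed by a single linear output node over the
concatenated per-protein features. Two deliberate restrictions carry the
method:

* **Bias-free layers.** No convolution or output unit has an offset term.
  Together with ReLU(0) = 0 and max-pool of zeros = 0, an all-zero protein
  track produces exactly zero activations at every depth and exactly zero
  output contribution. This is what makes sparse computation exact (only
  matched proteins need to be touched) and what makes the fast scoring path
  below an identity rather than an approximation. The cost is modeling
  capacity — the network cannot express negative baselines — which is
  acceptable because inputs are nonnegative and predictions should rise
  monotonically as matching proteins are added.
* **No convolution window spans two proteins.** Convolutions run per protein
  block, so the penultimate representation is a concatenation of per-protein
  feature blocks and the output is an additive sum of per-block
  contributions.

Scoring masks one protein at a time: c_ij = |y_j − ŷ_j^(−i)| / n_ij, where
ŷ_j^(−i) is the prediction with protein i's ones reset to zero and n_ij is
the number of positions reset (the literal count of matched residues, which
equals a multiple of the peptide length except for self-overlapping
peptides, whose overlapping copies share positions). A protein's score is
the mean of c_ij over the peptides that match it (pairs with n_ij = 0 are
undefined under the division and are skipped; a flag switches to the
alternative convention c_ij = 0 for non-matching pairs). Ranking is by
descending score with ties broken by ascending protein id.

Because masking protein i zeroes its whole block, ŷ_j^(−i) equals the full
prediction minus the protein's cached block contribution. The shared path
computes one forward pass per peptide and reads every masked prediction off
the cache; the naive path re-runs a full forward pass per (protein, peptide)
pair. Both are implemented; their exact agreement (< 1e−6) is a standing
test, with the naive path as the oracle.

## Architecture parameters

| parameter | default | rationale |
|---|---|---|
| filters per layer | 5, 10, 15, 20 | increasing channel count lets deeper layers form more complex patterns |
| convolution window | 4 residues per layer | local positional context on the binary track |
| pool window / stride | 2 per layer | four halvings give a 16× length reduction, keeping the penultimate width tractable at proteome scale |
| dropout | 0.2 after each conv block | regularization during training only; disabled for every scoring pass |
| optimizer | RMSprop, lr 0.01, ρ = 0.9, ε = 1e−8 | see convergence notes below |
| epochs / batch | 30 / mini-batches of 32, seeded shuffling | bounded memory; full batch available via config |
| initialization | uniform ±1/√fan-in, seeded | standard scaled init; the input has one channel (the binary match track) |

With these windows the minimum input length that leaves one penultimate
position is 61 residues; shorter proteins are right-padded with zeros, which
bias-free layers map to zeros, so padding is inert. The pooling remainder
(a trailing window shorter than the pool width) is dropped. The "fully
connected + output" stage is a single linear map from the concatenated
per-protein features to the scalar prediction: a genuine cross-protein
hidden layer would break the exact per-protein decomposition that the shared
scoring path and the sparse computation rely on, so it is not offered.

Dropout semantics are an open design point: the implementation defaults to
activation dropout on each block's pooled output (inverted scaling at train
time), with config switches for mask-before-pool placement and for
DropConnect (per-example masks on the weights themselves). All three are
gradient-checked; none changes the qualitative behavior.

## Training dynamics and the RMSE plateau

Training minimizes the plain sum of squared errors; the per-epoch trace
records the RMSE of a dropout-free full pass. On the standard synthetic
fixture the fit reliably separates present from absent proteins (see below)
but the training RMSE plateaus in the 0.1–0.5 range rather than approaching
zero, and this is a property of the optimizer regime, not a gradient defect
(the backpropagation is verified against finite differences). RMSprop
divides each gradient by the root of its running second moment, so
per-parameter steps keep magnitude ≈ lr whenever gradient signs are even
weakly persistent; near the optimum this leaves a jitter floor on the order
of lr × (summed activation magnitude per example), and the 20 % dropout adds
per-example gradient noise that the magnitude-normalized steps chase rather
than average away. Lower floors require smaller learning rates or decayed
schedules, which the configuration exposes but the defaults deliberately do
not use. Protein ranking is robust to this plateau because scores depend on
*differences* between masked and unmasked predictions, which are dominated
by the well-fitted high-probability peptides.

Two degeneracies of the bias-free + ReLU design are worth knowing: a filter
whose weights become entirely non-positive on a nonnegative input is
permanently dead (no bias can revive it), and a peptide whose features reach
exactly zero becomes untrainable. Seeded ±uniform initialization keeps both
rare at the default scale.

## Synthetic data

The generator emulates what a search pipeline hands to an inference tool:

* a proteome of i.i.d.-residue sequences with roughly natural amino-acid
  frequencies (K+R ≈ 11 %, so tryptic peptides have realistic lengths),
  default 60 proteins of 200–400 residues;
* deterministic tryptic digestion — cleave after K/R unless followed by P;
* a hidden uniformly-drawn "present" subset (default 20), each of whose
  tryptic peptides of length ≥ 6 (a realistic detectability floor) is
  detected independently with probability 0.5; detection is resampled until
  every present protein contributes at least one peptide;
* identification probabilities for detected true peptides drawn from a Beta
  shape scaled into [0.9, 1.0], and 30 noise peptides drawn from absent
  proteins with probabilities scaled into [0.0, 0.3];
* degenerate peptides: 15 % of proteins are designated in pairs and one
  internal tryptic peptide of the donor replaces one of the recipient's,
  so the pair shares a peptide while both remain valid tryptic structures.

It does **not** model spectra (masses, charges, intensities), missed
cleavages, modification states, protein abundance, or realistic homology
structure beyond the copied segments. Passing recovery tests on this
generator therefore demonstrates the machinery end to end — encoding,
optimization, attribution, evaluation — under the method's own generative
assumptions, not performance on real search-engine output.

Decoy generation for target–decoy evaluation digests each target protein
and permutes residues within each tryptic peptide while holding every K, R
and P in place (K/R set cleavage sites and P suppresses them, so the decoy's
digestion pattern, length and composition match the target exactly); a
config flag switches to shuffling the order of whole peptides instead.

## Numerical and interface choices

* Coordinates are 0-based, half-open, throughout the public API.
* Peptide–protein matching is literal string equality; I and L are distinct,
  and modified-peptide strings are reduced to plain uppercase sequences
  (bracketed tags removed, lowercase residues uppercased) before matching.
* Duplicate peptide rows collapse to the maximum probability.
* Peptides matching no candidate protein are excluded from training with a
  warning: a bias-free network maps their all-zero input to 0 regardless of
  weights, so they contribute only an irreducible constant to the loss.
* The global seed fans out deterministically to proteome generation, profile
  simulation, weight initialization, epoch shuffling and per-example dropout
  masks, so runs are bit-reproducible (dense and sparse paths consume
  identical randomness by construction).
* Scores are reported raw (not normalized to [0, 1]); thresholding is the
  evaluator's concern, and the top-k call size k is a user input.
* ROC uses the midrank tie convention; PR uses step-wise interpolation
  (average precision). Degenerate-protein precision is reported as absent
  when no degenerate protein is predicted present.

## Limitations

* Protein grouping/parsimony, protein-level FDR and posterior probabilities
  are out of scope; the output is a ranked score list.
* The fixed-learning-rate optimizer regime caps the achievable training
  RMSE as described above.
* Candidate selection requires at least one exact peptide occurrence;
  enzyme-aware filtering and search-engine-specific decoy conventions are
  not implemented.
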