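# Methods

## Data model and assumptions

The unit of analysis is one call sequence: a non-empty ordered string over a
small call alphabet (default `{A, B}`), labeled with the stimulus class that
elicited it (default `{E, L, T}` for eagle, leopard, falling tree). Trials
that elicited no vocal response are not representable and must be excluded
before ingest; one trial may contribute several sequences, and each sequence
counts once. Sequence segmentation (e.g. a silence criterion separating
consecutive sequences in a recording) is assumed to have happened upstream:
the package never touches audio.

## Extended prefixes and the trie

Sequence end is an explicit symbol. The extended prefix of a sequence at
position *t* is its first *t* symbols, padded with the end symbol `∅` once
the sequence has ended; `∅` is **absorbing** (always followed by `∅`). This
convention matters: it makes the depth-*t* trie nodes a partition of the
full corpus at every position, so the positional indices are always averages
over all N sequences and remain comparable across positions — terminating
early is itself informative (ending after `BA` is the leopard signature in
the motivating system), and conservation is what makes H non-increasing and
J non-decreasing. The trie's default depth is the longest sequence length
plus one, so every sequence reaches its terminator node.

Transition probabilities between nodes are unweighted count fractions
(the descriptive quantity edge thickness encodes in trie figures); the
class-weighted analysis below never uses them.

## Weights and indices

Class sizes in elicitation corpora are unbalanced by design, so classes are
reweighted to equal prior mass: w_y = 1/(K·N_y), held as exact rationals,
with Σ_y w_y N_y = 1 checked exactly. At a node s with class counts c_y(s),
the weighted node mass is Pr(s) = Σ_y w_y c_y(s) and the conditional class
distribution p_y(s) = w_y c_y(s)/Pr(s). Per position:

* H(t) = Σ_s Pr(s) H(p(s)), Shannon entropy in base K (so H ∈ [0, 1] for any
  number of classes; K = 3 gives the base-3 convention of three-danger
  systems), with 0·log 0 = 0;
* D(t|t−1) = H(t−1) − H(t), the Kullback-Leibler information gain, with
  D(0|0) = 0; non-negative because depth-t nodes refine depth-(t−1) nodes,
  and telescoping to H(0) − H(t);
* J(t) = Σ_s Pr(s) max_y p_y(s), the expected accuracy of guessing the
  maximum-probability class. Ties in the argmax do not affect J; when a
  predicted label must be reported, ties resolve to the earliest class in
  the declared class alphabet.

Node-level arithmetic uses exact rationals (counts are integers, weights
rationals), entering floating point only inside the logarithm, so the
anchors H(0) = 1 and J(0) = 1/K hold to machine precision. D values whose
magnitude falls below 1e−12 are clamped to zero (pure float round-off);
internal distribution checks use an absolute tolerance of 1e−9.

## Permutation null

The null at position t — "the t-th call adds no information beyond the first
t−1" — is simulated by shuffling class labels uniformly among sequences that
share the same extended (t−1)-prefix. This is the unique randomization that
preserves every depth-(t−1) statistic exactly (the label multiset within
each step-(t−1) category is unchanged) while destroying any association
between the class and the position-t symbol. At t = 1 the only step-0
category is the root, i.e. a global label shuffle. For each position and
each index (D and J), the 2.5% and 97.5% empirical quantiles of the permuted
index form a 95% interval; an observed value strictly outside it flags the
position as significant. No multiple-testing correction is applied across
positions.

Conventions chosen where more than one was defensible:

* Empirical quantiles use the order statistic k = ceil(q·n_perm) (k-th
  smallest). Default n_perm = 10,000 per position and index, overridable;
  at least 100 is enforced at the command line for quantile stability.
* Only the position-t statistic is recomputed per permutation (equivalent,
  for the flag at t, to recomputing the whole profile, since positions
  ≤ t−1 are invariant and positions > t are not consulted).
* Shuffles are unconstrained by covariates; a covariate-stratified analysis
  is available by running the pipeline on `stratify_corpus` subsets.
* One master seed drives everything; the substream for (position, index) is
  derived via numpy's SeedSequence spawn keys, so every interval is
  individually reproducible bit for bit.

The implementation permutes integer label arrays and tallies per-node count
matrices with vectorized bincounts rather than rebuilding the trie per draw;
the test suite pins this fast path to an exhaustive enumeration over all
within-group label arrangements on a small corpus, and to the corpus-level
shuffle operation for the invariance guarantees.

## Synthetic corpora

The generator draws whole sequences i.i.d. from class-conditional
finite-support distributions with exact class sizes. A finite-support
mixture (rather than, say, a positional Markov process) was chosen because
the analysis only sees prefix statistics, and a finite support makes every
expected node distribution, entropy, and accuracy available in closed form
(`expected_conditional_distribution`), giving the tests exact oracles.

`colobus_preset()` emulates an olive colobus elicitation corpus: class sizes
N_E = 39, N_T = 79, N_L = 166 (284 sequences; its metadata records the
119 responsive trials across four dataset blocks), with supports encoding
the qualitative grammar — eagle sequences A-initial, leopard sequences built
on 'BA' units (terminating after 'BA' or continuing with further 'BA'
grams), falling-tree sequences carrying 'BAA'. The support probabilities are
invented and anchored only to those qualitative patterns; the preset is a
stand-in for field data, not an estimate of it. Two closed-form properties
of the preset worth knowing:

* the prediction-gain index gains nothing at position 2 (J(2) = J(1) = 0.6
  exactly), while positions 1 and 3 gain strongly — so large preset corpora
  show J significant at positions 1 and 3 only;
* the KL index has a small genuine gain at position 2
  (D(2|1) ≈ 0.065 in expectation, versus ≈ 0.264 at position 1 and ≈ 0.419
  at position 3), because within the A-branch the second call partially
  separates falling-tree from leopard mass; on large corpora this secondary
  gain is itself detectable. Position-2 flatness in *both* indices is a
  property of particular corpora, not of the preset.

`null_spec` pools the class-conditional distributions (class-size-weighted
mixture, idempotent), making labels independent of tokens with class sizes
unchanged — the generative counterpart of the permutation null.

What the generator does **not** emulate: acoustic variation within call
types, caller identity and group effects, covariate structure (its corpora
carry no covariates), dependence between sequences from one trial, and
realistic sequence-length tails (support is at most four calls). Passing
tests therefore demonstrate correctness of the estimators and calibration of
the null machinery under i.i.d. sampling, not robustness to field-data
idiosyncrasies.

## Calibration study

Coverage of the nominal 95% interval is measured by simulating 500 replicate
corpora from the null preset (labels independent of sequences, study class
sizes), building each replicate's interval for D(1|0) from 1,000 within-root
shuffles, and recording how often the observed value falls inside
(closed interval). These sizes give a Monte-Carlo standard error of about
1 percentage point on the coverage estimate; because the permuted index is
discrete, ties between the observed value and a quantile atom count as
inside, so measured coverage sits at or slightly above the nominal level.

## Visualization conventions

For three-class corpora, node colors map the weighted class distribution to
RGB with channel order (leopard, falling tree, eagle): each channel is
round(255·p^γ) with γ = ln 0.6 / ln(1/3) ≈ 0.46497 — the unique power law
through both convention anchors (pure class → pure channel at 255; uniform
1/3 → gray 153). Channels are monotone in their class probability. DOT
export draws the first call type as a circle, the second as a box, root and
`∅` as plain labels, collapses absorbing `∅` chains, scales edge pen width
linearly with transition probability, and labels each node with its maximum
conditional probability. The profile plot shows J(t) and D(t|t−1) against
position with the null intervals as red vertical segments.

## Limitations

* Plug-in entropy estimates carry the usual small-sample positive bias in D;
  no bias correction or smoothing is applied (the permutation null is
  subject to the same bias, which is why significance is judged against it
  rather than against zero).
* Weights require every declared class to be observed; strata produced by
  `stratify_corpus` that lose a class entirely are refused by the analysis.
* The color map is defined only for exactly three classes.
* With fewer than ~100 permutations the 2.5%/97.5% order statistics are the
  sample extremes; the CLI refuses such runs.
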