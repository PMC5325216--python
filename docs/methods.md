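# Methods

## Learning rule and its implementation

The core model is the Rescorla-Wagner delta rule over a two-layer network.
Parameters: cue salience α and outcome learning rate β (shared scalars,
default 0.1 each, so the effective learning rate αβ = 0.01), asymptote
λ = 1.0.  The defaults are the standard settings for lexical-learning
simulations; per-cue salience is left as a configuration extension point.
Three properties are treated as contracts and tested exactly:

* weights from cues absent from an event are bit-identical before and
  after the update;
* an outcome acquires weights only from the first event in which it
  occurs (before that, the network does not know the outcome exists);
* a lone cue-outcome pair trained *t* times follows the closed form
  `w(t) = λ(1 − (1 − αβ)^t)`, approaching λ monotonically from below.

`WeightMatrix` stores the weights as a dense, capacity-doubling ndarray
behind stable label indices.  Discrimination weight matrices are sparse in
the statistical sense (most weights hover near zero), but at the scales
this package targets — toy lexicons, synthetic corpora of 10³–10⁵ tokens,
2 500-cell grids — dense blocks with vectorized row updates are faster and
considerably simpler than sparse indexing; the persistence format
(`write_weights_tsv`) stores only the nonzero triplets, so files stay
small.  Scaling to billion-token corpora would require chunked or sparse
storage and is out of scope.

### Training order

The incremental trainer expands an event of count *f* into *f* identical
updates and, when a shuffle seed is given, reshuffles the whole expanded
stream each pass.  This "frequency-proportional interleaving" is a
modelling choice: pre-asymptotic weights depend on order, and interleaving
avoids the artefacts of blocked presentation (all repetitions of one word
in a row).  With a fixed seed the result is bit-reproducible.

### Equilibrium solve

For each outcome the end state solves `M v = b` with
`M[i, j] = P(c_j | c_i)` and `b[i] = P(o | c_i)`, probabilities estimated
from count-weighted co-occurrence over the event stream.  Because shared
n-grams make cue sets collinear (in the five-word toy lexicon the cue `ai`
occurs in every word), `M` is rank-deficient; we fix the solution policy
as minimum-norm least squares with a relative singular-value cutoff of
1e-10 (`numpy.linalg.lstsq`).  Per-cue weights are therefore
policy-dependent, but any per-word *sum* of weights over a consistent
system is not: on the toy lexicon the solution reproduces the worked
decomposition 0.73 + 0.18 + 0.09 = 1.00 for *qaid* exactly.  Cues with
zero total count are excluded with a warning.  The equilibrium depends
only on event counts, never on stream order (tested by permutation).

### Incremental ↔ equilibrium agreement

Shuffled incremental training fluctuates around the equilibrium rather
than converging to it deterministically; the size of the fluctuation
scales with αβ and with how rarely a cue is updated.  In the toy lexicon
the rarest word's unique cue is updated once per pass, so its
self-activation is the slowest quantity to settle: after 300
frequency-proportional passes (≈3.2 M updates) all five self-activations
sit within ~0.02 of the equilibrium values, comfortably inside the 0.05
agreement band the test asserts.  Two hundred passes leave the rare word
at the edge of that band for some shuffle seeds, which is why the test
uses 300.

## Event construction

Tokenization is deliberately minimal — whitespace split, lowercasing,
punctuation stripped at token edges — because the cue layer, not the
tokenizer, carries the representational burden.  Letter n-grams wrap the
form in `#` and replace internal spaces with `#`, so multi-word units
contribute cross-word cues (`k#t` from *kick the bucket*).  All contiguous
windows are returned; words shorter than n−2 letters still yield at least
one boundary-marked n-gram, and no minimum-length filter is applied.  The
toy five-word lexicon instead uses bigram cues *without* boundary markers
(matching its standard exposition), so the extractor takes an explicit
`boundaries` flag.

Multi-word expressions are resolved by greedy longest-match-first against
the lexome dictionary; tokens without an entry fall back to an identity
lexome equal to the token string.  Homograph disambiguation is *not*
automated: the dictionary may carry contextual multi-word entries, but a
bare surface form maps to a single lexome, since no principled
disambiguation algorithm belongs in an event builder.

L2L window events never cross the boundary of the token sequence passed
in; the corpus generator therefore returns documents (lists of token
lists) rather than one flat stream, and callers decide what a "document"
is.  Sentence boundaries within a document are ignored.

## Measures

All seven measures are defined in terms of 1-norms, cosines and an OLS
residual:

| measure | definition | default |
|---|---|---|
| activation | Σ afferent weights from the lexome's own cues | — |
| a-diversity | 1-norm of the activation vector over all outcomes | — |
| G2L / L2L prior | column 1-norm | — |
| l-diversity | row 1-norm (L2L) | — |
| semantic density | # other lexomes with row-cosine > threshold | 0.9 |
| semantic typicality | cosine with the unweighted mean row vector | — |
| concept frequency | OLS residual of log frequency on the above | — |

Numerical conventions: rows of zero norm get cosine 0 to everything and 1
to themselves (unseen-lexome robustness); the typicality average is
unweighted (no frequency weighting); the prior is operationalized strictly
as the column 1-norm, with any "baseline firing" reading left as
interpretation.  Concept frequency regresses on all other measure columns
with an intercept; collinear columns are tolerated via a minimum-norm fit
(residuals are invariant to the choice within the collinear span) with a
warning, and the regression requires at least two more lexomes than
predictors.

In the assembled table, columns whose sample skewness exceeds 1.0 are
log-transformed and flagged — offset +1 for the count-valued density
column, no offset for strictly positive columns; columns containing
non-positive values or that are (near-)constant are left untouched.  A
lexome missing from a network gets `NA`, never a silent 0.

## Grid simulation

The non-linear-separation test bed is an `n_rows × n_cols` grid whose
class-A region is a filled disc: cells ranked by Euclidean distance to the
grid center, ties broken by a seeded shuffle, top `n_A` labeled A.  Two
encodings give each cell exactly two cues: one-hot (row and column
indicator labels) and hub features.  A *hub* is an A cell all of whose
in-grid neighbors are A; the second feature pair marks adjacency to a hub.
Neighborhoods are 8-connected (Moore) — with 4-connectivity the diagonal
rim of a disc would not touch any hub and perfect separation would fail.
Border cells use truncated in-grid neighborhoods.

Both class outcomes are trained, but classification ranks cells by the
activation of the A outcome alone, labelling the top `n_A` as A with ties
broken by row-major cell index.  On the standard 50×50 / 260-cell task a
single shuffled pass with hub features classifies perfectly (verified for
every tie-break seed 0–7); this is guaranteed only when every A cell is a
hub or a hub neighbor, which holds for discs thick relative to the
neighborhood but can fail for small or straggly discs, where one-cell
protrusions carry the same cue profile as distant B cells.  One-hot cues
under the same regime are imperfect, with all errors hugging the disc
edge and the deep interior classified correctly.  The original scattered
arrangement of the points before re-arrangement into a disc is not
reproducible (its coordinates were never published); only the disc layout
is generated.

## Evaluation statistics

Category cohesion compares within-category pairwise cosines against
(member, outsider) pairwise cosines with a Welch two-sample t-test.
Pairs sharing a word are treated as independent observations; that
dependence is acknowledged and deliberately not corrected, matching how
such group-mean tests are conventionally reported.  The sign test is the
exact one-sided upper-tail binomial probability at p = 0.5 (a two-sided
version would roughly double the p-value), cross-checked against integer
arithmetic.  The evidence ratio is `exp(|ΔAIC|/2)`, symmetric in its
arguments and saturating to `inf` past floating-point range; model scores
are user-supplied — no smoothing-spline regression is fitted here.

## Synthetic data

The corpus generator draws i.i.d. tokens from a Zipf distribution
(`p_r ∝ r^−s`, default exponent 1.0 — the classic value for natural
text — inverse-CDF over a finite vocabulary), organised into documents,
with multi-word expressions injected at configured per-position rates.
Defaults (vocabulary 1000, 20 documents × 500 tokens) keep an end-to-end
pipeline run in seconds.  What it emulates: rank-frequency skew, document
structure, recurring idioms.  What it does not: syntax, topical
coherence, burstiness, semantic correlation between collocates — so a
passing pipeline shows the machinery is correct, not that the predictors
would reach any particular effect size on real corpora.  Results at
billion-token scale are explicitly out of desk-scale reach; the
property-based suite plus the synthetic end-to-end run stand in for them.

The planted-category semantic matrix (category prototype + isotropic
Gaussian noise per row) is the test bed for the similarity-based
measures: at noise 0 within-category cosines are exactly 1, and at low
noise semantic density recovers category size − 1.

All generators are pure functions of spec + seed.

## Known limitations

* Streaming is by Python iterables; no out-of-core weight storage.
* Homograph senses require explicit contextual dictionary entries.
* The equilibrium per-cue decomposition is meaningful only up to the
  minimum-norm policy when cues are collinear.
* The Welch test in `category_cohesion` inherits the pairwise-dependence
  caveat above; p-values for large categories are anti-conservative.
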