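# ndlkit

Naive discriminative learning (NDL) for modelling lexical processing:
two-layer error-driven networks that map form cues onto meaning units, the
closed-form end state of that learning, and the family of network-derived
predictors used to model visual word recognition.

The package is aimed at computational psycholinguists who want to derive
discrimination-based predictors (activation, activation diversity, priors,
semantic density, …) from a corpus and feed them to their own statistical
models, and at anyone studying what plain two-layer networks can and cannot
learn.

## The model

A discrimination network is a `k × n` weight matrix from *cues* to
*outcomes*.  At each learning event *t*, with active cue set `C_t` and
present outcome set `O_t`, every weight from an active cue `c_i` to an
already-encountered outcome `o_j` changes by the Rescorla-Wagner rule

    Δw_ij = α β ( λ·1[o_j ∈ O_t] − Σ_{m ∈ C_t} w_mj )

with α = β = 0.1 and asymptote λ = 1 by default; weights from inactive cues
never change, and there is no squashing of outputs.  The long-run state of
this process solves, per outcome *o*, the linear system

    Σ_j P(c_j | c_i) · v_j = P(o | c_i)    for every cue c_i,

with conditional probabilities estimated from count-weighted co-occurrence.
Since n-gram cue sets are typically collinear, the system is rank-deficient
and `ndlkit` returns the minimum-norm least-squares solution.

Two networks are built from text:

* **G2L** — letter n-gram cues (word boundaries and spaces written `#`, so
  *corner* → `#co, cor, …, er#`) onto *lexomes*, identifiers of meanings
  that are not one-to-one with words: *pass away*, *kick the bucket* and
  *die* can share one lexome, while a homograph splits into several.
* **L2L** — a sliding window over the token stream, predicting the center
  word's lexome from its flanking words; rows of the trained matrix serve
  as distributional semantic vectors.

From the trained matrices come the lexical predictors: a lexome's
**activation** (summed afferent weights from its own cues), **a-diversity**
(1-norm of the whole activation vector — competition), the **G2L/L2L
priors** (column 1-norms — entrenchment independent of input),
**l-diversity** (row 1-norm), **semantic density** (neighbours above cosine
0.9), **semantic typicality** (cosine with the mean semantic vector) and
**concept frequency** (log frequency residualized on the other measures).

## Worked example

```sh
python examples/toy_lexicon_equilibrium.py
```

```
lexome frequencies: {'paid': 550, 'pail': 50, 'qaid': 1, 'said': 9900, 'sail': 50}

network: 6 bigram cues x 5 lexomes
paid: activation = 0.65(pa) + 0.04(ai) + 0.26(id) = 0.96
pail: activation = 0.08(pa) + 0.14(ai) + 0.31(il) = 0.52
qaid: activation = 0.73(qa) + 0.18(ai) + 0.09(id) = 1.00
said: activation = 0.67(sa) + 0.05(ai) + 0.28(id) = 1.00
sail: activation = 0.06(sa) + 0.13(ai) + 0.33(il) = 0.52
```

Although *qaid* occurred once in 10551 tokens, its unique bigram `qa` is
perfectly discriminative, so its equilibrium activation is a full 1.00 —
frequency is not the whole story under discrimination learning.  The other
examples cover the corpus-to-predictor pipeline
(`corpus_to_measures.py`), non-linear separation on a 50×50 grid — one-hot
cues reach accuracy 0.992 with all 20 errors at the disc edge, while hub
features separate perfectly in a single pass (`grid_separation.py`) — and
semantic-category cohesion plus sign-test / evidence-ratio statistics
(`semantic_categories.py`).

A thin CLI mirrors the pipeline:

```sh
ndlkit make-fixtures out/
ndlkit equilibrium out/toy_lexicon_events.tsv out/weights.tsv
ndlkit simulate-grid --encoding hub
```

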