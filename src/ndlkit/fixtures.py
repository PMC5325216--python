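"""Deterministic generators for test and demonstration inputs.

Everything here is synthetic and runs without any download: a five-word
toy lexicon with a closed-form equilibrium, Zipf-distributed corpora with
injected multi-word expressions, and category-structured semantic matrices.
The generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import LearningEvent, extract_letter_ngrams
from .learning import WeightMatrix

__all__ = [
    "TOY_LEXICON",
    "toy_lexicon",
    "SyntheticCorpusSpec",
    "synthetic_corpus",
    "synthetic_semantic_matrix",
]

# The worked five-word example: forms and token frequencies.  qaid's unique
# cue 'qa' makes it a highly discriminative cue despite frequency 1.
TOY_LEXICON: tuple[tuple[str, int], ...] = (
    ("paid", 550),
    ("pail", 50),
    ("qaid", 1),
    ("said", 9900),
    ("sail", 50),
)


def toy_lexicon() -> list[LearningEvent]:
    """The five-lexome toy lexicon with letter-bigram cues.

    One counted event per word (*paid, pail, qaid, said, sail* with
    frequencies 550, 50, 1, 9900, 50), bigram cues without boundary
    markers, giving the cue universe {ai, id, il, pa, qa, sa}.  Feeding
    this stream to the equilibrium solver reproduces the worked activation
    of 1.00 for *qaid* from its cues qa, ai, id.
    """
    return [
        LearningEvent(
            frozenset(extract_letter_ngrams(word, 2, boundaries=False)),
            frozenset({word}),
            count,
        )
        for word, count in TOY_LEXICON
    ]


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Parameters of the Zipfian synthetic corpus generator.

    The corpus emulates the statistical skeleton of a large text corpus:
    a power-law (Zipf) rank-frequency distribution over an artificial
    vocabulary, organised into documents, with multi-word expressions
    injected at a configurable rate per token position.  ``mwes`` maps a
    space-separated phrase to its insertion probability.
    """

    vocab_size: int = 1000
    zipf_exponent: float = 1.0
    n_documents: int = 20
    doc_length: int = 500
    mwes: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size < 1 or self.n_documents < 1 or self.doc_length < 1:
            raise ValueError("vocab_size, n_documents and doc_length must be positive")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be positive")
        for phrase, rate in self.mwes:
            if not phrase.split():
                raise ValueError("multi-word expression must be nonempty")
            if not 0 <= rate < 1:
                raise ValueError(f"insertion rate must lie in [0, 1), got {rate}")


def synthetic_corpus(spec: SyntheticCorpusSpec) -> list[list[str]]:
    """Generate a deterministic synthetic corpus as a list of documents.

    Each document is a token list.  Tokens are drawn i.i.d. from a Zipf
    distribution (p_r ∝ r^-s over ranks r = 1..V, inverse-CDF sampling);
    at each position, with the configured probability, a multi-word
    expression is emitted instead.  Identical specs (including seed) give
    byte-identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    ranks = np.arange(1, spec.vocab_size + 1, dtype=float)
    probs = ranks ** (-spec.zipf_exponent)
    probs /= probs.sum()
    cdf = np.cumsum(probs)
    width = len(str(spec.vocab_size))
    vocab = [f"w{r:0{width}d}" for r in range(1, spec.vocab_size + 1)]
    mwe_phrases = [p.split() for p, _ in spec.mwes]
    mwe_rates = np.array([r for _, r in spec.mwes])
    total_rate = float(mwe_rates.sum())

    docs: list[list[str]] = []
    for _ in range(spec.n_documents):
        doc: list[str] = []
        while len(doc) < spec.doc_length:
            u = rng.random()
            if total_rate > 0 and u < total_rate:
                which = int(np.searchsorted(np.cumsum(mwe_rates), u, side="right"))
                doc.extend(mwe_phrases[which])
            else:
                doc.append(vocab[int(np.searchsorted(cdf, rng.random(), side="left"))])
        docs.append(doc[: spec.doc_length])
    return docs


def synthetic_semantic_matrix(
    n_categories: int,
    size_per_category: int,
    noise: float,
    seed: int = 0,
    n_dims: int | None = None,
) -> WeightMatrix:
    """An L2L-shaped weight matrix with planted category structure.

    Each category gets a Gaussian prototype vector; member rows are the
    prototype plus isotropic Gaussian noise of the given standard
    deviation.  At noise 0 within-category cosines are exactly 1; at low
    noise, categories are recoverable by cosine clustering, which makes
    this the test bed for the semantic-similarity measures.

    Row labels are ``cat{i}_word{j}``; column labels ``dim{d}``.
    """
    if n_categories < 1 or size_per_category < 1:
        raise ValueError("n_categories and size_per_category must be positive")
    if noise < 0:
        raise ValueError("noise must be non-negative")
    if n_dims is None:
        n_dims = max(20, 4 * n_categories)
    rng = np.random.default_rng(seed)
    prototypes = rng.normal(size=(n_categories, n_dims))
    rows = []
    labels = []
    for c in range(n_categories):
        for m in range(size_per_category):
            rows.append(prototypes[c] + noise * rng.normal(size=n_dims))
            labels.append(f"cat{c}_word{m}")
    dims = [f"dim{d}" for d in range(n_dims)]
    return WeightMatrix(labels, dims, np.vstack(rows))
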