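"""Discrimination-based lexical predictors from trained weight matrices.

From the grapheme-to-lexome (G2L) network: a lexome's **activation** (sum
of afferent weights from its orthographic cues), the **a-diversity**
(1-norm of the full activation vector given those cues, a competition
measure), and the **G2L prior** (1-norm of the lexome's weight column, a
cue-independent entrenchment measure).  From the lexome-to-lexome (L2L)
network: the **L2L prior** (column 1-norm), the **l-diversity** (row
1-norm — how much a lexome as cue co-activates other lexomes), **semantic
density** (number of other lexomes whose row vectors exceed cosine 0.9
with the target's) and **semantic typicality** (cosine with the average
row vector).  **Concept frequency** is log written frequency residualized
on the learning-based predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .learning import WeightMatrix

__all__ = [
    "activation",
    "activation_vector",
    "pnorm",
    "mad",
    "a_diversity",
    "prior",
    "l_diversity",
    "cosine_similarity_matrix",
    "semantic_density",
    "semantic_typicality",
    "concept_frequency",
    "MeasureTable",
    "assemble_measure_table",
    "MEASURE_COLUMNS",
]

MEASURE_COLUMNS = (
    "g2l_activation",
    "g2l_adiversity",
    "g2l_prior",
    "l2l_prior",
    "l2l_ldiversity",
    "sem_density",
    "sem_typicality",
    "concept_frequency",
)


def activation(W: WeightMatrix, cues: Iterable[str], outcome: str) -> float:
    """Summed afferent weight from the active cues to one outcome.

    Cues unknown to the network contribute 0; an unknown outcome yields
    0 with a warning.
    """
    cues = set(cues)
    if not cues:
        raise ValueError("activation requires at least one cue")
    if not W.has_outcome(outcome):
        warnings.warn(f"outcome {outcome!r} unknown to the network; activation 0")
        return 0.0
    return float(sum(W.weight(c, outcome) for c in cues))


def activation_vector(W: WeightMatrix, cues: Iterable[str]) -> pd.Series:
    """Activations of every outcome given a set of active cues."""
    cues = set(cues)
    if not cues:
        raise ValueError("activation requires at least one cue")
    total = np.zeros(len(W.outcomes))
    for c in cues:
        total += W.row(c)
    return pd.Series(total, index=list(W.outcomes), name="activation")


def pnorm(v: Sequence[float] | np.ndarray, p: float) -> float:
    """The p-norm (Σ|v_i|^p)^(1/p); p=1 absolute length, p=2 Euclidean."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("pnorm of an empty vector is undefined")
    if p <= 0:
        raise ValueError(f"p must be positive, got {p}")
    return float(np.sum(np.abs(v) ** p) ** (1.0 / p))


def mad(v: Sequence[float] | np.ndarray) -> float:
    """Median absolute deviation from the median."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(v - np.median(v))))


def a_diversity(W: WeightMatrix, cues: Iterable[str]) -> float:
    """1-norm of the activation vector: diversity of co-activated outcomes."""
    return pnorm(activation_vector(W, cues).to_numpy(), 1.0)


def prior(W: WeightMatrix, outcome: str) -> float:
    """Column 1-norm: a lexome's cue-independent prior availability."""
    return pnorm(W.column(outcome), 1.0) if W.has_outcome(outcome) else 0.0


def l_diversity(W_l2l: WeightMatrix, lexome: str) -> float:
    """Row 1-norm in the L2L matrix: co-activation spread of a lexome cue."""
    return pnorm(W_l2l.row(lexome), 1.0) if W_l2l.has_cue(lexome) else 0.0


def cosine_similarity_matrix(W_l2l: WeightMatrix) -> pd.DataFrame:
    """Pairwise cosine similarity of the row (semantic) vectors.

    Returns a symmetric lexome×lexome DataFrame.  Rows with zero norm get
    similarity 0 to everything and 1 to themselves by convention.
    """
    rows = W_l2l.dense()
    labels = list(W_l2l.cues)
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = rows / safe[:, None]
    S = unit @ unit.T
    zero = norms == 0
    S[zero, :] = 0.0
    S[:, zero] = 0.0
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=labels, columns=labels)


def semantic_density(
    S: pd.DataFrame, lexome: str, threshold: float = 0.9
) -> int:
    """Number of *other* lexomes with cosine similarity above ``threshold``."""
    row = S.loc[lexome].drop(labels=[lexome])
    return int((row > threshold).sum())


def semantic_typicality(W_l2l: WeightMatrix, lexome: str) -> float:
    """Cosine of a lexome's semantic vector with the average semantic vector."""
    rows = W_l2l.dense()
    mean = rows.mean(axis=0)
    v = W_l2l.row(lexome)
    nv, nm = np.linalg.norm(v), np.linalg.norm(mean)
    if nv == 0 or nm == 0:
        return 0.0
    return float(v @ mean / (nv * nm))


def concept_frequency(
    log_freq: pd.Series, predictors: pd.DataFrame
) -> pd.Series:
    """Residualize log frequency on the learning-based predictors (OLS).

    The residual estimates the part of a word's frequency of use that the
    discrimination measures cannot account for — a proxy for how often the
    underlying concept is encountered outside language.  Collinear
    predictor columns are tolerated (minimum-norm fit) with a warning;
    residuals are unaffected by the choice within the collinear span.
    """
    X = predictors.loc[log_freq.index].to_numpy(dtype=float)
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            "need at least two more observations than predictors "
            f"({X.shape[0]} rows, {X.shape[1]} predictors)"
        )
    design = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, log_freq.to_numpy(float), rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "collinear predictor columns in concept-frequency regression; "
            "using the minimum-norm fit"
        )
    resid = log_freq.to_numpy(float) - design @ coef
    return pd.Series(resid, index=log_freq.index, name="concept_frequency")


@dataclass
class MeasureTable:
    """Per-lexome table of the discrimination-based predictors.

    ``table`` has one row per lexome and the columns of
    :data:`MEASURE_COLUMNS`; ``log_transformed`` flags columns stored on a
    log scale, with the offset that was added before taking logs.
    """

    table: pd.DataFrame
    log_transformed: dict[str, float] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        flags = ";".join(f"{c}+{off:g}" for c, off in self.log_transformed.items())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# log_transformed: {flags}\n")
            df.to_csv(fh, sep="\t", index_label="lexome", na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MeasureTable":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if not first.startswith("# log_transformed:"):
                raise ValueError("missing log_transformed header line")
            flags_str = first.split(":", 1)[1].strip()
            flags: dict[str, float] = {}
            if flags_str:
                for item in flags_str.split(";"):
                    col, off = item.rsplit("+", 1)
                    flags[col] = float(off)
            df = pd.read_csv(fh, sep="\t", index_col="lexome")
        return cls(df, flags)


def _maybe_log(
    col: pd.Series, offset: float, skew_threshold: float
) -> tuple[pd.Series, bool]:
    vals = col.dropna()
    if len(vals) < 3 or (vals + offset <= 0).any():
        return col, False
    arr = vals.to_numpy(float)
    if np.ptp(arr) < 1e-12 * max(1.0, np.abs(arr).max()):
        return col, False  # (near-)constant column: skewness undefined
    if stats.skew(arr) > skew_threshold:
        return np.log(col + offset), True
    return col, False


def assemble_measure_table(
    W_g2l: WeightMatrix,
    W_l2l: WeightMatrix,
    cue_map: Mapping[str, Iterable[str]],
    freq_map: Mapping[str, float],
    *,
    density_threshold: float = 0.9,
    skew_threshold: float = 1.0,
) -> MeasureTable:
    """Compute all predictors for the lexomes in ``cue_map``.

    ``cue_map`` gives each lexome's active orthographic cues (its letter
    n-grams); ``freq_map`` its written frequency.  A lexome missing from a
    network gets NA for the measures of that network, never a silent 0.
    Columns with sample skewness above ``skew_threshold`` are
    log-transformed (offset +1 for the count-valued density column, no
    offset for strictly positive measures) and flagged.
    """
    lexomes = list(cue_map)
    cols: dict[str, list[float]] = {c: [] for c in MEASURE_COLUMNS[:-1]}
    S = cosine_similarity_matrix(W_l2l) if W_l2l.shape[0] else None
    for lex in lexomes:
        cues = set(cue_map[lex])
        in_g2l = W_g2l.has_outcome(lex)
        in_l2l_row = W_l2l.has_cue(lex)
        in_l2l_col = W_l2l.has_outcome(lex)
        if in_g2l:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cols["g2l_activation"].append(activation(W_g2l, cues, lex))
            cols["g2l_adiversity"].append(a_diversity(W_g2l, cues))
            cols["g2l_prior"].append(prior(W_g2l, lex))
        else:
            for c in ("g2l_activation", "g2l_adiversity", "g2l_prior"):
                cols[c].append(np.nan)
        cols["l2l_prior"].append(prior(W_l2l, lex) if in_l2l_col else np.nan)
        if in_l2l_row and S is not None:
            cols["l2l_ldiversity"].append(l_diversity(W_l2l, lex))
            cols["sem_density"].append(
                semantic_density(S, lex, density_threshold)
            )
            cols["sem_typicality"].append(semantic_typicality(W_l2l, lex))
        else:
            for c in ("l2l_ldiversity", "sem_density", "sem_typicality"):
                cols[c].append(np.nan)
    df = pd.DataFrame(cols, index=pd.Index(lexomes, name="lexome"))

    flags: dict[str, float] = {}
    for col in df.columns:
        offset = 1.0 if col == "sem_density" else 0.0
        transformed, done = _maybe_log(df[col], offset, skew_threshold)
        if done:
            df[col] = transformed
            flags[col] = offset

    # concept frequency: residual of log frequency on the other predictors,
    # over the lexomes with complete data
    log_freq = pd.Series(
        {lex: np.log(freq_map[lex]) for lex in lexomes if lex in freq_map},
        dtype=float,
    )
    df["concept_frequency"] = np.nan
    complete = df.loc[
        df.index.intersection(log_freq.index),
        list(MEASURE_COLUMNS[:-1]),
    ].dropna()
    if len(complete) >= len(MEASURE_COLUMNS[:-1]) + 2:
        resid = concept_frequency(log_freq.loc[complete.index], complete)
        df.loc[resid.index, "concept_frequency"] = resid
    return MeasureTable(df, flags)
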