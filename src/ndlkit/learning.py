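"""Rescorla-Wagner learning: incremental updates and the equilibrium solve.

A two-layer discrimination network is a k×n weight matrix from cues to
outcomes.  At each learning event the weights on connections from the
*active* cues to every outcome encountered so far are adjusted by the
error-driven delta rule

    Δw_ij = α β (λ·present(o_j) − Σ_{m active} w_mj)

with learning rate αβ and asymptote λ.  Outcomes acquire weights only from
the first event in which they appear; weights from inactive cues never
change.  There is no squashing function on the outputs.

The long-run state of this process is characterized by a linear system per
outcome o:

    Σ_j P(c_j | c_i) v_j = P(o | c_i)   for every cue c_i,

where the conditional probabilities come from count-weighted cue/outcome
co-occurrence.  Boundary-marked n-gram cue sets are routinely collinear
(shared cues occur in every word), so the system is rank-deficient; the
minimum-norm least-squares solution is used, which leaves per-cue weights
solver-dependent but their per-word sums well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .events import EventStream, LearningEvent

__all__ = [
    "LearnerConfig",
    "WeightMatrix",
    "rw_update",
    "train",
    "equilibrium_weights",
    "write_weights_tsv",
    "read_weights_tsv",
]


@dataclass(frozen=True)
class LearnerConfig:
    """Rescorla-Wagner parameters and training-order policy.

    alpha and beta are shared scalar cue salience / outcome learning rate
    (the product αβ is the effective learning rate); lam is the asymptote
    of learning.  ``passes`` full sweeps are made over the stream; with a
    ``shuffle_seed`` the expanded event order is reshuffled each pass,
    interleaving repeated events frequency-proportionally.
    """

    alpha: float = 0.1
    beta: float = 0.1
    lam: float = 1.0
    passes: int = 1
    shuffle_seed: int | None = None

    def __post_init__(self) -> None:
        rate = self.alpha * self.beta
        if not 0.0 < rate < 1.0:
            raise ValueError(f"alpha*beta must lie in (0, 1), got {rate}")
        if self.lam <= 0:
            raise ValueError(f"lambda must be positive, got {self.lam}")
        if self.passes < 1:
            raise ValueError(f"passes must be >= 1, got {self.passes}")


class WeightMatrix:
    """Cue×outcome association weights with stable label indexing.

    Lookup of any (cue, outcome) pair is defined; absent entries read 0.
    Storage is a dense block that grows as new labels are encountered —
    the matrices handled here are small enough that dense arithmetic wins;
    the triplet TSV exporter emits only the nonzero entries.
    """

    def __init__(
        self,
        cues: Iterable[str] = (),
        outcomes: Iterable[str] = (),
        weights: np.ndarray | None = None,
    ) -> None:
        self._cue_index: dict[str, int] = {}
        self._out_index: dict[str, int] = {}
        for c in cues:
            self._intern(self._cue_index, c, "cue")
        for o in outcomes:
            self._intern(self._out_index, o, "outcome")
        k, n = len(self._cue_index), len(self._out_index)
        self._store = np.zeros((max(k, 4), max(n, 4)))
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (k, n):
                raise ValueError(f"weights shape {weights.shape} != ({k}, {n})")
            self._store[:k, :n] = weights

    @staticmethod
    def _intern(index: dict[str, int], label: str, kind: str) -> int:
        if label in index:
            raise ValueError(f"duplicate {kind} label {label!r}")
        index[label] = len(index)
        return index[label]

    # -- index management -------------------------------------------------
    @property
    def cues(self) -> tuple[str, ...]:
        return tuple(self._cue_index)

    @property
    def outcomes(self) -> tuple[str, ...]:
        return tuple(self._out_index)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self._cue_index), len(self._out_index)

    def _grow(self, rows: int, cols: int) -> None:
        r, c = self._store.shape
        if rows <= r and cols <= c:
            return
        new = np.zeros((max(rows, 2 * r), max(cols, 2 * c)))
        new[:r, :c] = self._store
        self._store = new

    def ensure_cue(self, label: str) -> int:
        idx = self._cue_index.get(label)
        if idx is None:
            idx = len(self._cue_index)
            self._cue_index[label] = idx
            self._grow(idx + 1, self._store.shape[1])
        return idx

    def ensure_outcome(self, label: str) -> int:
        idx = self._out_index.get(label)
        if idx is None:
            idx = len(self._out_index)
            self._out_index[label] = idx
            self._grow(self._store.shape[0], idx + 1)
        return idx

    def has_cue(self, label: str) -> bool:
        return label in self._cue_index

    def has_outcome(self, label: str) -> bool:
        return label in self._out_index

    # -- access -----------------------------------------------------------
    def weight(self, cue: str, outcome: str) -> float:
        i = self._cue_index.get(cue)
        j = self._out_index.get(outcome)
        if i is None or j is None:
            return 0.0
        return float(self._store[i, j])

    def row(self, cue: str) -> np.ndarray:
        """Efferent weights of a cue over all outcomes (zeros if unknown)."""
        n = len(self._out_index)
        i = self._cue_index.get(cue)
        if i is None:
            return np.zeros(n)
        return self._store[i, :n].copy()

    def column(self, outcome: str) -> np.ndarray:
        """Afferent weights of an outcome over all cues (zeros if unknown)."""
        k = len(self._cue_index)
        j = self._out_index.get(outcome)
        if j is None:
            return np.zeros(k)
        return self._store[:k, j].copy()

    def dense(self) -> np.ndarray:
        """The k×n weight array (a copy, rows = cues, columns = outcomes)."""
        k, n = self.shape
        return self._store[:k, :n].copy()

    def _view(self) -> np.ndarray:
        k, n = self.shape
        return self._store[:k, :n]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.cues, self.outcomes, self.dense())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightMatrix):
            return NotImplemented
        return (
            self.cues == other.cues
            and self.outcomes == other.outcomes
            and np.array_equal(self._view(), other._view())
        )


def rw_update(
    W: WeightMatrix, event: LearningEvent, cfg: LearnerConfig | None = None
) -> WeightMatrix:
    """Apply one Rescorla-Wagner update in place; returns ``W``.

    Weights from cues absent from the event are untouched.  For every
    active cue and every outcome the network has seen (including outcomes
    introduced by this event), the weight moves toward λ when the outcome
    is present and toward 0 when absent, in proportion to the summed
    support the active cues already give that outcome.  The event's
    ``count`` is ignored here; :func:`train` expands counts.
    """
    if cfg is None:
        cfg = LearnerConfig()
    rows = np.array([W.ensure_cue(c) for c in event.cues])
    for o in event.outcomes:
        W.ensure_outcome(o)
    n = len(W.outcomes)
    if n == 0:
        return W
    arr = W._view()
    present = np.zeros(n)
    for o in event.outcomes:
        present[W._out_index[o]] = 1.0
    totals = arr[rows].sum(axis=0)
    delta = cfg.alpha * cfg.beta * (cfg.lam * present - totals)
    arr[rows] += delta
    return W


def train(stream: EventStream, cfg: LearnerConfig | None = None) -> WeightMatrix:
    """Train a weight matrix incrementally over an event stream.

    Events with count > 1 are expanded to count identical consecutive
    updates; with ``cfg.passes`` > 1 the expanded stream is swept
    repeatedly, reshuffled per pass when ``cfg.shuffle_seed`` is set.
    The result is reproducible given (stream, cfg).
    """
    if cfg is None:
        cfg = LearnerConfig()
    events = list(stream)
    if not events:
        raise ValueError("cannot train on an empty event stream")
    expanded: list[LearningEvent] = []
    for e in events:
        expanded.extend([e] * e.count)
    rng = (
        np.random.default_rng(cfg.shuffle_seed)
        if cfg.shuffle_seed is not None
        else None
    )
    W = WeightMatrix()
    rate = cfg.alpha * cfg.beta
    order = np.arange(len(expanded))
    # cache integer indices and the λ·present target vector per distinct
    # event; the cached vector is rebuilt whenever new outcomes appeared
    cache: dict[int, tuple[np.ndarray, list[str], np.ndarray, int]] = {}
    for _ in range(cfg.passes):
        if rng is not None:
            rng.shuffle(order)
        for pos in order:
            e = expanded[pos]
            key = id(e)
            hit = cache.get(key)
            if hit is None:
                rows = np.array([W.ensure_cue(c) for c in e.cues])
                outs = list(e.outcomes)
                for o in outs:
                    W.ensure_outcome(o)
                hit = (rows, outs, np.empty(0), -1)
            rows, outs, target, n_cached = hit
            n = len(W._out_index)
            if n_cached != n:
                target = np.zeros(n)
                for o in outs:
                    target[W._out_index[o]] = cfg.lam
                cache[key] = (rows, outs, target, n)
            arr = W._store[: len(W._cue_index), :n]
            sub = arr[rows]
            arr[rows] = sub + rate * (target - sub.sum(axis=0))
    return W


def equilibrium_weights(stream: EventStream, lam: float = 1.0) -> WeightMatrix:
    """Solve the equilibrium linear system of Rescorla-Wagner learning.

    For each outcome o the column v solves  M v = b  where
    M[i, j] = P(c_j | c_i) and b[i] = P(o | c_i), probabilities estimated
    from count-weighted co-occurrence over the stream.  Rank-deficient
    systems (collinear cues) take the minimum-norm least-squares solution
    (relative singular-value cutoff 1e-10).  The solution depends only on
    the event counts, not on stream order.
    """
    events = list(stream)
    if not events:
        raise ValueError("cannot solve equilibrium for an empty event stream")
    cue_labels: dict[str, int] = {}
    out_labels: dict[str, int] = {}
    for e in events:
        for c in sorted(e.cues):
            cue_labels.setdefault(c, len(cue_labels))
        for o in sorted(e.outcomes):
            out_labels.setdefault(o, len(out_labels))
    k, n = len(cue_labels), len(out_labels)
    cue_count = np.zeros(k)
    cue_cooc = np.zeros((k, k))
    cue_out = np.zeros((k, n))
    for e in events:
        ci = [cue_labels[c] for c in e.cues]
        oi = [out_labels[o] for o in e.outcomes]
        cue_count[ci] += e.count
        cue_cooc[np.ix_(ci, ci)] += e.count
        cue_out[np.ix_(ci, oi)] += e.count
    live = cue_count > 0
    if not live.all():
        dead = [c for c, i in cue_labels.items() if not live[i]]
        warnings.warn(f"excluding zero-count cues from equilibrium solve: {dead}")
    idx = np.flatnonzero(live)
    M = cue_cooc[np.ix_(idx, idx)] / cue_count[idx, None]
    B = cue_out[idx] / cue_count[idx, None]
    V, *_ = np.linalg.lstsq(M, lam * B, rcond=1e-10)
    kept = [c for c, i in cue_labels.items() if live[i]]
    return WeightMatrix(kept, list(out_labels), V)


def write_weights_tsv(W: WeightMatrix, path: str | Path) -> None:
    """Persist a weight matrix as a plain-text triplet TSV.

    Two header lines give the matrix dimensions (k cues, n outcomes),
    followed by the full label indices and the nonzero (cue, outcome,
    weight) triplets.  The format round-trips exactly.
    """
    k, n = W.shape
    arr = W.dense()
    cues, outs = W.cues, W.outcomes
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"k\t{k}\n")
        fh.write(f"n\t{n}\n")
        fh.write("cues\t" + "\t".join(cues) + "\n")
        fh.write("outcomes\t" + "\t".join(outs) + "\n")
        fh.write("cue\toutcome\tweight\n")
        for i, j in zip(*np.nonzero(arr)):
            fh.write(f"{cues[i]}\t{outs[j]}\t{float(arr[i, j])!r}\n")


def read_weights_tsv(path: str | Path) -> WeightMatrix:
    with open(path, encoding="utf-8") as fh:
        k = int(fh.readline().split("\t")[1])
        n = int(fh.readline().split("\t")[1])
        cues = fh.readline().rstrip("\n").split("\t")[1:]
        outs = fh.readline().rstrip("\n").split("\t")[1:]
        if len(cues) != k or len(outs) != n:
            raise ValueError("weight file header is inconsistent")
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["cue", "outcome", "weight"]:
            raise ValueError(f"unexpected triplet header {header}")
        arr = np.zeros((k, n))
        ci = {c: i for i, c in enumerate(cues)}
        oi = {o: j for j, o in enumerate(outs)}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cue, out, w = line.split("\t")
            arr[ci[cue], oi[out]] = float(w)
    return WeightMatrix(cues, outs, arr)
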