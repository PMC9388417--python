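"""Numerical primitives shared across the package.

Categorical distributions with labelled support, Dirichlet-count utilities
(normalisation and expected-log parameterisation), and the softmax / floored-log
helpers used throughout the inference engine.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

#: probabilities are floored at this value inside logarithms
PROB_FLOOR = 1e-16
#: tolerance for "sums to one" checks
NORM_TOL = 1e-10


def floored_log(p: np.ndarray) -> np.ndarray:
    """Elementwise natural log with probabilities floored at ``PROB_FLOOR``."""
    return np.log(np.maximum(np.asarray(p, dtype=float), PROB_FLOOR))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    x = np.asarray(x, dtype=float)
    shifted = x - x.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats; terms with p == 0 contribute zero."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - floored_log(q[mask]))))


def entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats; 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    mask = p > 0
    return float(-np.sum(p[mask] * np.log(p[mask])))


@dataclass(frozen=True)
class CategoricalDist:
    """A probability distribution over a small labelled finite support.

    Invariants (checked at construction): labels unique and non-empty, all
    probabilities non-negative and summing to one within ``NORM_TOL``.
    """

    labels: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if len(self.labels) == 0:
            raise ValueError("support must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"support labels must be unique, got {self.labels}")
        if probs.shape != (len(self.labels),):
            raise ValueError(
                f"probs shape {probs.shape} does not match {len(self.labels)} labels"
            )
        if np.any(probs < 0):
            raise ValueError(f"negative probability in {probs}")
        if abs(probs.sum() - 1.0) > NORM_TOL:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")

    def __getitem__(self, label: str) -> float:
        return float(self.probs[self.labels.index(label)])

    def argmax_label(self) -> str:
        return self.labels[int(np.argmax(self.probs))]


def normalize_counts(counts: np.ndarray, axis: int = 0, name: str = "counts") -> np.ndarray:
    """Normalise non-negative concentration counts into probability columns.

    Each slice along ``axis`` is divided by its total so that it sums to one,
    preserving proportionality.  A slice with zero total is an error (it carries
    no information to normalise) and the offending column indices are named.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError(f"{name} must be non-negative")
    sums = counts.sum(axis=axis, keepdims=True)
    if np.any(sums == 0):
        bad = np.argwhere(np.squeeze(sums == 0, axis=axis))
        raise ValueError(f"{name}: all-zero column(s) at index {bad.ravel().tolist()}")
    return counts / sums


def dirichlet_expected_log(counts: np.ndarray, axis: int = 0) -> np.ndarray:
    """Expected log-probabilities E[ln p] under a Dirichlet with the given counts.

    Per entry this is ``digamma(count) - digamma(column sum)``.  Exponentiating
    and renormalising converges to ``normalize_counts`` as counts grow large,
    but at small counts the expected-log parameterisation is what a
    learning-aware agent should use in place of ln A / ln D.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("counts must be strictly positive for expected-log")
    return digamma(counts) - digamma(counts.sum(axis=axis, keepdims=True))
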