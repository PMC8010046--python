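"""Information-theoretic metrics over syntactic transition probabilities.

Entropy quantifies uncertainty about upcoming syntactic material given the
context; entropy reduction is the drop in that uncertainty after a word;
surprisal is the negative log-probability of a word given its context.  All
three are computed from a :class:`~masslmm.design.TransitionTable` estimated
either from a corpus (supplied as CSV) or from the experimental design
itself.  Logs are base 2 (bits) by default.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MissingContextError",
    "entropy",
    "entropy_reduction",
    "surprisal",
    "sequence_metrics",
]


class MissingContextError(KeyError):
    """A sequence token was used as a context absent from the table."""

    def __init__(self, context: str):
        super().__init__(f"context {context!r} not present in transition table")
        self.context = context


def _validate_dist(dist) -> np.ndarray:
    p = np.asarray(dist, dtype=float)
    if p.ndim != 1:
        raise ValueError("distribution must be a 1-D probability vector")
    if (p < 0).any():
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    return p


def entropy(dist, base: float = 2.0) -> float:
    """Shannon entropy of a probability vector, with 0*log(0) = 0."""
    p = _validate_dist(dist)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / math.log(base))


def entropy_reduction(prior, posterior, base: float = 2.0, signed: bool = False) -> float:
    """Drop in entropy from the prior to the posterior distribution.

    Floored at zero by default (uncertainty *reduction*); ``signed=True``
    returns the raw difference.
    """
    diff = entropy(prior, base=base) - entropy(posterior, base=base)
    return float(diff) if signed else float(max(0.0, diff))


def surprisal(p: float, base: float = 2.0) -> float:
    """Negative log-probability of an observed continuation."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"probability must be in (0, 1], got {p!r}")
    return float(-math.log(p) / math.log(base)) + 0.0


def sequence_metrics(
    table,
    sequence: Sequence[str],
    start_context: str | None = None,
    base: float = 2.0,
    provenance: str = "design",
) -> pd.DataFrame:
    """Per-position entropy, entropy reduction and surprisal for a token
    sequence under a transition table.

    Each token's surprisal is its conditional probability given the previous
    token (or ``start_context`` for the first token, when provided; otherwise
    the first token's surprisal is NaN).  The entropy at a position is the
    entropy over continuations of the token just read; tokens that are not
    contexts in the table mark the end of the trial, where uncertainty about
    upcoming material is zero by definition.  Entropy reduction compares
    successive entropies, floored at zero.

    Returns a DataFrame with columns ``position, token, surprisal, entropy,
    entropy_reduction`` and a ``provenance`` attribute.
    """
    if len(sequence) == 0:
        raise ValueError("sequence must contain at least one token")
    contexts = set(table.contexts)

    def _entropy_after(token: str) -> float:
        if token in contexts:
            return entropy(table.distribution(token).to_numpy(), base=base)
        return 0.0  # trial is over: no remaining uncertainty

    rows = []
    prev_entropy: float | None = None
    prev_context: str | None = start_context
    for i, token in enumerate(sequence):
        if prev_context is None:
            surp = float("nan")
        else:
            if prev_context not in contexts:
                raise MissingContextError(prev_context)
            p = table.prob(prev_context, token)
            if p <= 0:
                raise ValueError(
                    f"token {token!r} has zero probability after {prev_context!r}"
                )
            surp = surprisal(p, base=base)
        ent = _entropy_after(token)
        if prev_entropy is None and start_context is not None:
            prev_entropy = _entropy_after(start_context) if start_context in contexts else None
        red = (
            float("nan")
            if prev_entropy is None
            else max(0.0, prev_entropy - ent)
        )
        rows.append(
            {
                "position": i,
                "token": token,
                "surprisal": surp,
                "entropy": ent,
                "entropy_reduction": red,
            }
        )
        prev_entropy = ent
        prev_context = token
    report = pd.DataFrame(rows)
    report.attrs["provenance"] = provenance
    return report
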