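"""Factorial experimental design: sets, blocks, trials and the transition
probabilities the design implies.

The design mirrors a reading experiment in which each stimulus *set*
contributes 20 condition cells: twelve two-word (noun-adjective) cells formed
by crossing syntactic structure (indefinite phrase / sentence / definite
phrase) with noun conceptual specificity (high/low) and adjective form
typicality (high/low), plus eight single-word control cells (nouns: 2
specificity x 2 definiteness; adjectives: 2 typicality x 2 definiteness).
With 36 sets this yields 720 trials per participant, distributed over 10
blocks (6 two-word, 4 single-word) by a cyclic Latin square so that every
word token appears at most once per block.

Syntactic structure is fully determined by the definiteness marking of the
two words: an indefinite noun + indefinite adjective is an indefinite phrase;
a definite noun + bare (indefinite) adjective is a full sentence; definite
noun + definite adjective is a definite phrase.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "ConditionCell",
    "TransitionTable",
    "DesignInfeasibleError",
    "enumerate_set_cells",
    "generate_design",
    "design_transition_probabilities",
    "marginal_probabilities",
    "augment_trials",
]

N_TWO_WORD_BLOCKS = 6
N_ONE_WORD_BLOCKS = 4
N_BLOCKS = N_TWO_WORD_BLOCKS + N_ONE_WORD_BLOCKS

SYNTAX_LEVELS = ("indefinite_phrase", "sentence", "definite_phrase")

#: syntactic structure -> (noun definiteness, adjective definiteness)
SYNTAX_DEFINITENESS = {
    "indefinite_phrase": ("indefinite", "indefinite"),
    "sentence": ("definite", "indefinite"),
    "definite_phrase": ("definite", "definite"),
}

# experiment clock starts after instruction/practice screens
_CLOCK_START_S = 30.0
_ELEMENT_ON_S = 0.300
_ELEMENT_OFF_S = 0.300
_JITTER_RANGE_S = (0.46666, 0.700)
_BLOCK_BREAK_S = 10.0
_TASK_RT_RANGE_S = (1.0, 3.0)


class DesignInfeasibleError(ValueError):
    """The requested set count cannot be partitioned by the Latin square."""


@dataclass(frozen=True)
class ConditionCell:
    """One of the 20 condition cells contributed by every stimulus set."""

    block_type: str  # 'two_word' | 'one_word'
    syntactic: str  # structure level, or 'none' for single words
    noun_definiteness: str
    noun_specificity: str
    adj_typicality: str
    adj_definiteness: str
    word_category: str  # 'both' | 'noun' | 'adjective'

    def __post_init__(self) -> None:
        if self.block_type == "two_word":
            expected = SYNTAX_DEFINITENESS[self.syntactic]
            if (self.noun_definiteness, self.adj_definiteness) != expected:
                raise ValueError(
                    f"two-word cell with syntactic={self.syntactic!r} must have "
                    f"definiteness {expected}"
                )
            if self.word_category != "both":
                raise ValueError("two-word cells contain both words")
        else:
            if self.syntactic != "none":
                raise ValueError("one-word cells have no syntactic structure")
            if self.word_category not in ("noun", "adjective"):
                raise ValueError("one-word cells present exactly one category")


def enumerate_set_cells() -> list[ConditionCell]:
    """The 20 cells of one full set: 12 two-word followed by 8 one-word."""
    cells: list[ConditionCell] = []
    for syntactic in SYNTAX_LEVELS:
        noun_def, adj_def = SYNTAX_DEFINITENESS[syntactic]
        for spec in ("high", "low"):
            for typ in ("high", "low"):
                cells.append(
                    ConditionCell(
                        block_type="two_word",
                        syntactic=syntactic,
                        noun_definiteness=noun_def,
                        noun_specificity=spec,
                        adj_typicality=typ,
                        adj_definiteness=adj_def,
                        word_category="both",
                    )
                )
    for spec in ("high", "low"):
        for definiteness in ("definite", "indefinite"):
            cells.append(
                ConditionCell(
                    block_type="one_word",
                    syntactic="none",
                    noun_definiteness=definiteness,
                    noun_specificity=spec,
                    adj_typicality="none",
                    adj_definiteness="none",
                    word_category="noun",
                )
            )
    for typ in ("high", "low"):
        for definiteness in ("definite", "indefinite"):
            cells.append(
                ConditionCell(
                    block_type="one_word",
                    syntactic="none",
                    noun_definiteness="none",
                    noun_specificity="none",
                    adj_typicality=typ,
                    adj_definiteness=definiteness,
                    word_category="adjective",
                )
            )
    assert len(cells) == 20
    return cells


def _two_word_base_block(cell: ConditionCell) -> int:
    """Base block of a two-word cell before the Latin-square rotation.

    The 12 two-word cells split into 6 word-disjoint pairs: for each syntactic
    level, pairing 0 couples (high-spec noun, high-typ adj) with (low, low)
    and pairing 1 couples (high, low) with (low, high); each pair fills one
    block slot, so the two trials a set contributes to a block never share a
    word token.
    """
    s_idx = SYNTAX_LEVELS.index(cell.syntactic)
    pairing = 0 if (cell.noun_specificity == "high") == (cell.adj_typicality == "high") else 1
    return 2 * s_idx + pairing


def _one_word_base_block(cell: ConditionCell) -> int:
    """Base one-word block: noun cell k is paired with adjective cell k."""
    if cell.word_category == "noun":
        k = ("high", "low").index(cell.noun_specificity) * 2
        k += ("definite", "indefinite").index(cell.noun_definiteness)
    else:
        k = ("high", "low").index(cell.adj_typicality) * 2
        k += ("definite", "indefinite").index(cell.adj_definiteness)
    return k


def _draw_zipf(rng: np.random.Generator) -> float:
    """Zipf frequency (log10 occurrences per billion words), truncated normal."""
    while True:
        z = rng.normal(4.5, 0.7)
        if 1.0 <= z <= 7.0:
            return float(z)


def generate_design(
    n_sets: int = 36, n_participants: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Generate the full factorial trial table for ``n_participants``.

    Parameters
    ----------
    n_sets
        Number of stimulus sets; must be a positive multiple of 12 so the
        cyclic Latin square distributes sets evenly over the 6 two-word and
        4 one-word blocks.  The reference design uses 36.
    n_participants
        Participants to generate; block order, within-block trial order,
        task response times and inter-trial jitter are randomised per
        participant.  Stimulus attributes (word tokens, Zipf frequencies,
        task assignment) are shared across participants.
    seed
        Master seed; regeneration with the same arguments is bit-identical.

    Returns
    -------
    pandas.DataFrame
        One row per trial with factor columns as strings; ``720`` rows per
        participant in the reference design.
    """
    if not isinstance(n_sets, (int, np.integer)) or n_sets <= 0:
        raise ValueError(f"n_sets must be a positive int, got {n_sets!r}")
    if not isinstance(n_participants, (int, np.integer)) or n_participants <= 0:
        raise ValueError(
            f"n_participants must be a positive int, got {n_participants!r}"
        )
    if n_sets % 12 != 0:
        raise DesignInfeasibleError(
            f"n_sets={n_sets} cannot be rotated evenly across 6 two-word and "
            "4 one-word blocks; n_sets must be a multiple of 12"
        )

    ss = np.random.SeedSequence(seed)
    stim_rng = np.random.default_rng(ss.spawn(1)[0])
    participant_seeds = ss.spawn(n_participants + 1)[1:]

    cells = enumerate_set_cells()

    # stimulus attributes, shared across participants
    zipf: dict[str, float] = {}
    for set_id in range(n_sets):
        for kind in ("noun_high", "noun_low", "adj_high", "adj_low"):
            zipf[f"set{set_id:02d}_{kind}"] = _draw_zipf(stim_rng)

    # one static trial list (set x cell) with block assignment and task flags
    base_rows = []
    for set_id in range(n_sets):
        gender = "masc" if set_id < n_sets // 2 else "fem"
        for cell_idx, cell in enumerate(cells):
            if cell.block_type == "two_word":
                block_id = (_two_word_base_block(cell) + set_id) % N_TWO_WORD_BLOCKS
            else:
                block_id = (
                    N_TWO_WORD_BLOCKS
                    + (_one_word_base_block(cell) + set_id) % N_ONE_WORD_BLOCKS
                )
            noun_token = adj_token = ""
            noun_zipf = adj_zipf = np.nan
            if cell.word_category in ("both", "noun"):
                noun_token = f"set{set_id:02d}_noun_{cell.noun_specificity}"
                noun_zipf = zipf[noun_token]
            if cell.word_category in ("both", "adjective"):
                adj_token = f"set{set_id:02d}_adj_{cell.adj_typicality}"
                adj_zipf = zipf[adj_token]
            # round-robin task counterbalancing over cells before shuffling
            is_task = (set_id + cell_idx) % 3 == 0
            base_rows.append(
                {
                    "set_id": set_id,
                    "cell_idx": cell_idx,
                    "block_id": block_id,
                    "block_type": cell.block_type,
                    "syntactic": cell.syntactic,
                    "noun_definiteness": cell.noun_definiteness,
                    "noun_specificity": cell.noun_specificity,
                    "adj_typicality": cell.adj_typicality,
                    "adj_definiteness": cell.adj_definiteness,
                    "word_category": cell.word_category,
                    "gender": gender,
                    "noun_token": noun_token,
                    "adj_token": adj_token,
                    "noun_zipf": noun_zipf,
                    "adj_zipf": adj_zipf,
                    "is_task": is_task,
                }
            )
    base = pd.DataFrame(base_rows)

    # task types: per cell, cycle good/good/gram/plaus over that cell's task
    # sets -> overall 1/2 good, 1/4 grammatical, 1/4 plausibility violations
    base["task_type"] = "none"
    cycle = ["good", "gram_violation", "good", "plaus_violation"]
    for cell_idx in range(len(cells)):
        idx = base.index[(base["cell_idx"] == cell_idx) & base["is_task"]]
        base.loc[idx, "task_type"] = [cycle[i % 4] for i in range(len(idx))]

    frames = []
    for p, pseed in enumerate(participant_seeds):
        prng = np.random.default_rng(pseed)
        rows = base.copy()
        block_order = prng.permutation(N_BLOCKS)
        order = np.concatenate(
            [
                prng.permutation(np.flatnonzero(rows["block_id"].to_numpy() == b))
                for b in block_order
            ]
        )
        rows = rows.iloc[order].reset_index(drop=True)
        rows.insert(0, "participant_id", f"P{p:02d}")

        onsets = np.empty(len(rows))
        t = _CLOCK_START_S
        prev_block = None
        for i, r in enumerate(rows.itertuples(index=False)):
            if prev_block is not None and r.block_id != prev_block:
                t += _BLOCK_BREAK_S
            prev_block = r.block_id
            onsets[i] = t
            dur = 2 * (_ELEMENT_ON_S + _ELEMENT_OFF_S)  # fixation + first word
            if r.block_type == "two_word":
                dur += _ELEMENT_ON_S + _ELEMENT_OFF_S
            if r.is_task:
                dur += prng.uniform(*_TASK_RT_RANGE_S)
            else:
                dur += _ELEMENT_ON_S + _ELEMENT_OFF_S  # continue symbol
            t += dur + prng.uniform(*_JITTER_RANGE_S)
        rows["onset_time_s"] = onsets
        frames.append(rows)

    trials = pd.concat(frames, ignore_index=True)
    trials.insert(0, "trial_id", np.arange(len(trials)))
    return trials.drop(columns="cell_idx")


def augment_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Add the derived analysis columns the model presets reference.

    ``log_onset_time`` (natural log of seconds from experiment start),
    ``word_definiteness``/``word_zipf`` (the single word's attributes in
    one-word trials), and ``noun_type`` (noun specificity in two-word trials,
    'none' for single-word adjectives).
    """
    out = trials.copy()
    if (out["onset_time_s"] <= 0).any():
        raise ValueError("onset_time_s must be positive to take its log")
    out["log_onset_time"] = np.log(out["onset_time_s"].to_numpy())
    is_noun = out["word_category"] == "noun"
    is_adj = out["word_category"] == "adjective"
    out["word_definiteness"] = np.where(
        is_adj, out["adj_definiteness"], out["noun_definiteness"]
    )
    out["word_zipf"] = np.where(is_adj, out["adj_zipf"], out["noun_zipf"])
    out["noun_type"] = np.where(is_adj, "none", out["noun_specificity"])
    return out


class TransitionTable:
    """Conditional distributions P(outcome | context) stored long-form.

    Backed by a DataFrame with columns ``context, outcome, probability``;
    every context's distribution sums to one.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"context", "outcome", "probability"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"transition table missing columns: {sorted(missing)}")
        if (frame["probability"] < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        sums = frame.groupby("context")["probability"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"context distributions do not sum to 1: {bad.to_dict()}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def contexts(self) -> list[str]:
        return sorted(self.frame["context"].unique())

    def distribution(self, context: str) -> pd.Series:
        sub = self.frame[self.frame["context"] == context]
        if sub.empty:
            from .infotheory import MissingContextError

            raise MissingContextError(context)
        return sub.set_index("outcome")["probability"].sort_index()

    def prob(self, context: str, outcome: str) -> float:
        dist = self.distribution(context)
        return float(dist.get(outcome, 0.0))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransitionTable":
        return cls(pd.read_csv(path))


def design_transition_probabilities(
    trials: pd.DataFrame, context: str, outcome: str = "syntactic"
) -> TransitionTable:
    """Empirical P(outcome | context) over the two-word trials of a design.

    Counts are accumulated as exact rationals before the final division, so
    balanced designs give exact probabilities (1, 1/2, 1/3 ...).
    """
    for col in (context, outcome):
        if col not in trials.columns:
            raise ValueError(f"unknown factor {col!r}")
    sub = trials[trials["block_type"] == "two_word"]
    counts: dict[tuple[str, str], int] = {}
    totals: dict[str, int] = {}
    for ctx, out in zip(sub[context], sub[outcome]):
        counts[(ctx, out)] = counts.get((ctx, out), 0) + 1
        totals[ctx] = totals.get(ctx, 0) + 1
    rows = [
        {
            "context": ctx,
            "outcome": out,
            "probability": float(Fraction(c, totals[ctx])),
        }
        for (ctx, out), c in sorted(counts.items())
    ]
    return TransitionTable(pd.DataFrame(rows))


def marginal_probabilities(trials: pd.DataFrame, factor: str) -> pd.Series:
    """Relative frequencies of a factor's levels over two-word trials."""
    if factor not in trials.columns:
        raise ValueError(f"unknown factor {factor!r}")
    sub = trials[trials["block_type"] == "two_word"]
    counts = sub[factor].value_counts().sort_index()
    return counts / counts.sum()
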