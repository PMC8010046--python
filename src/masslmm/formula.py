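"""Fixed-effect design matrices for the nested model comparisons.

A :class:`ModelSpec` lists the fixed-effect terms (factors, covariates, and
interactions; ``a*b`` denotes the full crossing) and the subset that the
reduced model drops (the *variables of interest*).  Factors are coded with
treatment (reference = alphabetically first observed level) or sum-to-zero
contrasts; covariates are z-scored over the trials entering the analysis.
The reduced design matrix is the full matrix minus the columns belonging to
the terms of interest, so the likelihood-ratio degrees of freedom equal the
dropped column count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "DesignInfo",
    "AnalysisPreset",
    "build_design_matrices",
    "PRESETS",
]


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of a full/reduced nested model pair.

    ``fixed`` terms may use ``*`` (full crossing -> mains plus all
    interactions) and ``:`` (interaction only).  ``interest`` names the
    elementary terms absent from the reduced model and must be a subset of
    the expansion of ``fixed``.
    """

    fixed: tuple[str, ...]
    interest: tuple[str, ...]
    group: str = "participant_id"
    coding: str = "treatment"

    def __post_init__(self) -> None:
        if self.coding not in ("treatment", "sum"):
            raise ValueError(f"unknown coding {self.coding!r}")
        expanded = set(expand_terms(self.fixed))
        for term in expand_terms(self.interest):
            if term not in expanded:
                raise ValueError(
                    f"interest term {term!r} is not among the fixed terms"
                )


def _canonical(term: str) -> str:
    parts = term.split(":")
    return ":".join(sorted(p.strip() for p in parts))


def expand_terms(terms: Sequence[str]) -> list[str]:
    """Expand ``*`` crossings and canonicalise interaction component order."""
    out: list[str] = []
    for term in terms:
        if "*" in term:
            factors = [p.strip() for p in term.split("*")]
            for r in range(1, len(factors) + 1):
                for combo in itertools.combinations(factors, r):
                    c = _canonical(":".join(combo))
                    if c not in out:
                        out.append(c)
        else:
            c = _canonical(term)
            if c not in out:
                out.append(c)
    return out


class _FactorCoding:
    """Level coding for one factor, reusable on new (grid) data."""

    def __init__(self, name: str, levels: list[str], coding: str):
        if len(levels) < 2:
            raise ValueError(
                f"factor {name!r} needs >=2 observed levels, got {levels}"
            )
        self.name = name
        self.levels = levels
        self.coding = coding

    @property
    def n_columns(self) -> int:
        return len(self.levels) - 1

    def column_names(self) -> list[str]:
        if self.coding == "treatment":
            return [f"{self.name}[{lv}]" for lv in self.levels[1:]]
        return [f"{self.name}[S.{lv}]" for lv in self.levels[:-1]]

    def encode(self, values: np.ndarray) -> np.ndarray:
        unknown = set(values) - set(self.levels)
        if unknown:
            raise ValueError(
                f"factor {self.name!r} has unknown level(s) {sorted(unknown)}"
            )
        out = np.zeros((len(values), self.n_columns))
        if self.coding == "treatment":
            for j, lv in enumerate(self.levels[1:]):
                out[:, j] = values == lv
        else:
            for j, lv in enumerate(self.levels[:-1]):
                out[:, j] = values == lv
            out[values == self.levels[-1], :] = -1.0
        return out


class _CovariateScaling:
    """Global z-scoring of a numeric covariate."""

    def __init__(self, name: str, mean: float, sd: float):
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"covariate {name!r} is constant or non-finite")
        self.name = name
        self.mean = mean
        self.sd = sd

    def encode(self, values: np.ndarray) -> np.ndarray:
        return ((values - self.mean) / self.sd)[:, None]


@dataclass
class DesignInfo:
    """Built full and reduced fixed-effect matrices plus their metadata."""

    full: np.ndarray
    reduced: np.ndarray
    columns: list[str]
    term_columns: dict[str, list[int]]  # term -> column indices in `full`
    interest_columns: list[int]
    groups: np.ndarray  # integer participant codes, aligned to rows
    group_labels: list[str]
    spec: ModelSpec
    _factors: dict = field(default_factory=dict, repr=False)
    _covariates: dict = field(default_factory=dict, repr=False)
    _terms: list[str] = field(default_factory=list, repr=False)

    @property
    def df_interest(self) -> int:
        return self.full.shape[1] - self.reduced.shape[1]

    def encode_rows(self, data: pd.DataFrame) -> np.ndarray:
        """Encode new rows (e.g. a reference grid) with the stored codings."""
        return _assemble(data, self._terms, self._factors, self._covariates)[0]


def _term_matrix(
    data: pd.DataFrame, term: str, factors: dict, covariates: dict
) -> tuple[np.ndarray, list[str]]:
    mats, names = [], []
    for var in term.split(":"):
        if var in factors:
            enc = factors[var]
            mats.append(enc.encode(data[var].astype(str).to_numpy()))
            names.append(enc.column_names())
        else:
            sc = covariates[var]
            mats.append(sc.encode(data[var].to_numpy(dtype=float)))
            names.append([var])
    # column-wise Kronecker over the term's components
    mat = mats[0]
    cols = names[0]
    for m, nm in zip(mats[1:], names[1:]):
        mat = np.einsum("ij,ik->ijk", mat, m).reshape(len(data), -1)
        cols = [f"{a}:{b}" for a in cols for b in nm]
    return mat, cols


def _assemble(
    data: pd.DataFrame, terms: list[str], factors: dict, covariates: dict
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    blocks = [np.ones((len(data), 1))]
    columns = ["Intercept"]
    term_columns: dict[str, list[int]] = {}
    for term in terms:
        mat, cols = _term_matrix(data, term, factors, covariates)
        start = sum(b.shape[1] for b in blocks)
        term_columns[term] = list(range(start, start + mat.shape[1]))
        blocks.append(mat)
        columns.extend(cols)
    return np.column_stack(blocks), columns, term_columns


def build_design_matrices(trials: pd.DataFrame, spec: ModelSpec) -> DesignInfo:
    """Build the full and reduced fixed-effect matrices for one analysis.

    Raises on missing variables, single-level or partially unobserved
    factors, NaNs in the used columns, rank deficiency (naming the aliased
    columns), and more columns than trials.
    """
    terms = expand_terms(spec.fixed)
    interest = expand_terms(spec.interest)
    variables = sorted({v for t in terms for v in t.split(":")})
    for var in variables + [spec.group]:
        if var not in trials.columns:
            raise ValueError(f"term variable {var!r} not in trial table")

    factors: dict[str, _FactorCoding] = {}
    covariates: dict[str, _CovariateScaling] = {}
    for var in variables:
        col = trials[var]
        if isinstance(col.dtype, pd.CategoricalDtype):
            observed = set(col.astype(str))
            unused = [c for c in col.cat.categories.astype(str) if c not in observed]
            if unused:
                raise ValueError(
                    f"factor {var!r} has unobserved level(s) {unused}"
                )
            factors[var] = _FactorCoding(var, sorted(observed), spec.coding)
        elif col.dtype == object or col.dtype == bool:
            if col.isna().any():
                raise ValueError(f"factor {var!r} contains missing values")
            levels = sorted(col.astype(str).unique())
            factors[var] = _FactorCoding(var, levels, spec.coding)
        else:
            x = col.to_numpy(dtype=float)
            if not np.isfinite(x).all():
                raise ValueError(f"covariate {var!r} contains non-finite values")
            covariates[var] = _CovariateScaling(var, float(x.mean()), float(x.std()))

    full, columns, term_columns = _assemble(trials, terms, factors, covariates)
    interest_cols = sorted(
        itertools.chain.from_iterable(term_columns[t] for t in interest)
    )
    keep = [j for j in range(full.shape[1]) if j not in set(interest_cols)]
    reduced = full[:, keep]

    n, p = full.shape
    if n < p:
        raise ValueError(f"fewer trials ({n}) than fixed-effect columns ({p})")
    rank = np.linalg.matrix_rank(full)
    if rank < p:
        _, r = np.linalg.qr(full)
        diag = np.abs(np.diag(r))
        aliased = [columns[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    labels = sorted(pd.unique(trials[spec.group].astype(str)))
    code = {lab: i for i, lab in enumerate(labels)}
    groups = trials[spec.group].astype(str).map(code).to_numpy(dtype=np.int64)

    return DesignInfo(
        full=full,
        reduced=reduced,
        columns=columns,
        term_columns=term_columns,
        interest_columns=interest_cols,
        groups=groups,
        group_labels=labels,
        spec=spec,
        _factors=factors,
        _covariates=covariates,
        _terms=terms,
    )


@dataclass(frozen=True)
class AnalysisPreset:
    """A named analysis: model spec, test window, and trial subset."""

    name: str
    spec: ModelSpec
    window: tuple[float, float]
    description: str

    def subset_mask(self, trials: pd.DataFrame) -> np.ndarray:
        two = (trials["block_type"] == "two_word").to_numpy()
        cat = trials["word_category"].to_numpy()
        if self.name in ("syntactic-complexity", "noun-definiteness"):
            return two
        if self.name == "block-definiteness":
            return two | (cat == "noun")
        if self.name == "single-word":
            return ~two
        if self.name == "composition":
            return two | (cat == "adjective")
        raise ValueError(f"no subset rule for preset {self.name!r}")


_COMMON = ("noun_zipf", "adj_zipf", "log_onset_time")

PRESETS: dict[str, AnalysisPreset] = {
    # two-word trials, adjective window: 3-level structure factor, chi2(2)
    "syntactic-complexity": AnalysisPreset(
        "syntactic-complexity",
        ModelSpec(
            fixed=("syntactic", "noun_specificity*adj_typicality") + _COMMON,
            interest=("syntactic",),
        ),
        (0.700, 1.100),
        "syntactic structure (3 levels) on two-word trials, adjective window",
    ),
    # two-word trials, noun window: binary noun definiteness, chi2(1)
    "noun-definiteness": AnalysisPreset(
        "noun-definiteness",
        ModelSpec(
            fixed=("noun_definiteness", "noun_specificity*adj_typicality") + _COMMON,
            interest=("noun_definiteness",),
        ),
        (0.100, 0.500),
        "noun definiteness on two-word trials, noun window",
    ),
    # two-word + single-noun trials: block x definiteness crossing, chi2(3)
    "block-definiteness": AnalysisPreset(
        "block-definiteness",
        ModelSpec(
            fixed=(
                "block_type*noun_definiteness",
                "noun_specificity",
                "noun_zipf",
                "log_onset_time",
            ),
            interest=(
                "block_type",
                "noun_definiteness",
                "block_type:noun_definiteness",
            ),
        ),
        (0.100, 0.500),
        "block type x noun definiteness, two-word plus single-noun trials",
    ),
    # single-word trials: word category x definiteness crossing, chi2(3)
    "single-word": AnalysisPreset(
        "single-word",
        ModelSpec(
            fixed=(
                "word_category*word_definiteness",
                "word_zipf",
                "log_onset_time",
            ),
            interest=(
                "word_category",
                "word_definiteness",
                "word_category:word_definiteness",
            ),
        ),
        (0.100, 0.500),
        "word category x definiteness on single-word trials",
    ),
    # two-word + single-adjective trials: 3 x 2 x 2 crossing, chi2(11)
    "composition": AnalysisPreset(
        "composition",
        ModelSpec(
            fixed=(
                "noun_type*adj_typicality*adj_definiteness",
                "adj_zipf",
                "log_onset_time",
            ),
            interest=("noun_type*adj_typicality*adj_definiteness",),
        ),
        (0.750, 0.950),
        "noun type x adjective typicality x adjective definiteness, "
        "two-word plus single-adjective trials",
    ),
}
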