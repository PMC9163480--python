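"""Behavior-transition counting, independence testing, Markov estimation.

The transition matrix has one row per source state (proximity plus the
seven physical behaviors) and one column per target state (the same set
plus the absorbing ``end``).  Each ordered adjacent pair of states within a
bout increments one cell; runs of the same behavior are collapsed to one
state by default, which makes the diagonal structurally zero.

Cell-wise significance uses Haberman adjusted standardized residuals,

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - R_i/N) (1 - C_j/N)),

which are approximately standard normal under independence; a seeded
permutation alternative (targets resampled from the column marginals,
row sums fixed) is available for small tables.  Structural zeros are
excluded from testing.  Transition probabilities are the row-normalized
maximum-likelihood estimates; rows never observed as a source are flagged
undefined rather than silently uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .event_log import Bout, SOURCE_STATES, TARGET_STATES


@dataclass
class TransitionMatrix:
    """Labeled count matrix of behavior-to-behavior transitions."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: np.ndarray  # shape (n_rows, n_cols), non-negative ints
    collapse_repeats: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    def structural_zero_mask(self) -> np.ndarray:
        """Boolean mask of cells impossible by construction (self-loops)."""
        mask = np.zeros(self.counts.shape, dtype=bool)
        if self.collapse_repeats:
            for i, rl in enumerate(self.row_labels):
                for j, cl in enumerate(self.col_labels):
                    if rl == cl:
                        mask[i, j] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass
class ResidualTable:
    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    adjusted_residual: np.ndarray  # NaN where untested/undefined
    significant: np.ndarray        # bool
    alpha: float
    tested: np.ndarray             # bool: cells included in the test
    method: str = "adjusted_residual"

    def cell(self, source: str, target: str) -> Tuple[float, float, bool]:
        i = self.row_labels.index(source)
        j = self.col_labels.index(target)
        return (float(self.expected[i, j]), float(self.adjusted_residual[i, j]),
                bool(self.significant[i, j]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rl in enumerate(self.row_labels):
            for j, cl in enumerate(self.col_labels):
                rows.append({
                    "source": rl, "target": cl,
                    "observed": int(self.observed[i, j]),
                    "expected": float(self.expected[i, j]),
                    "residual": float(self.adjusted_residual[i, j]),
                    "tested": bool(self.tested[i, j]),
                    "significant": bool(self.significant[i, j]),
                })
        return pd.DataFrame(rows)


@dataclass
class MarkovModel:
    """Row-stochastic MLE of the behavior transition chain."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    prob: np.ndarray          # NaN rows where undefined
    defined: np.ndarray       # bool per row: had >= 1 outgoing transition
    row_totals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def p(self, source: str, target: str) -> float:
        return float(self.prob[self.row_labels.index(source),
                               self.col_labels.index(target)])

    def modal_target(self, source: str) -> Optional[str]:
        i = self.row_labels.index(source)
        if not self.defined[i]:
            return None
        return self.col_labels[int(np.nanargmax(self.prob[i]))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.prob, index=list(self.row_labels),
                            columns=list(self.col_labels))


def count_transitions(bouts: Sequence[Bout], collapse_repeats: bool = True,
                      row_labels: Sequence[str] = SOURCE_STATES,
                      col_labels: Sequence[str] = TARGET_STATES) -> TransitionMatrix:
    """Count ordered adjacent state pairs over all bouts.

    With ``collapse_repeats`` a run of identical behaviors counts as a
    single state, so self-transitions never occur.  Transitions into
    ``end`` are counted; ``end`` has no outgoing transitions.
    """
    ridx = {l: i for i, l in enumerate(row_labels)}
    cidx = {l: j for j, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for bout in bouts:
        states = list(bout.behaviors)
        if collapse_repeats:
            states = [s for k, s in enumerate(states) if k == 0 or s != states[k - 1]]
        for a, b in zip(states, states[1:]):
            if a == "end":
                continue  # absorbing: nothing follows an end
            counts[ridx[a], cidx[b]] += 1
    return TransitionMatrix(tuple(row_labels), tuple(col_labels), counts,
                            collapse_repeats=collapse_repeats)


def pool_matrices(per_trial: Sequence[TransitionMatrix]) -> TransitionMatrix:
    """Elementwise sum of per-trial matrices with identical labels."""
    if not per_trial:
        raise ValueError("cannot pool an empty list of matrices")
    first = per_trial[0]
    for m in per_trial[1:]:
        if m.row_labels != first.row_labels or m.col_labels != first.col_labels:
            diff = (set(m.row_labels) ^ set(first.row_labels)) | \
                   (set(m.col_labels) ^ set(first.col_labels))
            raise ValueError(f"label mismatch between matrices: {sorted(diff)}")
        if m.collapse_repeats != first.collapse_repeats:
            raise ValueError("mixed collapse_repeats policies cannot be pooled")
    total = np.sum([m.counts for m in per_trial], axis=0)
    return TransitionMatrix(first.row_labels, first.col_labels, total,
                            collapse_repeats=first.collapse_repeats)


def independence_residuals(m: TransitionMatrix, alpha: float = 0.05,
                           method: str = "adjusted_residual",
                           n_permutations: int = 1000,
                           rng: Optional[np.random.Generator] = None,
                           bonferroni: bool = False) -> ResidualTable:
    """Test each transition cell against the row/column independence null.

    ``method="adjusted_residual"`` flags cells whose Haberman adjusted
    standardized residual exceeds the two-sided normal critical value at
    ``alpha``.  ``method="permutation"`` instead resamples each row's
    targets from the pooled column-marginal distribution (row sums fixed,
    seeded via ``rng``) and uses the two-sided permutation p-value of
    ``|O - E|``.  Structurally-zero cells (self-transitions under repeat
    collapsing) are never tested.  Cells with zero expected count are
    flagged not-significant with a warning.

    With ``bonferroni=True`` the alpha is divided by the number of tested
    cells.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    N = m.n_transitions
    if N == 0:
        raise ValueError("cannot test an empty transition matrix")
    O = m.counts.astype(float)
    R = O.sum(axis=1, keepdims=True)
    C = O.sum(axis=0, keepdims=True)
    E = R @ C / N

    structural = m.structural_zero_mask()
    tested = ~structural
    n_tested = int(tested.sum())
    alpha_eff = alpha / n_tested if bonferroni else alpha

    resid = np.full(O.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(E * (1.0 - R / N) * (1.0 - C / N))
        ok = tested & (denom > 0)
        resid[ok] = (O[ok] - E[ok]) / denom[ok]
    undefined = tested & ~ok
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} tested cell(s) have zero expected "
                      "count; flagged not-significant", stacklevel=2)

    if method == "adjusted_residual":
        z_crit = stats.norm.ppf(1.0 - alpha_eff / 2.0)
        significant = np.zeros(O.shape, dtype=bool)
        significant[ok] = np.abs(resid[ok]) > z_crit
    elif method == "permutation":
        rng = rng if rng is not None else np.random.default_rng()
        p_col = (C / N).ravel()
        row_sums = R.ravel().astype(int)
        exceed = np.zeros(O.shape, dtype=np.int64)
        obs_dev = np.abs(O - E)
        for _ in range(n_permutations):
            sim = np.vstack([rng.multinomial(n, p_col) for n in row_sums]).astype(float)
            exceed += np.abs(sim - E) >= obs_dev - 1e-12
        pvals = (exceed + 1.0) / (n_permutations + 1.0)
        significant = np.zeros(O.shape, dtype=bool)
        significant[ok] = pvals[ok] <= alpha_eff
    else:
        raise ValueError(f"unknown method {method!r}")

    return ResidualTable(m.row_labels, m.col_labels, m.counts.copy(), E, resid,
                         significant, alpha, tested, method=method)


def pearson_chi_square(table: ResidualTable) -> float:
    """Pearson chi-square statistic over the tested cells with E > 0."""
    ok = table.tested & (table.expected > 0)
    O = table.observed[ok].astype(float)
    E = table.expected[ok]
    return float(np.sum((O - E) ** 2 / E))


def fit_markov(m: TransitionMatrix) -> MarkovModel:
    """Maximum-likelihood transition probabilities (row-normalized counts)."""
    if m.n_transitions == 0:
        raise ValueError("cannot fit a Markov model to an empty matrix")
    counts = m.counts.astype(float)
    row_tot = counts.sum(axis=1)
    defined = row_tot > 0
    prob = np.full(counts.shape, np.nan)
    prob[defined] = counts[defined] / row_tot[defined, None]
    return MarkovModel(m.row_labels, m.col_labels, prob, defined, row_tot)


def first_round_pool(bouts_by_trial, trials, rounds: Sequence[int] = (1,),
                     collapse_repeats: bool = True) -> TransitionMatrix:
    """Pool per-trial transition matrices over the selected trial rounds.

    Pooling only round-1 trials (the default) avoids pseudoreplication
    from each female appearing in all three rounds.
    """
    by_id = {t.trial_id: t for t in trials}
    selected = []
    for trial_id, bouts in bouts_by_trial.items():
        t = by_id.get(trial_id)
        if t is not None and t.trial_round in rounds:
            selected.append(count_transitions(bouts, collapse_repeats=collapse_repeats))
    if not selected:
        raise ValueError(f"no trials found for rounds {list(rounds)}")
    return pool_matrices(selected)


__all__ = [
    "TransitionMatrix", "ResidualTable", "MarkovModel", "count_transitions",
    "pool_matrices", "independence_residuals", "pearson_chi_square",
    "fit_markov", "first_round_pool",
]
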