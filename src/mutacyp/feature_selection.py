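"""F-score feature ranking with a Pearson-correlation redundancy filter.

A candidate feature is scored by its between-class separation

    F = |x̄_n - x̄_d| / (σ_n + σ_d)

where x̄_n, σ_n and x̄_d, σ_d are the mean and sample standard deviation of
the feature over neutral (benign) and deleterious mutations. Candidates
with F below a threshold (default 0.4) are dropped; survivors are admitted
greedily in order of descending F, skipping any candidate whose absolute
Pearson correlation with an already-admitted feature reaches the redundancy
cap (default 0.8). The greedy descending-F order is this package's
reconstruction of the inclusion procedure; it reproduces the published
outcome that raw entropy (F = 0.66) is excluded through its |r| = 0.82
anticorrelation with Abs_dSS while all five final features survive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profile_io import BENIGN, DELETERIOUS


@dataclass(frozen=True)
class SelectionConfig:
    f_min: float = 0.4
    r_max: float = 0.8  # applied to |r|

    def __post_init__(self) -> None:
        if self.f_min < 0:
            raise ValueError("f_min must be nonnegative")
        if not 0 < self.r_max <= 1:
            raise ValueError("r_max must lie in (0, 1]")


@dataclass
class SelectionReport:
    """Outcome of the inclusion procedure with per-rejection reasons."""

    f_scores: dict[str, float]
    correlations: pd.DataFrame
    kept: list[str]
    rejected: dict[str, str]  # feature -> reason

    def __post_init__(self) -> None:
        all_feats = set(self.kept) | set(self.rejected)
        if all_feats != set(self.f_scores):
            raise ValueError("kept ∪ rejected must equal the candidate set")


def f_score(values_neutral: Sequence[float], values_deleterious: Sequence[float]) -> float:
    """Discriminatory power |x̄_n - x̄_d| / (σ_n + σ_d), sample σ.

    Zero pooled spread with equal means is 0; with unequal means it is
    +inf (infinite separation — such a feature is always kept).
    """
    xn = np.asarray(values_neutral, dtype=float)
    xd = np.asarray(values_deleterious, dtype=float)
    if xn.size < 2 or xd.size < 2:
        raise ValueError("each class needs at least 2 values")
    num = abs(xn.mean() - xd.mean())
    denom = xn.std(ddof=1) + xd.std(ddof=1)
    if denom == 0.0:
        return 0.0 if num == 0.0 else math.inf
    return float(num / denom)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on zero variance."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("samples must have equal length")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = math.sqrt(float(xc @ xc)) * math.sqrt(float(yc @ yc))
    if denom == 0.0:
        raise ValueError("correlation undefined: zero variance in a sample")
    return float((xc @ yc) / denom)


def apply_inclusion_criteria(
    f_scores: Mapping[str, float],
    correlations: pd.DataFrame,
    cfg: SelectionConfig = SelectionConfig(),
) -> SelectionReport:
    """Run the inclusion procedure on precomputed F-scores and correlations.

    Useful both internally and for auditing published summary statistics.
    ``correlations`` must be a symmetric feature-by-feature frame (only the
    entries among surviving candidates are consulted).
    """
    fmap = {k: abs(v) for k, v in f_scores.items()}
    rejected: dict[str, str] = {}
    survivors = []
    for name, f in fmap.items():
        if f < cfg.f_min:
            rejected[name] = f"below f_min ({f:.3g} < {cfg.f_min:g})"
        else:
            survivors.append(name)
    # descending |F|, ties broken lexicographically
    survivors.sort(key=lambda n: (-fmap[n], n))
    kept: list[str] = []
    for name in survivors:
        clash = None
        for prev in kept:
            r = abs(float(correlations.loc[name, prev]))
            if r >= cfg.r_max:
                clash = (prev, r)
                break
        if clash is None:
            kept.append(name)
        else:
            rejected[name] = (
                f"redundant with {clash[0]} (|r| = {clash[1]:.3g} >= {cfg.r_max:g})"
            )
    return SelectionReport(
        f_scores=fmap, correlations=correlations, kept=kept, rejected=rejected
    )


def select_features(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    cfg: SelectionConfig = SelectionConfig(),
    *,
    within_class_correlation: bool = False,
) -> SelectionReport:
    """Score every column of ``matrix`` and apply the inclusion procedure.

    ``labels`` hold 'benign'/'deleterious' per row. Correlations are pooled
    over both classes by default; ``within_class_correlation`` averages the
    two class-conditional correlation matrices instead.
    """
    lab = np.asarray(labels)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    is_del = lab == DELETERIOUS
    is_ben = lab == BENIGN
    if not is_del.any() or not is_ben.any():
        raise ValueError("both classes must be present in the labels")
    fscores = {
        col: f_score(matrix.loc[is_ben, col], matrix.loc[is_del, col])
        for col in matrix.columns
    }
    if within_class_correlation:
        corr = (matrix[is_del].corr() + matrix[is_ben].corr()) / 2.0
    else:
        corr = matrix.corr()
    return apply_inclusion_criteria(fscores, corr, cfg)


def mcc_subset_search(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    *,
    seed: int = 0,
    max_candidates: int = 15,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive subset search maximizing 5-fold-CV MCC of an LDA model.

    Mirrors the model-driven stage of feature selection: every non-empty
    subset of up to ``max_candidates`` columns is scored by the mean test
    MCC of a cross-validated linear discriminant, and the best subset is
    returned with its score. Exponential in the candidate count, hence the
    hard cap.
    """
    from .evaluation import cross_validate

    cols = list(matrix.columns)
    if len(cols) > max_candidates:
        raise ValueError(
            f"subset search capped at {max_candidates} candidates, got {len(cols)}"
        )
    best: tuple[tuple[str, ...], float] = ((), -math.inf)
    for k in range(1, len(cols) + 1):
        for subset in itertools.combinations(cols, k):
            cv = cross_validate(
                matrix[list(subset)], labels, model="lda", seed=seed
            )
            score = cv.mean_test_mcc
            if score > best[1]:
                best = (subset, score)
    return best
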