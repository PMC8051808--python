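"""Model-accuracy evaluation against observed binary events.

Predicted event probabilities are coded to yes/no at a cut-off, tallied into
a 2x2 confusion table against the observed labels, and scored with:

* Pearson chi-square (no continuity correction) and its df=1 upper-tail p,
* the minimum-P-value (maximum chi-square) optimum cut-off over a grid,
* error rate (fp + fn) / n,
* true skill statistic TSS = sensitivity + specificity - 1,
* a non-parametric (empirical) ROC curve whose trapezoidal area equals the
  Mann-Whitney probability that a random positive outranks a random negative
  (ties counting one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2_dist


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; the statistic is undefined."""


@dataclass(frozen=True)
class PredictionSet:
    """Paired (predicted probability of the positive state, observed 0/1 label)."""

    probabilities: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if probs.ndim != 1 or labels.shape != probs.shape:
            raise ValueError("probabilities and labels must be equal-length vectors")
        if probs.size == 0:
            raise ValueError("PredictionSet must contain at least one case")
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return int(self.probabilities.size)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion counts must be nonnegative integers")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise DegenerateTableError("no observed positives")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise DegenerateTableError("no observed negatives")
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def confusion_at_cutoff(preds: PredictionSet, cutoff: float) -> ConfusionTable:
    """Code predicted-positive iff probability >= cutoff and tally against labels."""
    if not (0.0 <= cutoff <= 1.0 + 1e-12):
        raise ValueError("cutoff must lie in [0, 1]")
    predicted = preds.probabilities >= cutoff
    observed = preds.labels.astype(bool)
    return ConfusionTable(
        tp=int(np.sum(predicted & observed)),
        fp=int(np.sum(predicted & ~observed)),
        fn=int(np.sum(~predicted & observed)),
        tn=int(np.sum(~predicted & ~observed)),
    )


def pearson_chi2_2x2(table: ConfusionTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, and its df=1 p-value.

        chi2 = n (tn*tp - fp*fn)^2 / ((tn+fp)(fn+tp)(tn+fn)(fp+tp))

    Raises :class:`DegenerateTableError` when any margin is zero (the
    statistic is undefined there, not NaN).
    """
    margins = (
        table.tn + table.fp,
        table.fn + table.tp,
        table.tn + table.fn,
        table.fp + table.tp,
    )
    if table.n == 0 or any(m == 0 for m in margins):
        raise DegenerateTableError(f"zero margin in table {table}")
    num = table.n * (table.tn * table.tp - table.fp * table.fn) ** 2
    chi2 = num / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(_chi2_dist.sf(chi2, df=1))
    return float(chi2), p


def error_rate(table: ConfusionTable) -> float:
    """Fraction of wrong predictions, (fp + fn) / n."""
    if table.n == 0:
        raise ValueError("empty table")
    return (table.fp + table.fn) / table.n


def true_skill_statistic(table: ConfusionTable) -> float:
    """TSS = sensitivity + specificity - 1, in [-1, 1].

    Requires both observed classes; otherwise the score is undefined and a
    :class:`DegenerateTableError` is raised.
    """
    return table.sensitivity + table.specificity - 1.0


DEFAULT_CUTOFF_GRID = tuple(c / 100 for c in range(1, 97))


@dataclass
class CutoffProfile:
    """Chi-square profile over a cut-off grid, with degenerate points flagged."""

    cutoffs: list[float]
    chi2: list[float | None]
    p_values: list[float | None]

    def as_rows(self):
        return list(zip(self.cutoffs, self.chi2, self.p_values))


def select_optimum_cutoff(
    preds: PredictionSet, grid=DEFAULT_CUTOFF_GRID
) -> tuple[float, CutoffProfile]:
    """Smallest grid cut-off attaining the maximum chi-square (minimum p-value).

    Degenerate cut-offs (a zero table margin, e.g. nothing predicted positive)
    are recorded as ``None`` in the profile and never selected; if every grid
    point is degenerate the selection fails explicitly.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("cut-off grid is empty")
    chi2s: list[float | None] = []
    ps: list[float | None] = []
    for cutoff in grid:
        table = confusion_at_cutoff(preds, cutoff)
        try:
            c, p = pearson_chi2_2x2(table)
        except DegenerateTableError:
            c, p = None, None
        chi2s.append(c)
        ps.append(p)
    profile = CutoffProfile(cutoffs=grid, chi2=chi2s, p_values=ps)

    best = None
    for cutoff, c in zip(grid, chi2s):
        if c is None:
            continue
        if best is None or c > best[1] + 1e-12:
            best = (cutoff, c)
    if best is None:
        raise DegenerateTableError(
            "chi-square is undefined at every grid cut-off "
            "(single-class labels or empty grid)"
        )
    return best[0], profile


@dataclass
class RocCurve:
    """Empirical ROC: (1 - specificity, sensitivity) per threshold, plus area."""

    points: list[tuple[float, float]]
    area: float
    thresholds: list[float] = field(default_factory=list)


def roc_auc(preds: PredictionSet) -> RocCurve:
    """Non-parametric ROC over all distinct prediction values.

    The trapezoidal area equals the probability that a random positive is
    ranked above a random negative, with ties counting one half (the
    Mann-Whitney statistic). Both observed classes must be present.
    """
    labels = preds.labels
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTableError("ROC requires both observed classes")

    thresholds = sorted(set(preds.probabilities), reverse=True)
    points = [(0.0, 0.0)]
    for t in thresholds:
        table = confusion_at_cutoff(preds, t)
        points.append((1.0 - table.specificity, table.sensitivity))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))

    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    area = float(np.trapezoid(ys, xs))
    return RocCurve(points=points, area=area, thresholds=[float(t) for t in thresholds])
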