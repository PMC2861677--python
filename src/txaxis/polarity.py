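"""Pathway-level summaries of differential-expression calls.

The net direction of regulation of a pathway is the number of
up-regulated minus down-regulated member transcripts, expressed as a
percentage of *all* regulated genes in the study (pathway members or
not).  Stacking these scores across studies gives a pathway-by-study
matrix on which the transcriptional axis is quantified: pathways are
ordered by the Pearson correlation of their score row with the
reference (OXPHOS) row, and the axis fraction is the share of pathways
whose correlation with the reference is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import GeneSetCollection
from .sam import DECallSet

__all__ = [
    "PathwayPolarityProfile",
    "PathwayStudyMatrix",
    "UndefinedCorrelationError",
    "net_regulation",
    "stack_profiles",
    "sort_by_reference_similarity",
    "axis_fraction",
    "cross_study_correlation",
    "plot_pathway_study_heatmap",
]

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A correlation is requested for a zero-variance score row."""


@dataclass(frozen=True)
class PathwayPolarityProfile:
    """Per-pathway net-direction-of-regulation scores for one comparison.

    ``net_scores[p] = 100 * (n_up[p] - n_down[p]) / total_regulated``
    (0 when nothing is regulated study-wide), so scores lie in
    [-100, +100] percent.
    """

    pathway_names: tuple[str, ...]
    net_scores: np.ndarray
    n_up: np.ndarray
    n_down: np.ndarray
    total_regulated: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_names", tuple(self.pathway_names))
        object.__setattr__(self, "net_scores", np.asarray(self.net_scores, dtype=float))
        object.__setattr__(self, "n_up", np.asarray(self.n_up, dtype=int))
        object.__setattr__(self, "n_down", np.asarray(self.n_down, dtype=int))
        n = len(self.pathway_names)
        if not (len(self.net_scores) == len(self.n_up) == len(self.n_down) == n):
            raise ValueError("per-pathway arrays have inconsistent lengths")
        if self.total_regulated < 0:
            raise ValueError("total_regulated must be nonnegative")
        if np.any(np.abs(self.net_scores) > 100 + 1e-9):
            raise ValueError("net scores must lie in [-100, 100]")

    def score(self, pathway: str) -> float:
        return float(self.net_scores[self.pathway_names.index(pathway)])


@dataclass(frozen=True)
class PathwayStudyMatrix:
    """Net-regulation scores stacked pathway-by-study."""

    pathway_names: tuple[str, ...]
    study_ids: tuple[str, ...]
    scores: np.ndarray
    reference_name: str = "OXPHOS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pathway_names", tuple(self.pathway_names))
        object.__setattr__(self, "study_ids", tuple(self.study_ids))
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.shape != (len(self.pathway_names), len(self.study_ids)):
            raise ValueError("score matrix shape mismatch")
        if np.any(np.abs(scores) > 100 + 1e-9):
            raise ValueError("scores must lie in [-100, 100]")
        if self.reference_name not in self.pathway_names:
            raise ValueError(f"reference pathway {self.reference_name!r} missing")

    @property
    def n_studies(self) -> int:
        return len(self.study_ids)

    def row(self, pathway: str) -> np.ndarray:
        return self.scores[self.pathway_names.index(pathway)]


def net_regulation(calls: DECallSet, sets: GeneSetCollection) -> PathwayPolarityProfile:
    """Net direction of regulation per pathway for one comparison.

    Counts the called-up and called-down genes inside each pathway and
    normalizes their difference by the total number of regulated genes
    study-wide (members of any pathway or none).  Pathway genes absent
    from the call set's gene universe are ignored (logged).
    """
    universe = set(calls.gene_ids)
    unknown = sum(len(members - universe) for members in sets.sets.values())
    if unknown:
        logger.info("%d pathway gene IDs not in the study's gene universe", unknown)
    up = calls.called_genes("up")
    down = calls.called_genes("down")
    total = len(up) + len(down)
    names = sets.names
    n_up = np.array([len(sets[p] & up) for p in names], dtype=int)
    n_down = np.array([len(sets[p] & down) for p in names], dtype=int)
    if total > 0:
        scores = 100.0 * (n_up - n_down) / total
    else:
        scores = np.zeros(len(names))
    return PathwayPolarityProfile(
        pathway_names=names,
        net_scores=scores,
        n_up=n_up,
        n_down=n_down,
        total_regulated=total,
    )


def stack_profiles(
    profiles: Sequence[PathwayPolarityProfile],
    study_ids: Sequence[str],
    reference_name: str = "OXPHOS",
) -> PathwayStudyMatrix:
    """Stack per-study polarity profiles into a pathway-by-study matrix.

    All profiles must share the same pathway list (same collection).
    """
    if len(profiles) != len(study_ids):
        raise ValueError("one study ID per profile required")
    if not profiles:
        raise ValueError("no profiles to stack")
    names = profiles[0].pathway_names
    for p in profiles[1:]:
        if p.pathway_names != names:
            raise ValueError("profiles have differing pathway lists")
    scores = np.column_stack([p.net_scores for p in profiles])
    return PathwayStudyMatrix(names, tuple(study_ids), scores, reference_name)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution on n-2 df); requires variance."""
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def sort_by_reference_similarity(
    matrix: PathwayStudyMatrix,
) -> list[tuple[str, float]]:
    """Order pathways by Pearson similarity of their score row to the reference.

    The reference pathway comes first with r = 1; remaining pathways
    follow by descending correlation, ties broken alphabetically.
    Zero-variance rows have undefined correlation (recorded as NaN) and
    sort last, alphabetically among themselves.
    """
    if matrix.n_studies < 3:
        raise ValueError("similarity ordering needs at least 3 studies")
    ref = matrix.row(matrix.reference_name)
    if np.std(ref) == 0:
        raise UndefinedCorrelationError("reference row has zero variance")
    defined: list[tuple[str, float]] = []
    undefined: list[str] = []
    for name in matrix.pathway_names:
        if name == matrix.reference_name:
            continue
        row = matrix.row(name)
        if np.std(row) == 0:
            undefined.append(name)
            logger.info("pathway %r has zero score variance; similarity undefined", name)
            continue
        r, _ = _pearson(row, ref)
        defined.append((name, r))
    defined.sort(key=lambda t: (-t[1], t[0]))
    ordered = [(matrix.reference_name, 1.0)] + defined
    ordered += [(name, float("nan")) for name in sorted(undefined)]
    return ordered


def axis_fraction(matrix: PathwayStudyMatrix, alpha: float = 0.05) -> float:
    """Fraction of non-reference pathways significantly correlated with the reference.

    Significance is a two-sided Pearson test (t on n-2 df) at level
    ``alpha`` across studies.  Rows with undefined correlation count as
    not significant.  This is the quantity behind the claim that most
    pathway-level regulation moves along the OXPHOS axis.
    """
    if matrix.n_studies < 4:
        raise ValueError("axis fraction needs at least 4 studies")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ref = matrix.row(matrix.reference_name)
    if np.std(ref) == 0:
        raise UndefinedCorrelationError("reference row has zero variance")
    others = [n for n in matrix.pathway_names if n != matrix.reference_name]
    if not others:
        raise ValueError("no non-reference pathways")
    n_sig = 0
    for name in others:
        row = matrix.row(name)
        if np.std(row) == 0:
            continue
        _, p = _pearson(row, ref)
        if p < alpha:
            n_sig += 1
    return n_sig / len(others)


def cross_study_correlation(
    matrix: PathwayStudyMatrix, pathway_a: str, pathway_b: str
) -> tuple[float, float]:
    """Pearson correlation of two pathways' net-regulation rows across studies.

    Returns ``(r, two-sided p)``; symmetric in its arguments.  Raises
    :class:`UndefinedCorrelationError` when either row has zero variance
    (no silent NaN propagation).
    """
    if matrix.n_studies < 4:
        raise ValueError("cross-study correlation needs at least 4 studies")
    for name in (pathway_a, pathway_b):
        if name not in matrix.pathway_names:
            raise KeyError(f"pathway {name!r} not in matrix")
    a, b = matrix.row(pathway_a), matrix.row(pathway_b)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError(
            f"zero-variance score row for {pathway_a!r} or {pathway_b!r}"
        )
    if pathway_a == pathway_b:
        return 1.0, 0.0
    return _pearson(a, b)


def plot_pathway_study_heatmap(matrix: PathwayStudyMatrix, path: str) -> None:
    """Render the pathway-by-study score matrix as a yellow-blue heat map.

    Rows follow the reference-similarity ordering; yellow marks
    down-regulation and blue up-regulation of a pathway.  Requires
    matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [name for name, _ in sort_by_reference_similarity(matrix)]
    idx = [matrix.pathway_names.index(n) for n in order]
    data = matrix.scores[idx]
    vmax = max(np.abs(data).max(), 1e-9)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.n_studies), max(4, 0.18 * len(order)))
    )
    im = ax.imshow(data, cmap="YlGnBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(order)), order, fontsize=5)
    ax.set_xticks(range(matrix.n_studies), matrix.study_ids, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="net regulation (% of regulated genes)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
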