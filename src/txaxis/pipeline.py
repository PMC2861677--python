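"""The two headline procedures of the transcriptional-axis analysis.

Extreme-group comparison: rank samples by mean expression of the
reference (OXPHOS) pathway, compare the top-k against the bottom-k with
SAM, and summarize the calls as per-pathway net-regulation scores.
Across studies, the resulting pathway-by-study matrix is ordered by
similarity to the OXPHOS row.

Sequential binned comparison: pair the i-th-highest against the
i-th-lowest group of samples for i = 1..B and record the number of
differentially expressed transcripts per pair; on axis-structured data
the counts fall off as the compared groups approach the middle of the
ranking.

Note on circularity: the genes used for ranking are *not* excluded from
the subsequent differential-expression test, so the reference pathway's
own net score is upward-biased by construction; it is reported all the
same (result metadata records the ranking pathway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .containers import ExpressionStudy, GeneSetCollection, derive_seed
from .polarity import (
    PathwayPolarityProfile,
    PathwayStudyMatrix,
    net_regulation,
    sort_by_reference_similarity,
    stack_profiles,
)
from .sam import DECallSet, TwoGroupDesign, call_de

__all__ = [
    "SampleRanking",
    "BinPairs",
    "AxisCurve",
    "Figure1Result",
    "MultiStudyAxisResult",
    "CurveResult",
    "rank_by_pathway_expression",
    "extreme_groups",
    "sequential_bins",
    "default_group_size",
    "de_count_curve",
    "run_figure1",
    "run_figure1_multi",
]

logger = logging.getLogger(__name__)

DEFAULT_EXTREME_K = 10
DEFAULT_N_COMPARISONS = 10


@dataclass(frozen=True)
class SampleRanking:
    """Samples ordered by descending mean reference-pathway expression."""

    sample_ids: tuple[str, ...]
    means: np.ndarray
    pathway: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        means = np.asarray(self.means, dtype=float)
        object.__setattr__(self, "means", means)
        if len(means) != len(self.sample_ids):
            raise ValueError("one mean per sample required")
        if np.any(np.diff(means) > 1e-12):
            raise ValueError("means must be non-increasing along the ranking")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class BinPairs:
    """Disjoint high/low sample groups for sequential comparisons 1..B."""

    comparisons: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    group_size: int

    def __post_init__(self) -> None:
        comps = tuple(
            (tuple(hi), tuple(lo)) for hi, lo in self.comparisons
        )
        object.__setattr__(self, "comparisons", comps)
        seen: set[str] = set()
        for hi, lo in comps:
            for grp in (hi, lo):
                if len(grp) != self.group_size:
                    raise ValueError("every group must have group_size samples")
                overlap = seen & set(grp)
                if overlap:
                    raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
                seen |= set(grp)

    @property
    def n_comparisons(self) -> int:
        return len(self.comparisons)

    def design(self, i: int) -> TwoGroupDesign:
        """Two-group design of comparison ``i`` (1-based); high group is A."""
        hi, lo = self.comparisons[i - 1]
        return TwoGroupDesign(frozenset(hi), frozenset(lo))


@dataclass(frozen=True)
class AxisCurve:
    """Differentially-expressed transcript counts for comparisons 1..B."""

    de_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.de_counts)
        object.__setattr__(self, "de_counts", counts)
        if any(c < 0 for c in counts):
            raise ValueError("DE counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.de_counts)


@dataclass(frozen=True)
class Figure1Result:
    """Extreme-group pipeline output for one study."""

    study_id: str
    ranking: SampleRanking
    design: TwoGroupDesign
    calls: DECallSet
    profile: PathwayPolarityProfile


@dataclass(frozen=True)
class MultiStudyAxisResult:
    """Extreme-group pipeline output across several studies."""

    results: tuple[Figure1Result, ...]
    matrix: PathwayStudyMatrix
    ordering: tuple[tuple[str, float], ...]

    @property
    def ordered_pathways(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.ordering)


@dataclass(frozen=True)
class CurveResult:
    """Sequential-bin pipeline output for one study."""

    study_id: str
    bins: BinPairs
    curve: AxisCurve
    calls: tuple[DECallSet, ...]
    profiles: tuple[PathwayPolarityProfile, ...]


def rank_by_pathway_expression(
    study: ExpressionStudy, sets: GeneSetCollection, pathway: str | None = None
) -> SampleRanking:
    """Rank samples by their mean expression over a pathway's genes.

    Uses the collection's reference pathway when ``pathway`` is None.
    Pathway genes absent from the study are ignored (logged); at least
    one must be present.  Descending order; ties broken by sample ID.
    """
    if pathway is None:
        pathway = sets.reference_name
    if pathway not in sets:
        raise KeyError(f"pathway {pathway!r} not in collection")
    gidx = study.gene_index()
    rows = [gidx[g] for g in sorted(sets[pathway]) if g in gidx]
    n_missing = len(sets[pathway]) - len(rows)
    if not rows:
        raise ValueError(f"no gene of pathway {pathway!r} is present in the study")
    if n_missing:
        logger.info(
            "%d of %d %r genes absent from study %s",
            n_missing, len(sets[pathway]), pathway, study.study_id,
        )
    means = study.values[rows].mean(axis=0)
    order = sorted(range(study.n_samples), key=lambda j: (-means[j], study.sample_ids[j]))
    return SampleRanking(
        sample_ids=tuple(study.sample_ids[j] for j in order),
        means=means[order],
        pathway=pathway,
    )


def extreme_groups(ranking: SampleRanking, k: int = DEFAULT_EXTREME_K) -> TwoGroupDesign:
    """Top-k (group A) vs bottom-k (group B) samples of the ranking."""
    if k < 2:
        raise ValueError("k must be at least 2 for a two-group test")
    if 2 * k > ranking.n_samples:
        raise ValueError(f"2k = {2 * k} exceeds the {ranking.n_samples} samples")
    return TwoGroupDesign(
        frozenset(ranking.sample_ids[:k]), frozenset(ranking.sample_ids[-k:])
    )


def default_group_size(n_samples: int, n_comparisons: int = DEFAULT_N_COMPARISONS) -> int:
    """Group size rule: floor(n/2B) clamped to [10, 13] when that is feasible."""
    g = min(13, max(10, n_samples // (2 * n_comparisons)))
    if 2 * n_comparisons * g > n_samples:
        raise ValueError(
            f"{n_samples} samples cannot fill {n_comparisons} comparisons "
            f"of 2 x {g}; pass group_size explicitly"
        )
    return g


def sequential_bins(
    ranking: SampleRanking,
    n_comparisons: int = DEFAULT_N_COMPARISONS,
    group_size: int | None = None,
) -> BinPairs:
    """Pair the i-th-highest against the i-th-lowest group, i = 1..B.

    Comparison i takes ranking positions [(i-1)g+1 .. ig] as the high
    group and [n-ig+1 .. n-(i-1)g] as the low group; samples in the
    middle of the ranking (if any) are unused.
    """
    n = ranking.n_samples
    if group_size is None:
        group_size = default_group_size(n, n_comparisons)
    if group_size < 2 or n_comparisons < 1:
        raise ValueError("need group_size >= 2 and n_comparisons >= 1")
    if 2 * n_comparisons * group_size > n:
        raise ValueError(
            f"2 x {n_comparisons} x {group_size} samples needed, study has {n}"
        )
    comps = []
    ids = ranking.sample_ids
    for i in range(1, n_comparisons + 1):
        hi = ids[(i - 1) * group_size : i * group_size]
        lo = ids[n - i * group_size : n - (i - 1) * group_size]
        comps.append((hi, lo))
    return BinPairs(comparisons=tuple(comps), group_size=group_size)


def de_count_curve(
    study: ExpressionStudy,
    bins: BinPairs,
    sets: GeneSetCollection,
    target_fdr: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CurveResult:
    """SAM DE-counts and pathway profiles for each sequential comparison.

    Comparison i uses a child seed derived from ``(seed, i)`` so curves
    are reproducible yet permutations are independent across bins.
    """
    calls_list: list[DECallSet] = []
    profiles: list[PathwayPolarityProfile] = []
    counts: list[int] = []
    for i in range(1, bins.n_comparisons + 1):
        calls = call_de(
            study,
            bins.design(i),
            target_fdr=target_fdr,
            n_permutations=n_permutations,
            seed=derive_seed(seed, i),
        )
        calls_list.append(calls)
        profiles.append(net_regulation(calls, sets))
        counts.append(calls.n_called)
    return CurveResult(
        study_id=study.study_id,
        bins=bins,
        curve=AxisCurve(tuple(counts)),
        calls=tuple(calls_list),
        profiles=tuple(profiles),
    )


def run_figure1(
    study: ExpressionStudy,
    sets: GeneSetCollection,
    k: int = DEFAULT_EXTREME_K,
    target_fdr: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> Figure1Result:
    """Extreme-group pipeline on one study.

    Rank by reference-pathway expression, compare top-k vs bottom-k with
    SAM at the target FDR, and score every pathway's net direction of
    regulation.
    """
    ranking = rank_by_pathway_expression(study, sets)
    design = extreme_groups(ranking, k)
    calls = call_de(
        study, design, target_fdr=target_fdr, n_permutations=n_permutations, seed=seed
    )
    profile = net_regulation(calls, sets)
    return Figure1Result(
        study_id=study.study_id,
        ranking=ranking,
        design=design,
        calls=calls,
        profile=profile,
    )


def run_figure1_multi(
    studies: Sequence[ExpressionStudy],
    sets: GeneSetCollection,
    k: int = DEFAULT_EXTREME_K,
    target_fdr: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> MultiStudyAxisResult:
    """Extreme-group pipeline across studies, stacked and similarity-ordered.

    Each study gets a child seed derived from ``(seed, study index)``.
    The pathway-by-study matrix is ordered by Pearson similarity to the
    reference row (reference first).
    """
    if len(studies) < 3:
        raise ValueError("similarity ordering needs at least 3 studies")
    results = tuple(
        run_figure1(
            study, sets, k=k, target_fdr=target_fdr,
            n_permutations=n_permutations, seed=derive_seed(seed, idx),
        )
        for idx, study in enumerate(studies)
    )
    matrix = stack_profiles(
        [r.profile for r in results],
        [r.study_id for r in results],
        reference_name=sets.reference_name,
    )
    ordering = tuple(sort_by_reference_similarity(matrix))
    return MultiStudyAxisResult(results=results, matrix=matrix, ordering=ordering)
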