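"""Unpaired two-class Significance Analysis of Microarrays (SAM).

The moderated statistic for gene *i* is

    d_i = (mean_A - mean_B) / (s_i + s0)

where ``s_i`` is the pooled standard error of the mean difference and
``s0`` is a small "fudge factor" that damps the statistic for genes with
near-zero variance.  ``s0`` is chosen among the percentiles
{0, 5, ..., 100} of the ``s_i`` distribution as the value minimizing the
coefficient of variation of ``d`` across windows of ``s`` (so that the
spread of ``d`` is roughly independent of gene variance).

The false discovery rate is estimated by permuting the group labels:
for a threshold t, the expected number of null genes with ``|d| >= t``
(averaged over permutations) is divided by the observed count, and each
gene's q-value is the smallest such ratio over all thresholds at or
below its own ``|d|``.  Genes with q below the target FDR are called up
or down by the sign of ``d``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb

import numpy as np

from .containers import ExpressionStudy

__all__ = [
    "TwoGroupDesign",
    "DECallSet",
    "d_statistics",
    "estimate_s0",
    "permutation_null",
    "call_de",
    "S0_PERCENTILES",
]

logger = logging.getLogger(__name__)

#: candidate percentiles of the pooled-SE distribution scanned for s0
S0_PERCENTILES: tuple[int, ...] = tuple(range(0, 101, 5))

DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_TARGET_FDR = 0.05


@dataclass(frozen=True)
class TwoGroupDesign:
    """An unpaired two-group comparison (sample-ID sets)."""

    group_a: frozenset[str]
    group_b: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", frozenset(self.group_a))
        object.__setattr__(self, "group_b", frozenset(self.group_b))
        if self.group_a & self.group_b:
            raise ValueError("groups overlap: " f"{sorted(self.group_a & self.group_b)}")
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each group needs at least 2 samples")

    def swapped(self) -> "TwoGroupDesign":
        return TwoGroupDesign(self.group_b, self.group_a)

    def validate_against(self, study: ExpressionStudy) -> None:
        known = set(study.sample_ids)
        missing = (self.group_a | self.group_b) - known
        if missing:
            raise ValueError(f"design samples not in study: {sorted(missing)}")


@dataclass(frozen=True)
class DECallSet:
    """Per-gene SAM results for one two-group comparison.

    ``calls`` holds ``"up"``, ``"down"`` or ``"none"`` per gene; called
    genes have q-value below the target FDR and a d-score whose sign
    matches the call direction.
    """

    gene_ids: tuple[str, ...]
    d_scores: np.ndarray
    pooled_se: np.ndarray
    s0: float
    q_values: np.ndarray
    calls: tuple[str, ...]
    target_fdr: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "calls", tuple(self.calls))
        for name in ("d_scores", "pooled_se", "q_values"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.gene_ids)
        if not (len(self.d_scores) == len(self.pooled_se) == len(self.q_values) == len(self.calls) == n):
            raise ValueError("per-gene arrays have inconsistent lengths")
        if np.any((self.q_values < 0) | (self.q_values > 1)):
            raise ValueError("q-values must lie in [0, 1]")
        for d, q, c in zip(self.d_scores, self.q_values, self.calls):
            if c == "up" and not d > 0:
                raise ValueError("'up' call with non-positive d")
            if c == "down" and not d < 0:
                raise ValueError("'down' call with non-negative d")
            if c in ("up", "down") and not q < self.target_fdr:
                raise ValueError("called gene with q >= target FDR")

    @property
    def n_called(self) -> int:
        return sum(c != "none" for c in self.calls)

    def called_genes(self, direction: str | None = None) -> frozenset[str]:
        """Gene IDs called DE; optionally restrict to 'up' or 'down'."""
        if direction is None:
            return frozenset(g for g, c in zip(self.gene_ids, self.calls) if c != "none")
        return frozenset(g for g, c in zip(self.gene_ids, self.calls) if c == direction)


# ---------------------------------------------------------------------------
# d-statistic


def _design_columns(study: ExpressionStudy, design: TwoGroupDesign) -> tuple[np.ndarray, np.ndarray]:
    design.validate_against(study)
    return study.sample_columns(design.group_a), study.sample_columns(design.group_b)


def _d_and_s_for_masks(
    pooled: np.ndarray, masks_a: np.ndarray, n_a: int, n_b: int, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """d and pooled SE for each row of boolean group-A masks.

    ``pooled`` is the (genes, n_a + n_b) value matrix restricted to design
    samples; ``masks_a`` is (n_labelings, n_a + n_b). Returns (genes,
    n_labelings) arrays.
    """
    m = masks_a.astype(float).T  # (n, L)
    w = 1.0 - m
    sum_a = pooled @ m
    sum_b = pooled @ w
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    sq = pooled**2
    ss_a = sq @ m - n_a * mean_a**2
    ss_b = sq @ w - n_b * mean_b**2
    # clip tiny negative residuals from cancellation
    resid = np.clip(ss_a + ss_b, 0.0, None)
    s = np.sqrt((1.0 / n_a + 1.0 / n_b) * resid / (n_a + n_b - 2))
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (mean_a - mean_b) / denom
    return d, s


def d_statistics(
    study: ExpressionStudy, design: TwoGroupDesign, s0: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """SAM d-score and pooled standard error per gene.

    d_i = (mean_A - mean_B) / (s_i + s0), with
    s_i = sqrt((1/n_A + 1/n_B) * (SS_A + SS_B) / (n_A + n_B - 2)).

    With ``s0 = 0`` every gene must have within-group variance; a gene
    that is constant within both groups then has an undefined statistic
    and raises.
    """
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    cols_a, cols_b = _design_columns(study, design)
    pooled = study.values[:, np.concatenate([cols_a, cols_b])]
    n_a, n_b = len(cols_a), len(cols_b)
    mask = np.zeros((1, n_a + n_b), dtype=bool)
    mask[0, :n_a] = True
    d, s = _d_and_s_for_masks(pooled, mask, n_a, n_b, s0)
    d, s = d[:, 0], s[:, 0]
    if s0 == 0.0 and np.any(s == 0.0):
        g = int(np.argmax(s == 0.0))
        raise ZeroDivisionError(
            f"gene {study.gene_ids[g]!r} has zero variance in both groups and s0=0"
        )
    return d, s


# ---------------------------------------------------------------------------
# fudge factor


def estimate_s0(
    d_scores_at_s0_zero: np.ndarray, pooled_se: np.ndarray
) -> float:
    """Select s0 among percentiles {0,5,...,100} of the pooled SE.

    The chosen value minimizes the coefficient of variation, across
    windows of ``s``, of the median absolute deviation of the damped
    statistic d(s0) = r / (s + s0).  Deterministic; ties resolve to the
    smallest percentile.  Needs at least 100 genes for stable windows.
    """
    d0 = np.asarray(d_scores_at_s0_zero, dtype=float)
    s = np.asarray(pooled_se, dtype=float)
    if d0.shape != s.shape or d0.ndim != 1:
        raise ValueError("d and s must be 1-D arrays of equal length")
    n = len(s)
    if n < 100:
        raise ValueError("s0 estimation needs at least 100 genes")
    if np.all(s == 0):
        raise ValueError("all pooled standard errors are zero (degenerate data)")
    if np.all(s == s[0]):
        return float(s[0])

    # numerators of d (finite even where s == 0)
    r = np.where(np.isfinite(d0), d0 * s, 0.0)
    r = np.where((s == 0) & ~np.isfinite(d0), np.nan, r)

    order = np.argsort(s, kind="stable")
    n_windows = 100 if n >= 1000 else max(5, n // 20)
    windows = np.array_split(order, n_windows)

    best_alpha, best_cv = None, np.inf
    for alpha in S0_PERCENTILES:
        cand = float(np.percentile(s, alpha))
        with np.errstate(divide="ignore", invalid="ignore"):
            d_alpha = r / (s + cand)
        mads = np.array(
            [_mad(d_alpha[w]) for w in windows if len(w) > 0], dtype=float
        )
        mean_mad = np.mean(mads)
        if mean_mad == 0 or not np.isfinite(mean_mad):
            continue
        cv = float(np.std(mads) / mean_mad)
        if cv < best_cv - 1e-15:
            best_cv, best_alpha = cv, alpha
    if best_alpha is None:
        # fall back to the median of s when every window is degenerate
        return float(np.percentile(s, 50))
    return float(np.percentile(s, best_alpha))


def _mad(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return np.nan
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


# ---------------------------------------------------------------------------
# permutation null


def _labelings(
    n: int, n_a: int, n_permutations: int, seed: int
) -> tuple[np.ndarray, bool]:
    """Boolean group-A masks over the pooled design columns.

    Exhaustive (and seed-independent) when C(n, n_a) <= n_permutations;
    otherwise ``n_permutations`` uniform label shuffles drawn with the
    given seed.
    """
    total = comb(n, n_a)
    if total <= n_permutations:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), n_a)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    keys = rng.random((n_permutations, n))
    order = np.argsort(keys, axis=1)
    masks = np.zeros((n_permutations, n), dtype=bool)
    rows = np.arange(n_permutations)[:, None]
    masks[rows, order[:, :n_a]] = True
    return masks, False


def permutation_null(
    study: ExpressionStudy,
    design: TwoGroupDesign,
    s0: float,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
) -> np.ndarray:
    """Null d-score matrix from label permutations.

    Returns one row per permuted labeling, each row the ascending-sorted
    d-vector across genes.  When the number of distinct labelings is at
    most ``n_permutations`` all of them are enumerated (deterministic,
    seed ignored); otherwise labels are shuffled uniformly at random.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    cols_a, cols_b = _design_columns(study, design)
    pooled = study.values[:, np.concatenate([cols_a, cols_b])]
    n_a, n_b = len(cols_a), len(cols_b)
    masks, exhaustive = _labelings(n_a + n_b, n_a, n_permutations, seed)
    if exhaustive:
        logger.debug(
            "exhaustive permutation null: %d labelings for %d-vs-%d",
            len(masks), n_a, n_b,
        )
    d, _ = _d_and_s_for_masks(pooled, masks, n_a, n_b, s0)
    return np.sort(d.T, axis=1)


# ---------------------------------------------------------------------------
# q-values and calls


#: scores within this distance of a threshold count as exceeding it, so
#: exact ties (e.g. the identity labeling inside an exhaustive null) are
#: counted consistently regardless of floating-point evaluation order
TIE_TOL = 1e-9


def _q_values(d_obs: np.ndarray, null_d: np.ndarray) -> np.ndarray:
    """Permutation q-values from observed and null d-scores.

    For each candidate threshold t = |d_g|: the FDR estimate is the mean
    count of null |d| >= t per permutation, divided by the observed count
    of |d| >= t, clamped to [0, 1].  The q-value is the minimum FDR over
    thresholds at or below the gene's own |d|, which makes q
    non-increasing in |d|.
    """
    abs_obs = np.abs(d_obs)
    n_perm = null_d.shape[0]
    thresholds = abs_obs - TIE_TOL
    flat_null = np.sort(np.abs(null_d).ravel())
    # mean null exceedances per permutation at each gene's threshold
    v = (len(flat_null) - np.searchsorted(flat_null, thresholds, side="left")) / n_perm
    sorted_obs = np.sort(abs_obs)
    r = len(abs_obs) - np.searchsorted(sorted_obs, thresholds, side="left")
    fdr = np.minimum(v / np.maximum(r, 1), 1.0)
    # running min from the smallest |d| upward
    order = np.argsort(abs_obs, kind="stable")
    q = np.empty_like(fdr)
    q[order] = np.minimum.accumulate(fdr[order])
    return q


def call_de(
    study: ExpressionStudy,
    design: TwoGroupDesign,
    target_fdr: float = DEFAULT_TARGET_FDR,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    s0: float | None = None,
) -> DECallSet:
    """Full SAM analysis of one two-group comparison.

    Estimates s0 (unless supplied), computes observed d-scores and the
    permutation null, assigns q-values, and calls genes with
    q < ``target_fdr`` as up or down by the sign of d.
    """
    if not 0 < target_fdr < 1:
        raise ValueError("target_fdr must lie in (0, 1)")
    cols_a, cols_b = _design_columns(study, design)
    pooled = study.values[:, np.concatenate([cols_a, cols_b])]
    n_a, n_b = len(cols_a), len(cols_b)
    mask = np.zeros((1, n_a + n_b), dtype=bool)
    mask[0, :n_a] = True
    d0, s = _d_and_s_for_masks(pooled, mask, n_a, n_b, 0.0)
    d0, s = d0[:, 0], s[:, 0]
    if s0 is None:
        s0 = estimate_s0(d0, s)
    if s0 < 0:
        raise ValueError("s0 must be nonnegative")
    if s0 == 0.0 and np.any(s == 0.0):
        raise ZeroDivisionError("zero-variance gene with s0=0; supply s0 > 0")
    r = pooled[:, :n_a].mean(axis=1) - pooled[:, n_a:].mean(axis=1)
    d_obs = r / (s + s0)
    null_d = permutation_null(study, design, s0, n_permutations, seed)
    q = _q_values(d_obs, null_d)
    calls = tuple(
        "up" if (qg < target_fdr and dg > 0)
        else "down" if (qg < target_fdr and dg < 0)
        else "none"
        for dg, qg in zip(d_obs, q)
    )
    return DECallSet(
        gene_ids=study.gene_ids,
        d_scores=d_obs,
        pooled_se=s,
        s0=float(s0),
        q_values=q,
        calls=calls,
        target_fdr=target_fdr,
        n_permutations=n_permutations,
        seed=seed,
    )
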