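"""Synthetic expression studies with a known latent transcriptional axis.

Each sample carries a latent axis score z ~ N(0, 1).  Genes belong to
pathways that load on the axis with a signed magnitude (metabolic
pathways positively, signaling pathways negatively) or to an
unstructured background with loading zero, and observed log2 expression
is

    x[g, j] = baseline_mean + loading[g] * z[j] + eps,   eps ~ N(0, noise_sd)

This mimics the structure of the large normalized microarray studies
the axis analysis was designed for (whole-genome platforms, hundreds of
samples), while giving every downstream stage exact ground truth: the
latent scores, the per-gene loadings, and the pathway membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .containers import ExpressionStudy, GeneSetCollection, derive_seed

__all__ = [
    "PathwaySpec",
    "AxisSimConfig",
    "SimTruth",
    "default_pathway_spec",
    "default_axis_config",
    "generate_study",
    "generate_multi_study",
]

#: canonical study conditions: whole-genome-scale matrix, large cohort
DEFAULT_N_GENES = 5000
DEFAULT_N_SAMPLES = 200
DEFAULT_NOISE_SD = 0.7
DEFAULT_BASELINE_MEAN = 8.0
DEFAULT_PATHWAY_SIZE = 50

METABOLIC_PATHWAYS = (
    "OXPHOS",
    "TCA cycle",
    "Glycolysis",
    "Fatty acid metabolism",
    "Pyruvate metabolism",
    "Pentose phosphate pathway",
    "Amino acid metabolism",
    "Purine metabolism",
    "Glutathione metabolism",
    "Propanoate metabolism",
)

SIGNALING_PATHWAYS = (
    "MAPK signaling",
    "JAK-STAT signaling",
    "Calcium signaling",
    "Wnt signaling",
    "TGF-beta signaling",
    "ErbB signaling",
    "Notch signaling",
    "Hedgehog signaling",
    "mTOR signaling",
    "Insulin signaling",
)


@dataclass(frozen=True)
class PathwaySpec:
    """One simulated pathway: name, member count, loading sign and magnitude."""

    name: str
    n_genes: int
    sign: int
    beta: float

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError(f"pathway {self.name!r} needs a positive gene count")
        if self.sign not in (-1, 0, 1):
            raise ValueError("loading sign must be -1, 0 or +1")
        if self.beta < 0:
            raise ValueError("loading magnitude beta must be nonnegative")


@dataclass(frozen=True)
class AxisSimConfig:
    """Configuration of one simulated study."""

    n_genes: int
    n_samples: int
    pathway_spec: tuple[PathwaySpec, ...]
    noise_sd: float
    baseline_mean: float
    seed: int
    study_id: str = "sim_study"

    def __post_init__(self) -> None:
        spec = tuple(
            p if isinstance(p, PathwaySpec) else PathwaySpec(*p)
            for p in self.pathway_spec
        )
        object.__setattr__(self, "pathway_spec", spec)
        if self.n_genes <= 0 or self.n_samples <= 0:
            raise ValueError("n_genes and n_samples must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        names = [p.name for p in spec]
        if len(set(names)) != len(names):
            raise ValueError("pathway names must be unique")
        if sum(p.n_genes for p in spec) > self.n_genes:
            raise ValueError(
                "pathway gene counts exceed n_genes "
                f"({sum(p.n_genes for p in spec)} > {self.n_genes})"
            )

    def scaled(self, strength: float) -> "AxisSimConfig":
        """Copy with every pathway loading magnitude multiplied by ``strength``."""
        if strength < 0:
            raise ValueError("axis strength must be nonnegative")
        spec = tuple(replace(p, beta=p.beta * strength) for p in self.pathway_spec)
        return replace(self, pathway_spec=spec)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated study."""

    axis_scores: np.ndarray
    gene_loadings: np.ndarray
    pathway_membership: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis_scores", np.asarray(self.axis_scores, dtype=float))
        object.__setattr__(self, "gene_loadings", np.asarray(self.gene_loadings, dtype=float))
        object.__setattr__(self, "pathway_membership", dict(self.pathway_membership))

    BACKGROUND = "background"


def default_pathway_spec(
    beta: float = 1.0,
    n_metabolic: int = 10,
    n_signaling: int = 10,
    n_background_sets: int = 30,
    pathway_size: int = DEFAULT_PATHWAY_SIZE,
) -> tuple[PathwaySpec, ...]:
    """Canonical pathway layout: metabolic +beta, signaling -beta, null sets.

    Metabolic pathways (OXPHOS first) load positively on the axis,
    signaling pathways negatively, and ``n_background_sets`` pathways
    are drawn from unstructured background genes (loading zero).
    """
    if n_metabolic > len(METABOLIC_PATHWAYS) or n_signaling > len(SIGNALING_PATHWAYS):
        raise ValueError("not enough built-in pathway names")
    spec = [
        PathwaySpec(name, pathway_size, +1, beta)
        for name in METABOLIC_PATHWAYS[:n_metabolic]
    ]
    spec += [
        PathwaySpec(name, pathway_size, -1, beta)
        for name in SIGNALING_PATHWAYS[:n_signaling]
    ]
    spec += [
        PathwaySpec(f"Background set {i + 1:02d}", pathway_size, 0, 0.0)
        for i in range(n_background_sets)
    ]
    return tuple(spec)


def default_axis_config(seed: int, beta: float = 1.0, **overrides) -> AxisSimConfig:
    """Study configuration under the canonical conditions.

    5,000 genes, 200 samples, 10 metabolic pathways at +beta and 10
    signaling at -beta (50 genes each), 30 null pathways of background
    genes, noise SD 0.7 on the log2 scale.
    """
    params = dict(
        n_genes=DEFAULT_N_GENES,
        n_samples=DEFAULT_N_SAMPLES,
        pathway_spec=default_pathway_spec(beta=beta),
        noise_sd=DEFAULT_NOISE_SD,
        baseline_mean=DEFAULT_BASELINE_MEAN,
        seed=seed,
    )
    params.update(overrides)
    return AxisSimConfig(**params)


def generate_study(
    config: AxisSimConfig,
) -> tuple[ExpressionStudy, GeneSetCollection, SimTruth]:
    """Simulate one study: expression matrix, gene sets, and ground truth.

    Deterministic: identical config (including seed) reproduces the
    output bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    n_g, n_s = config.n_genes, config.n_samples
    width = max(5, len(str(n_g)))
    gene_ids = tuple(f"G{i:0{width}d}" for i in range(1, n_g + 1))
    sample_ids = tuple(f"S{j:04d}" for j in range(1, n_s + 1))

    loadings = np.zeros(n_g)
    membership: dict[str, str] = {g: SimTruth.BACKGROUND for g in gene_ids}
    sets: dict[str, frozenset[str]] = {}
    cursor = 0
    for p in config.pathway_spec:
        members = gene_ids[cursor : cursor + p.n_genes]
        cursor += p.n_genes
        sets[p.name] = frozenset(members)
        loadings[cursor - p.n_genes : cursor] = p.sign * p.beta
        for g in members:
            membership[g] = p.name

    z = rng.standard_normal(n_s)
    noise = rng.normal(0.0, config.noise_sd, size=(n_g, n_s))
    values = config.baseline_mean + np.outer(loadings, z) + noise

    if not sets:
        raise ValueError("pathway_spec is empty; simulate at least one gene set "
                         "(use beta=0 pathways for a null study)")
    study = ExpressionStudy(config.study_id, gene_ids, sample_ids, values)
    reference = "OXPHOS" if "OXPHOS" in sets else next(iter(sets))
    collection = GeneSetCollection(sets, reference_name=reference)
    truth = SimTruth(axis_scores=z, gene_loadings=loadings, pathway_membership=membership)
    return study, collection, truth


def generate_multi_study(
    base_config: AxisSimConfig,
    n_studies: int,
    axis_strengths: Sequence[float],
    seed: int,
) -> list[tuple[ExpressionStudy, SimTruth]]:
    """Simulate several studies sharing one gene/pathway layout.

    Study ``k`` scales every loading magnitude by ``axis_strengths[k]``
    and uses a child seed derived from the top-level ``seed``, so the
    studies are independent yet the whole ensemble is reproducible.
    The shared :class:`GeneSetCollection` is the one returned by
    :func:`generate_study` on any member (the layout is identical).
    """
    if n_studies < 2:
        raise ValueError("correlation analyses need at least 2 studies")
    if len(axis_strengths) != n_studies:
        raise ValueError("need one axis strength per study")
    out: list[tuple[ExpressionStudy, SimTruth]] = []
    for k in range(n_studies):
        cfg = replace(
            base_config.scaled(float(axis_strengths[k])),
            seed=derive_seed(seed, k),
            study_id=f"{base_config.study_id}_{k + 1:02d}",
        )
        study, _, truth = generate_study(cfg)
        out.append((study, truth))
    return out
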