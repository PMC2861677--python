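"""Core in-memory containers shared across the analysis stages.

An :class:`ExpressionStudy` holds one study's gene-by-sample matrix of
log2-scale expression values; a :class:`GeneSetCollection` holds named
pathways (gene-ID sets) with one pathway designated as the reference for
axis analyses (oxidative phosphorylation by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = ["ExpressionStudy", "GeneSetCollection", "derive_seed"]


def derive_seed(master: int, *key: int) -> int:
    """Derive a reproducible child seed from a master seed and an index key.

    Uses numpy's SeedSequence so children with different keys are
    statistically independent. The result fits in a signed 32-bit int.
    """
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _check_unique(ids: tuple[str, ...], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise ValueError(f"duplicate {what} ID: {x!r}")
            seen.add(x)


@dataclass(frozen=True)
class ExpressionStudy:
    """One study's gene-by-sample log2-expression matrix.

    Parameters
    ----------
    study_id:
        Identifier for the study (e.g. a GEO accession or a simulation tag).
    gene_ids, sample_ids:
        Unique, ordered identifiers for the matrix rows and columns.
    values:
        ``(n_genes, n_samples)`` float array of log2-scale expression; must
        be finite (normalization and missing-value handling happen upstream).
    """

    study_id: str
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D gene-by-sample matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def sample_columns(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given samples, in study column order."""
        wanted = set(sample_ids)
        missing = wanted - set(self.sample_ids)
        if missing:
            raise KeyError(f"samples not in study: {sorted(missing)}")
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if s in wanted], dtype=int
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named pathways, each a set of gene identifiers.

    ``reference_name`` names the pathway used as the axis reference
    (OXPHOS in the analyses this package was built for). Gene IDs are
    opaque, case-sensitive strings; a gene may belong to several sets.
    """

    sets: Mapping[str, frozenset[str]]
    reference_name: str = "OXPHOS"

    def __post_init__(self) -> None:
        frozen = {str(k): frozenset(v) for k, v in self.sets.items()}
        object.__setattr__(self, "sets", frozen)
        for name, members in frozen.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        if self.reference_name not in frozen:
            raise ValueError(
                f"reference pathway {self.reference_name!r} not in collection"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets
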