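"""Readers and writers for the pipeline's text formats.

Expression matrices are tab-separated (gene IDs in the first column,
sample IDs in the header); gene sets use the standard GMT layout (set
name, description, then member gene IDs).  All files are UTF-8; line
endings are normalized on read.  Each pipeline output directory carries
a run manifest (JSON) recording the configuration, seeds, input digests
and tool version so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import yaml

from .containers import ExpressionStudy, GeneSetCollection
from .polarity import PathwayPolarityProfile, PathwayStudyMatrix
from .sam import DECallSet
from .synthetic import SimTruth

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "write_de_calls",
    "read_de_calls",
    "write_polarity_profile",
    "write_pathway_study_matrix",
    "read_pathway_study_matrix",
    "write_sim_truth",
    "RunManifest",
    "write_manifest",
    "read_manifest",
    "file_digest",
    "load_config",
]

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


class FormatError(ValueError):
    """A file does not conform to its expected text format."""


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").replace("\r", "\n").split("\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_tsv(path: str | Path, study_id: str | None = None) -> ExpressionStudy:
    """Read a gene-by-sample expression matrix from tab-separated text.

    The first header column names the gene-ID column (ignored); the rest
    are sample IDs.  Rejects ragged rows, duplicate gene IDs and
    non-numeric or missing cells, naming the offending coordinates.
    """
    path = Path(path)
    lines = [ln for ln in _read_lines(path) if ln != ""]
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must name at least one sample")
    sample_ids = tuple(header[1:])
    n_cols = len(header)
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_cols} (ragged row)"
            )
        gene = fields[0]
        if gene in seen:
            raise FormatError(f"{path}: duplicate gene ID {gene!r} at line {lineno}")
        seen.add(gene)
        row: list[float] = []
        for col, cell in enumerate(fields[1:]):
            if cell == "" or cell.upper() in ("NA", "NAN"):
                raise FormatError(
                    f"{path}: missing value at gene {gene!r} (line {lineno}), "
                    f"sample {sample_ids[col]!r}"
                )
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r} "
                    f"(line {lineno}), sample {sample_ids[col]!r}"
                ) from None
        gene_ids.append(gene)
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return ExpressionStudy(
        study_id=study_id if study_id is not None else path.stem,
        gene_ids=tuple(gene_ids),
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
    )


def write_expression_tsv(study: ExpressionStudy, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(study.sample_ids) + "\n")
        for g, row in zip(study.gene_ids, study.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: str | Path, reference_name: str = "OXPHOS") -> GeneSetCollection:
    """Read a GMT gene-set file: name TAB description TAB gene IDs.

    Duplicate genes within a set are deduplicated (logged); empty sets
    and duplicate set names are rejected with line numbers.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(_read_lines(path), start=1):
        if line == "":
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}: line {lineno}: GMT lines need name, description and >= 1 gene"
            )
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate pathway name {name!r}")
        genes = [g for g in fields[2:] if g != ""]
        if not genes:
            raise FormatError(f"{path}: line {lineno}: pathway {name!r} has no genes")
        unique = frozenset(genes)
        if len(unique) < len(genes):
            logger.info(
                "%s line %d: %d duplicate gene IDs in %r deduplicated",
                path, lineno, len(genes) - len(unique), name,
            )
        sets[name] = unique
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, reference_name=reference_name)


def write_gmt(sets: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name in sets.names:
            fh.write(name + "\t" + description + "\t" + "\t".join(sorted(sets[name])) + "\n")


# ---------------------------------------------------------------------------
# SAM call sets


def write_de_calls(calls: DECallSet, path: str | Path) -> None:
    """Write a call set as TSV with '#' comment lines for run metadata."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# s0={float(calls.s0)!r}\n")
        fh.write(f"# target_fdr={float(calls.target_fdr)!r}\n")
        fh.write(f"# n_permutations={calls.n_permutations}\n")
        fh.write(f"# seed={calls.seed}\n")
        fh.write("gene_id\td\ts\tq\tcall\n")
        for g, d, s, q, c in zip(
            calls.gene_ids, calls.d_scores, calls.pooled_se, calls.q_values, calls.calls
        ):
            fh.write(f"{g}\t{float(d)!r}\t{float(s)!r}\t{float(q)!r}\t{c}\n")


def read_de_calls(path: str | Path) -> DECallSet:
    meta: dict[str, str] = {}
    gene_ids: list[str] = []
    d: list[float] = []
    s: list[float] = []
    q: list[float] = []
    calls: list[str] = []
    header_seen = False
    for lineno, line in enumerate(_read_lines(path), start=1):
        if line == "":
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path}: line {lineno}: expected 5 fields")
        gene_ids.append(fields[0])
        d.append(float(fields[1]))
        s.append(float(fields[2]))
        q.append(float(fields[3]))
        calls.append(fields[4])
    return DECallSet(
        gene_ids=tuple(gene_ids),
        d_scores=np.array(d),
        pooled_se=np.array(s),
        s0=float(meta.get("s0", "nan")),
        q_values=np.array(q),
        calls=tuple(calls),
        target_fdr=float(meta.get("target_fdr", "0.05")),
        n_permutations=int(meta.get("n_permutations", "0")),
        seed=int(meta.get("seed", "0")),
    )


# ---------------------------------------------------------------------------
# polarity tables


def write_polarity_profile(profile: PathwayPolarityProfile, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# total_regulated={profile.total_regulated}\n")
        fh.write("pathway\tnet_score\tn_up\tn_down\n")
        for name, score, up, down in zip(
            profile.pathway_names, profile.net_scores, profile.n_up, profile.n_down
        ):
            fh.write(f"{name}\t{float(score)!r}\t{up}\t{down}\n")


def write_pathway_study_matrix(matrix: PathwayStudyMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# reference={matrix.reference_name}\n")
        fh.write("pathway\t" + "\t".join(matrix.study_ids) + "\n")
        for name, row in zip(matrix.pathway_names, matrix.scores):
            fh.write(name + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_pathway_study_matrix(path: str | Path) -> PathwayStudyMatrix:
    reference = "OXPHOS"
    names: list[str] = []
    rows: list[list[float]] = []
    study_ids: tuple[str, ...] | None = None
    for lineno, line in enumerate(_read_lines(path), start=1):
        if line == "":
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "reference":
                reference = value.strip()
            continue
        fields = line.split("\t")
        if study_ids is None:
            study_ids = tuple(fields[1:])
            continue
        if len(fields) != len(study_ids) + 1:
            raise FormatError(f"{path}: line {lineno}: ragged row")
        names.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    if study_ids is None or not rows:
        raise FormatError(f"{path}: no matrix data")
    return PathwayStudyMatrix(tuple(names), study_ids, np.array(rows), reference)


def write_sim_truth(truth: SimTruth, study: ExpressionStudy, path: str | Path) -> None:
    """Ground truth as key/value TSV (axis scores, loadings, membership)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("kind\tid\tvalue\n")
        for sid, z in zip(study.sample_ids, truth.axis_scores):
            fh.write(f"axis_score\t{sid}\t{float(z)!r}\n")
        for gid, load in zip(study.gene_ids, truth.gene_loadings):
            fh.write(f"gene_loading\t{gid}\t{float(load)!r}\n")
        for gid in study.gene_ids:
            fh.write(f"membership\t{gid}\t{truth.pathway_membership[gid]}\n")


# ---------------------------------------------------------------------------
# run manifests and config files


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record written next to every pipeline output."""

    tool: str
    version: str
    created: str
    config: Mapping[str, Any]
    seeds: Mapping[str, int]
    input_digests: Mapping[str, str]
    outputs: tuple[str, ...] = ()

    @classmethod
    def create(
        cls,
        config: Mapping[str, Any],
        seeds: Mapping[str, int],
        inputs: Iterable[str | Path] = (),
        outputs: Iterable[str] = (),
    ) -> "RunManifest":
        from . import __version__

        return cls(
            tool="txaxis",
            version=__version__,
            created=datetime.now(timezone.utc).isoformat(),
            config=dict(config),
            seeds=dict(seeds),
            input_digests={str(p): file_digest(p) for p in inputs},
            outputs=tuple(outputs),
        )


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    path = Path(out_dir) / MANIFEST_NAME
    path.write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return path


def read_manifest(out_dir: str | Path) -> RunManifest:
    path = Path(out_dir) / MANIFEST_NAME
    data = json.loads(path.read_text(encoding="utf-8"))
    data["outputs"] = tuple(data.get("outputs", ()))
    return RunManifest(**data)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML config of pipeline parameters (flat key/value mapping)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data
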