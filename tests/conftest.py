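"""Shared fixtures: small deterministic studies and designs."""

from __future__ import annotations

import numpy as np
import pytest

import txaxis as tx


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_study():
    """5 genes x 6 samples with fixed values for hand-checkable tests."""
    rng = np.random.default_rng(7)
    values = np.round(rng.normal(8.0, 1.0, size=(5, 6)), 3)
    return tx.ExpressionStudy(
        study_id="tiny",
        gene_ids=tuple(f"g{i}" for i in range(1, 6)),
        sample_ids=tuple(f"s{j}" for j in range(1, 7)),
        values=values,
    )


@pytest.fixture
def tiny_design(tiny_study):
    ids = tiny_study.sample_ids
    return tx.TwoGroupDesign(frozenset(ids[:3]), frozenset(ids[3:]))


def make_null_study(n_genes=2000, n_samples=20, seed=0, noise_sd=1.0):
    """Pure-noise study: one beta=0 pathway so the layout is non-degenerate."""
    cfg = tx.AxisSimConfig(
        n_genes=n_genes,
        n_samples=n_samples,
        pathway_spec=(tx.PathwaySpec("OXPHOS", min(50, n_genes), +1, 0.0),),
        noise_sd=noise_sd,
        baseline_mean=8.0,
        seed=seed,
    )
    return tx.generate_study(cfg)


def halves_design(study):
    """First half of samples vs second half, in study order."""
    n = study.n_samples // 2
    return tx.TwoGroupDesign(
        frozenset(study.sample_ids[:n]), frozenset(study.sample_ids[n : 2 * n])
    )


@pytest.fixture(scope="session")
def axis_ensemble():
    """20 studies under the canonical axis conditions, with their gene sets.

    Shared across the acceptance checks that exercise the full
    extreme-group pipeline (axis fraction, sign recovery).
    """
    base = tx.default_axis_config(seed=0)
    pairs = tx.generate_multi_study(base, 20, [1.0] * 20, seed=101)
    _, sets, _ = tx.generate_study(base)
    studies = [s for s, _ in pairs]
    multi = tx.run_figure1_multi(studies, sets, n_permutations=200, seed=101)
    return sets, multi
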