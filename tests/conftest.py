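"""Shared fixtures: small synthetic cohorts reused across test modules.

Session scope keeps the expensive image generation to a handful of
cohorts for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import zebra
from zebra import pipeline


@pytest.fixture(scope="session")
def small_spec() -> zebra.SyntheticCohortSpec:
    """Compact, well-separated cohort: 6 FN + 4 control cases."""
    return zebra.SyntheticCohortSpec(
        n_cases_pos=6, n_cases_neg=4, glomeruli_per_case=(2, 3),
        target_fraction_range=(0.10, 0.30), seed=7,
    )


@pytest.fixture(scope="session")
def small_tiles(small_spec):
    """Labelled tiles + manifest + case records for the small cohort."""
    tiles, manifest, records = pipeline.tiles_from_cohort(
        small_spec, zebra.TilingConfig()
    )
    return tiles, manifest, records


@pytest.fixture(scope="session")
def small_folds(small_tiles):
    tiles, _, records = small_tiles
    return zebra.make_case_folds(list(records["case_id"]), k=5, seed=7)


@pytest.fixture(scope="session")
def trained_segmenter(small_tiles, small_folds):
    """A podocyte segmenter cross-validated on the small cohort."""
    tiles, _, _ = small_tiles
    cfg = zebra.SegTrainConfig(target="podocyte", seed=7)
    return zebra.train_segmenter(tiles, small_folds, cfg), cfg


@pytest.fixture(scope="session")
def full_run():
    """Default-scale end-to-end pipeline run (the study conditions)."""
    cfg = zebra.RunConfig(seed=11)
    cfg.cohort.seed = 11
    return zebra.run_all(cfg)


@pytest.fixture(scope="session")
def zs_cohort():
    """30-case cohort (ground truth only) for score-recovery checks."""
    spec = zebra.SyntheticCohortSpec(
        n_cases_pos=15, n_cases_neg=15, glomeruli_per_case=(3, 4),
        source_mpp=0.25, seed=23,
    )
    cases, manifest = zebra.generate_cohort(spec)
    return cases, manifest


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
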