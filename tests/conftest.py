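"""Shared fixtures: small specimens and the session-scoped paired pipeline
runs used by the headline-direction and localization checks."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from perifem import (
    ImplantSpec,
    MaterialTable,
    PipelineConfig,
    SpecimenSpec,
    build_truth,
    run_refined_branch,
    run_simplified_branch,
)

DIRECTION_SEEDS = (1, 2, 3, 4, 5)


def small_specimen_spec(**over) -> SpecimenSpec:
    """Compact single-implant specimen for fast solves (unthreaded implant)."""
    kw = dict(
        domain_size_mm=(8.0, 6.0, 10.0),
        voxel_mm=0.5,
        cortical_thickness_mm=1.0,
        target_bvtv=0.3,
        correlation_length_mm=1.5,
        anisotropy=(1.0, 1.0, 1.5),
        implants=(
            ImplantSpec(thread_depth_mm=0.0, axis_entry_point_mm=(4.0, 3.0, 10.0)),
        ),
        rng_seed=0,
    )
    kw.update(over)
    return SpecimenSpec(**kw)


def small_config(**over) -> PipelineConfig:
    kw = dict(specimen=small_specimen_spec(), master_seed=3, bypass_segmentation=True)
    kw.update(over)
    return PipelineConfig(**kw)


@pytest.fixture(scope="session")
def paired_runs():
    """Refined + simplified branch results for the default two-implant
    specimen over the direction-check seeds."""
    out = {}
    for seed in DIRECTION_SEEDS:
        cfg = PipelineConfig(master_seed=seed)
        truth = build_truth(cfg)
        refined = run_refined_branch(cfg, truth=truth)
        simplified = run_simplified_branch(cfg, truth=truth)
        out[seed] = (cfg, refined, simplified)
    return out


@pytest.fixture(scope="session")
def bypass_run_seed1(paired_runs):
    """Refined branch solved on ground-truth labels (segmentation bypassed)
    for the first direction seed, to quantify segmentation-induced error."""
    cfg, _, _ = paired_runs[DIRECTION_SEEDS[0]]
    cfg_b = replace(cfg, bypass_segmentation=True)
    truth = build_truth(cfg)
    return run_refined_branch(cfg_b, truth=truth)


@pytest.fixture(scope="session")
def solid_limit_runs():
    """Paired runs in the solid limit (BV/TV -> 1) with matched materials:
    the refined and simplified models should coincide."""
    spec = small_specimen_spec(target_bvtv=0.995)
    matched = MaterialTable({2: (14400.0, 0.309), 3: (110000.0, 0.35),
                             4: (14400.0, 0.309), 1: (14400.0, 0.309)})
    cfg = PipelineConfig(
        specimen=spec,
        master_seed=7,
        bypass_segmentation=True,
        refined_materials=matched,
        simplified_materials=matched,
    )
    truth = build_truth(cfg)
    refined = run_refined_branch(cfg, truth=truth)
    simplified = run_simplified_branch(cfg, truth=truth)
    return refined, simplified


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
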