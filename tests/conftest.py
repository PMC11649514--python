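"""Shared fixtures: synthetic cases at the sizes the checks need.

Image-bearing fixtures use compact slides (1–1.5 mm) so the rendered
pipeline stays fast; cell-level fixtures use the full 4×4 mm default
geometry. Everything is seeded and session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ki67hotspot as k

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def compact_spec(seed: int, **overrides) -> k.SlideSpec:
    """1×1 mm slide for image-level checks."""
    base = dict(width_um=1000.0, height_um=1000.0, hotspot_center_um=(500.0, 500.0),
                benign_region_count=0, insitu_region_count=0, seed=seed)
    base.update(overrides)
    return k.SlideSpec(**base)


def registration_spec(seed: int, **overrides) -> k.SlideSpec:
    """1.5×1.5 mm slide with distractors, for serial-section checks."""
    base = dict(width_um=1500.0, height_um=1500.0, hotspot_center_um=(700.0, 700.0),
                benign_region_count=1, insitu_region_count=1, seed=seed)
    base.update(overrides)
    return k.SlideSpec(**base)


def _compact_cells(case: k.SyntheticCase) -> k.SyntheticCase:
    for col in ("ki67_class", "region_class"):
        case.cells[col] = case.cells[col].astype("category")
    return case


@pytest.fixture(scope="session")
def rendered_case() -> k.SyntheticCase:
    """One rendered 1×1 mm case (~2000 nuclei)."""
    return k.generate_case(compact_spec(2))


@pytest.fixture(scope="session")
def rendered_bank() -> list[k.SyntheticCase]:
    """Twenty rendered compact cases for the detection contract."""
    return [k.generate_case(compact_spec(seed)) for seed in range(20)]


@pytest.fixture(scope="session")
def default_bank() -> list[k.SyntheticCase]:
    """100 cell-level cases at the default 4×4 mm geometry and contrast."""
    return [_compact_cells(k.generate_case(k.SlideSpec(seed=seed), render=False))
            for seed in range(100)]


@pytest.fixture(scope="session")
def study100() -> k.StudyReport:
    """100-case study, rule + manual arms, cohort-heterogeneous positivity."""
    cfg = k.StudyConfig(n_cases=100, seed=7, arms=("rule", "manual"),
                        non_serial_fraction=0.0)
    return k.run_study(cfg)


@pytest.fixture(scope="session")
def vds_study() -> k.StudyReport:
    """15-case image study with both DIA arms; 4 cases are non-serial."""
    cfg = k.StudyConfig(
        n_cases=15, seed=11, non_serial_fraction=4 / 15,
        spec_overrides=dict(width_um=1500.0, height_um=1500.0,
                            hotspot_center_um=(700.0, 700.0),
                            benign_region_count=1, insitu_region_count=1),
        search_params=k.SearchParams(min_cells=500),
    )
    return k.run_study(cfg)


@pytest.fixture(scope="session")
def serial_pair() -> k.SyntheticCase:
    """Rendered serial pair with a known non-trivial transform."""
    return k.generate_case(registration_spec(
        3, serial_shift_um=(120.0, -80.0), serial_rotation_deg=1.0))


@pytest.fixture(scope="session")
def identity_pair() -> k.SyntheticCase:
    """Rendered serial pair with the identity transform."""
    return k.generate_case(registration_spec(
        7, serial_shift_um=(0.0, 0.0), serial_rotation_deg=0.0))


@pytest.fixture(scope="session")
def nonserial_pair() -> k.SyntheticCase:
    """Rendered pair whose CK section comes from an unrelated layout."""
    return k.generate_case(registration_spec(6, serial_mode="non_serial"))
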