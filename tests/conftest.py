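"""Shared fixtures: simulated panels at the sizes the checks need.

All panels are generated programmatically with fixed seeds; session scope
keeps the expensive ones to a single build per run.
"""
from __future__ import annotations

import numpy as np
import pytest

import gpbench as gp


@pytest.fixture(scope="session")
def small_panel() -> gp.GenotypePanel:
    """200 x 240 panel on 4 chromosomes for cheap unit tests."""
    return gp.simulate_panel(
        gp.PanelConfig(n_individuals=200, n_markers=240, n_chromosomes=4,
                       n_founder_haplotypes=60), seed=11)


@pytest.fixture(scope="session")
def bench_panel() -> gp.GenotypePanel:
    """Desk-scale benchmark panel: 2,600 x 3,000 on 10 chromosomes
    (2,000 fitting + validation, the rest test)."""
    return gp.simulate_panel(
        gp.PanelConfig(n_individuals=2600, n_markers=3000), seed=7)


@pytest.fixture(scope="session")
def bench_grm(bench_panel) -> gp.GRM:
    return gp.vanraden_grm(bench_panel)


@pytest.fixture(scope="session")
def big_n_panel() -> gp.GenotypePanel:
    """Many individuals, few markers: 10,000 x 300 for calibration checks
    whose precision scales with n."""
    return gp.simulate_panel(
        gp.PanelConfig(n_individuals=10_000, n_markers=300, n_chromosomes=3),
        seed=13)


@pytest.fixture(scope="session")
def corr_panel() -> gp.GenotypePanel:
    """5,000 x 1,200 panel for the correlated-trait calibration."""
    return gp.simulate_panel(
        gp.PanelConfig(n_individuals=5000, n_markers=1200), seed=17)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
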