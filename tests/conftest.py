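"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from cortical_continuum.preprocess import normalize_merfish, normalize_snrnaseq, qc_filter_cells
from cortical_continuum.simulate import (
    ContinuumSimParams,
    SpatialSectionSpec,
    simulate_archetype_mixture,
    simulate_continuum,
    simulate_cortical_section,
)


@pytest.fixture(scope="session")
def continuum_data():
    """The published continuum configuration (eps=0.2, 600x60, s=100)."""
    counts, truth = simulate_continuum(ContinuumSimParams(epsilon=0.2, seed=0))
    nm = normalize_snrnaseq(counts)
    return counts, nm, truth


@pytest.fixture(scope="session")
def mixture_data():
    """600 cells as uniform-Dirichlet mixtures of 3 archetype profiles."""
    counts, truth = simulate_archetype_mixture(600, 60, seed=0)
    X = np.asarray(counts.X, dtype=float)
    z = (X - X.mean(axis=0)) / X.std(axis=0)
    return counts, z, truth


@pytest.fixture(scope="session")
def section_data():
    """Default synthetic cortical section plus its normalized matrix."""
    counts, spatial, truth = simulate_cortical_section(SpatialSectionSpec(seed=0))
    iegs = [g for g in counts.var_names if g.startswith("ieg_")]
    nm = normalize_merfish(qc_filter_cells(counts), exclude=iegs)
    return counts, spatial, truth, nm


@pytest.fixture(scope="session")
def section_identity_sets(section_data):
    _, _, _, nm = section_data
    return {t: [g for g in nm.var_names if g.startswith(f"id{t}_")] for t in "ABC"}
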