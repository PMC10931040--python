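import dataclasses

import numpy as np
import pandas as pd
import pytest

from alkanir import (
    SpectraSet,
    default_design,
    default_library,
    select_model,
    simulate_study,
    stratified_split,
    treatment_grid,
)


def make_spectra(absorbance, wavenumbers=None, ids=None, groups=None) -> SpectraSet:
    """Small SpectraSet builder for unit tests."""
    absorbance = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n, p = absorbance.shape
    if wavenumbers is None:
        wavenumbers = np.arange(p, dtype=float)
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=absorbance,
        sample_ids=np.asarray(ids, dtype=object),
        diet_group=None if groups is None else np.asarray(groups, dtype=object),
    )


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def noiseless_design(design):
    return dataclasses.replace(
        design, analytic_cv={a: 0.0 for a in design.alkanes}
    )


@pytest.fixture(scope="session")
def study(design):
    """One default 48-hen study with spectra, fixed seed."""
    return simulate_study(design, seed=11)


@pytest.fixture(scope="session")
def noiseless_study(noiseless_design):
    """Zero analytic noise, concentrations only (exact mass-balance chain)."""
    return simulate_study(noiseless_design, seed=3, with_spectra=False)


@pytest.fixture(scope="session")
def clean_library():
    """Spectral library with every artifact switched off (noise-free forward model)."""
    return dataclasses.replace(
        default_library(), scatter_sd=0.0, baseline_coeffs_sd=(0.0, 0.0, 0.0), noise_sd=0.0
    )


@pytest.fixture(scope="session")
def selected_models(study):
    """Full treatment-grid model selection for the two alfalfa-dominated
    alkanes (the expensive search, shared across tests)."""
    grid = treatment_grid()
    groups = study.animals["diet_group"]
    out = {}
    for alkane in ("C29", "C31"):
        refs = study.excreta_lab[alkane]
        plan = stratified_split(refs, groups, seed=5)
        result, model = select_model(
            study.spectra, refs, plan, grid, a_max=10, alkane=alkane
        )
        out[alkane] = (plan, result, model)
    return out
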