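"""Split, NIPALS PLS, LOOCV, metrics, model selection, leakage guard."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from alkanir import (
    TreatmentSpec,
    external_validation,
    loocv,
    metrics,
    pls_fit,
    select_model,
    simulate_study,
    stratified_split,
)
from alkanir.calibration import break_ties, loocv_matrix, r2_pearson
from alkanir.preprocess import apply_treatment, fit_context, select_window
from alkanir.spectra import ALFALFA, CONTROL
from conftest import make_spectra


# ---------------------------------------------------------------- split

def test_split_sizes_and_quartile_structure(study):
    refs = study.excreta_lab["C29"]
    groups = study.animals["diet_group"]
    plan = stratified_split(refs, groups, seed=4)
    assert len(plan.calibration_ids) == 40
    assert len(plan.validation_ids) == 8
    assert set(plan.calibration_ids) | set(plan.validation_ids) == set(refs.index)
    for group in (CONTROL, ALFALFA):
        cells = plan.strata[group]
        assert len(cells) == 4
        chosen = [c["chosen"] for c in cells]
        assert len(set(chosen)) == 4
        for cell in cells:
            assert cell["chosen"] in cell["interval_ids"]
            assert len(cell["interval_ids"]) == 6  # 24 / 4


def test_split_determinism_and_seed_effect(study):
    refs = study.excreta_lab["C25"]
    groups = study.animals["diet_group"]
    p1 = stratified_split(refs, groups, seed=4)
    p2 = stratified_split(refs, groups, seed=4)
    assert list(p1.validation_ids) == list(p2.validation_ids)
    p3 = stratified_split(refs, groups, seed=5)
    for group in (CONTROL, ALFALFA):
        ids1 = [c["interval_ids"] for c in p1.strata[group]]
        ids3 = [c["interval_ids"] for c in p3.strata[group]]
        assert ids1 == ids3  # boundaries never move with the seed


def test_split_small_group_errors():
    refs = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    groups = pd.Series(["g"] * 3, index=refs.index)
    with pytest.raises(ValueError, match="needs >= 4"):
        stratified_split(refs, groups, seed=0)


# ---------------------------------------------------------------- PLS

def _random_xy(seed, n=20, p=8):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + 0.1 * rng.normal(size=n)
    return X, y


def test_first_weight_proportional_to_xty():
    X, y = _random_xy(0)
    model = pls_fit(X, y, 3)
    target = (X - X.mean(0)).T @ (y - y.mean())
    cos = model.weights[0] @ target / np.linalg.norm(target)
    assert cos == pytest.approx(1.0, abs=1e-10)


def test_exact_fit_when_y_linear_in_x():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(15, 6))
    y = X @ rng.normal(size=6)
    model = pls_fit(X, y, 6)
    resid = model.predict_matrix(X) - y
    assert np.max(np.abs(resid)) < 1e-8


def test_pls_equals_ols_at_full_rank():
    X, y = _random_xy(2, n=12, p=5)
    model = pls_fit(X, y, 5)
    Xc = X - X.mean(0)
    beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
    np.testing.assert_allclose(model.coefficients, beta, atol=1e-8)


def test_pls_matches_sklearn_nipals():
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X, y = _random_xy(3, n=25, p=10)
    ours = pls_fit(X, y, 4)
    ref = sklearn.PLSRegression(n_components=4, scale=False).fit(X, y)
    np.testing.assert_allclose(
        ours.predict_matrix(X), ref.predict(X).ravel(), atol=1e-8
    )


def test_pls_input_validation():
    X, _ = _random_xy(4, n=10, p=4)
    with pytest.raises(ValueError, match="zero variance"):
        pls_fit(X, np.ones(10), 2)
    with pytest.raises(ValueError, match="exceeds"):
        pls_fit(X, np.arange(10.0), 5)


def test_rmsec_monotone_in_components():
    X, y = _random_xy(5, n=30, p=12)
    model = pls_fit(X, y, 10)
    rmsec = [
        metrics(model.predict_matrix(X, a), y)[0] for a in range(1, 11)
    ]
    assert all(b <= a + 1e-12 for a, b in zip(rmsec, rmsec[1:]))


def test_rmsec_below_rmsecv_majority():
    """Training error below LOOCV error in most noisy replicates."""
    wins = 0
    for seed in range(20):
        X, y = _random_xy(100 + seed, n=18, p=6)
        model = pls_fit(X, y, 3)
        rmsec = metrics(model.predict_matrix(X, 3), y)[0]
        rmsecv = loocv_matrix(X, y, 3)[2]
        wins += rmsec < rmsecv
    assert wins >= 15


# ---------------------------------------------------------------- metrics

def test_metrics_hand_values():
    rmse, r2 = metrics([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
    assert rmse == pytest.approx(np.sqrt(1.0 / 3.0), abs=1e-12)
    assert r2 == pytest.approx(0.5, abs=1e-12)
    rmse, r2 = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert rmse == 0.0 and r2 == 1.0
    y = np.array([1.0, 2.0, 3.0])
    _, r2 = metrics(np.full(3, y.mean()), y)
    assert r2 == pytest.approx(0.0, abs=1e-12)


def test_metrics_zero_variance_flagged():
    with pytest.warns(UserWarning, match="zero variance"):
        _, r2 = metrics([1.0, 2.0], [5.0, 5.0])
    assert np.isnan(r2)
    assert r2_pearson([1.0, 2.0, 4.0], [1.0, 2.0, 3.0]) <= 1.0


# ---------------------------------------------------------------- LOOCV

def _toy_spectra_y(seed, n=10, p=40):
    rng = np.random.default_rng(seed)
    grid = np.arange(0.0, 2.0 * p, 2.0)
    bands = np.vstack(
        [np.exp(-0.5 * ((grid - c) / 8.0) ** 2) for c in (20.0, 40.0, 60.0)]
    )
    conc = rng.uniform(0.5, 2.0, size=(n, 3))
    x = conc @ bands + 0.05 * rng.normal(size=(n, 1)) + 0.01 * rng.normal(size=(n, p))
    y = conc[:, 1] + 0.02 * rng.normal(size=n)
    return make_spectra(x, wavenumbers=grid), pd.Series(y, index=[f"s{i}" for i in range(n)])


@pytest.mark.parametrize("treatment", [TreatmentSpec(2, 5, "SNV"), TreatmentSpec(0, 1, "MSC")])
def test_loocv_matches_brute_force_refit(treatment):
    """Independent fold loop (preprocessing refit per fold) agrees to 1e-12."""
    spectra, y = _toy_spectra_y(6)
    a_max = 3
    got = loocv(spectra, y, treatment, a_max)
    n = spectra.n_samples
    errs = np.zeros((a_max, n))
    for i in range(n):
        train_ids = [s for j, s in enumerate(spectra.sample_ids) if j != i]
        train = spectra.subset(train_ids)
        test = spectra.subset([spectra.sample_ids[i]])
        ctx = fit_context(train, treatment)
        Xtr = apply_treatment(train, treatment, ctx).absorbance
        Xte = apply_treatment(test, treatment, ctx).absorbance
        model = pls_fit(Xtr, y.loc[train_ids].to_numpy(), a_max)
        for a in range(1, a_max + 1):
            errs[a - 1, i] = (model.predict_matrix(Xte, a)[0] - y.iloc[i]) ** 2
    np.testing.assert_allclose(got, np.sqrt(errs.mean(axis=1)), atol=1e-12)


def test_loocv_noise_free_exact_recovery(noiseless_design, clean_library):
    """Noise-free linear spectra: RMSECV vanishes at sufficient components."""
    small = dataclasses.replace(noiseless_design, n_per_group=6)
    b = simulate_study(small, clean_library, seed=1)
    windowed = select_window(b.spectra, 4000, 7500)
    y = b.excreta_lab["C29"]
    rmsecv = loocv(windowed, y, TreatmentSpec(0, 1, "none"), 6)
    assert rmsecv.min() < 1e-6
    model = pls_fit(
        apply_treatment(windowed, TreatmentSpec(0, 1, "none")).absorbance,
        y.loc[windowed.sample_ids].to_numpy(),
        5,
    )
    rmsec, _ = metrics(
        model.predict_matrix(apply_treatment(windowed, TreatmentSpec(0, 1, "none")).absorbance),
        y.loc[windowed.sample_ids].to_numpy(),
    )
    assert rmsec < 1e-6


# ---------------------------------------------------------------- selection

def test_tie_breaking_rules():
    # equal RMSECV: fewer components win, then earlier grid position
    assert break_ties([(0.5, 3, 0), (0.5, 2, 1)]) == (0.5, 2, 1)
    assert break_ties([(0.5, 2, 1), (0.5, 2, 0)]) == (0.5, 2, 0)
    assert break_ties([(0.4, 9, 5), (0.5, 1, 0)]) == (0.4, 9, 5)


def test_selected_models_use_scatter_correction(selected_models):
    """Strong multiplicative scatter in the generator drives the search to a
    scatter-corrected treatment for the alfalfa-dominated alkanes."""
    for alkane in ("C29", "C31"):
        _, result, _ = selected_models[alkane]
        assert result.treatment.scatter in ("SNV", "MSC")


def test_candidate_log_is_exhaustive(selected_models):
    _, result, _ = selected_models["C29"]
    assert len(result.candidates) == 33 * 10
    assert result.rmsecv == pytest.approx(result.candidates["RMSECV"].min())


def test_parameter_recovery_high_variance_alkanes(selected_models):
    """The diet-sensitive alkanes calibrate well on default synthetic data."""
    for alkane in ("C29", "C31"):
        _, result, _ = selected_models[alkane]
        assert result.r2cv >= 0.7


def test_duplicate_treatment_resolves_by_grid_order(study):
    refs = study.excreta_lab["C25"]
    plan = stratified_split(refs, study.animals["diet_group"], seed=4)
    t = TreatmentSpec(2, 9, "SNV")
    result, _ = select_model(study.spectra, refs, plan, [t, t], a_max=2)
    assert result.treatment is t  # first grid entry wins the exact tie


# ---------------------------------------------------------------- validation

def test_external_validation_leakage_guard(selected_models, study):
    plan, _, model = selected_models["C29"]
    with pytest.raises(ValueError, match="overlap"):
        external_validation(
            model,
            study.spectra.subset(plan.calibration_ids[:4]),
            study.excreta_lab["C29"],
        )


def test_msc_reference_leakage_changes_predictions(selected_models, study):
    """Refitting the MSC reference on all samples (leaky) changes validation
    predictions on scattered spectra; the guard matters."""
    plan, result, model = selected_models["C29"]
    t = result.treatment
    if t.scatter != "MSC":  # the search picked SNV; force an MSC pipeline
        t = TreatmentSpec(2, 13, "MSC", t.order)
    windowed = select_window(study.spectra, *model.window)
    cal = windowed.subset(plan.calibration_ids)
    val = windowed.subset(plan.validation_ids)
    proper = apply_treatment(val, t, fit_context(cal, t)).absorbance
    leaky = apply_treatment(val, t, fit_context(windowed, t)).absorbance
    assert not np.allclose(proper, leaky)


def test_raw_rmsecv_worse_than_snv_derivative(study):
    """Scatter + baseline artifacts: raw-spectrum PLS loses to SNV + second
    derivative for the alkanes whose reference noise floor is low."""
    groups = study.animals["diet_group"]
    for alkane in ("C25", "C29", "C31"):
        refs = study.excreta_lab[alkane]
        plan = stratified_split(refs, groups, seed=5)
        cal = select_window(study.spectra, 4000, 7500).subset(plan.calibration_ids)
        raw = loocv(cal, refs, TreatmentSpec(0, 1, "none"), 10).min()
        corrected = loocv(cal, refs, TreatmentSpec(2, 13, "SNV"), 10).min()
        assert corrected < raw
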