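"""Recovery rates, excreta adjustment, NNLS mixing model, subset search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from alkanir import (
    adjust_excreta,
    combination_search,
    estimate_per_animal,
    evaluate_estimates,
    nnls_solve,
    proportion,
    recovery_rates,
    simulate_study,
)
from alkanir.spectra import ALFALFA, ALKANES, CONTROL


def _chain(bundle):
    """Lab-source recovery -> adjustment -> per-animal estimates."""
    groups = bundle.animals["diet_group"]
    rec = recovery_rates(
        bundle.animals["intake_g_dm_d"],
        bundle.animals["output_g_dm_d"],
        bundle.diet,
        bundle.excreta_lab,
        groups,
    )
    adjusted = adjust_excreta(bundle.excreta_lab, rec.group_means, groups)
    return rec, adjusted, estimate_per_animal(bundle.feed, bundle.alfalfa, adjusted)


# ---------------------------------------------------------------- recovery

def test_recovery_hand_value():
    ids = pd.Index(["a"], name="sample_id")
    rec = recovery_rates(
        pd.Series([100.0], index=ids),
        pd.Series([25.0], index=ids),
        pd.DataFrame({"C25": [8.0]}, index=ids),
        pd.DataFrame({"C25": [12.0]}, index=ids),
        pd.Series(["g"], index=ids),
    )
    assert rec.per_animal.loc["a", "C25"] == pytest.approx(0.375, abs=1e-12)


def test_recovery_identity_when_balanced():
    ids = pd.Index(["a", "b"], name="sample_id")
    rec = recovery_rates(
        pd.Series([100.0, 90.0], index=ids),
        pd.Series([20.0, 30.0], index=ids),
        pd.DataFrame({"C25": [5.0, 6.0]}, index=ids),
        pd.DataFrame({"C25": [25.0, 18.0]}, index=ids),  # output*E == intake*D
        pd.Series(["g", "g"], index=ids),
    )
    np.testing.assert_allclose(rec.per_animal["C25"], 1.0, rtol=1e-12)


def test_recovery_constant_truth_recovered_exactly(noiseless_design):
    forty = {a: 0.40 for a in ALKANES}
    d = dataclasses.replace(
        noiseless_design, true_recovery={CONTROL: dict(forty), ALFALFA: dict(forty)}
    )
    b = simulate_study(d, seed=4, with_spectra=False)
    rec, _, _ = _chain(b)
    np.testing.assert_allclose(rec.per_animal.to_numpy(), 0.40, rtol=1e-12)


def test_recovery_nonpositive_denominator_names_offender():
    ids = pd.Index(["a"], name="sample_id")
    with pytest.raises(ValueError, match="'a'.*'C25'"):
        recovery_rates(
            pd.Series([100.0], index=ids),
            pd.Series([25.0], index=ids),
            pd.DataFrame({"C25": [0.0]}, index=ids),
            pd.DataFrame({"C25": [12.0]}, index=ids),
            pd.Series(["g"], index=ids),
        )


# ---------------------------------------------------------------- adjustment

def test_adjust_unit_recovery_identity():
    ids = pd.Index(["a", "b"], name="sample_id")
    e = pd.DataFrame({"C25": [2.0, 3.0]}, index=ids)
    means = pd.DataFrame({"C25": [1.0]}, index=pd.Index(["g"], name="diet_group"))
    out = adjust_excreta(e, means, pd.Series(["g", "g"], index=ids))
    pd.testing.assert_frame_equal(out, e)


def test_adjust_divides_by_group_mean():
    ids = pd.Index(["a"], name="sample_id")
    e = pd.DataFrame({"C25": [2.0]}, index=ids)
    means = pd.DataFrame({"C25": [0.4]}, index=pd.Index(["g"], name="diet_group"))
    out = adjust_excreta(e, means, pd.Series(["g"], index=ids))
    assert out.loc["a", "C25"] == pytest.approx(5.0, abs=1e-12)


def test_adjust_missing_group_errors():
    ids = pd.Index(["a"], name="sample_id")
    e = pd.DataFrame({"C25": [2.0]}, index=ids)
    means = pd.DataFrame({"C25": [0.4]}, index=pd.Index(["other"], name="diet_group"))
    with pytest.raises(ValueError, match="missing recovery group"):
        adjust_excreta(e, means, pd.Series(["g"], index=ids))


# ---------------------------------------------------------------- NNLS

def test_nnls_recovers_consistent_mixture():
    rng = np.random.default_rng(0)
    f = rng.uniform(1.0, 5.0, size=5)
    a = rng.uniform(1.0, 5.0, size=5)
    x_f, x_a = nnls_solve(f, a, 0.3 * f + 0.7 * a)
    assert x_f == pytest.approx(0.3, abs=1e-10)
    assert x_a == pytest.approx(0.7, abs=1e-10)


def test_nnls_constraint_activation():
    rng = np.random.default_rng(1)
    f = rng.uniform(1.0, 5.0, size=5)
    a = rng.uniform(1.0, 5.0, size=5)
    e = -f  # unconstrained optimum would need x_f < 0
    x_f, x_a = nnls_solve(f, a, e)
    assert x_f == 0.0
    assert x_a == pytest.approx(max(0.0, float(a @ e) / float(a @ a)), abs=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nnls_matches_dense_grid_oracle(seed):
    """Lawson-Hanson solution beats every point of a dense (x_f, x_a) grid."""
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.2, 3.0, size=(5, 2))
    e = rng.uniform(0.0, 6.0, size=5)
    x_f, x_a = nnls_solve(m[:, 0], m[:, 1], e)

    step = 2e-3
    g = np.arange(0.0, 3.0 + step / 2, step)
    gram = m.T @ m
    lin = m.T @ e
    xf_grid, xa_grid = np.meshgrid(g, g, indexing="ij")
    obj = (
        gram[0, 0] * xf_grid**2
        + 2 * gram[0, 1] * xf_grid * xa_grid
        + gram[1, 1] * xa_grid**2
        - 2 * (lin[0] * xf_grid + lin[1] * xa_grid)
    )
    best = np.unravel_index(np.argmin(obj), obj.shape)
    obj_nnls = (
        gram[0, 0] * x_f**2 + 2 * gram[0, 1] * x_f * x_a + gram[1, 1] * x_a**2
        - 2 * (lin[0] * x_f + lin[1] * x_a)
    )
    assert obj_nnls <= obj[best] + 1e-9
    if x_f < 3.0 and x_a < 3.0:
        assert abs(x_f - g[best[0]]) <= 2 * step
        assert abs(x_a - g[best[1]]) <= 2 * step


def test_nnls_input_validation():
    with pytest.raises(ValueError, match=">= 2"):
        nnls_solve([1.0], [1.0], [1.0])
    with pytest.raises(ValueError, match="both zero"):
        nnls_solve([0.0, 0.0], [0.0, 0.0], [1.0, 1.0])
    with pytest.warns(UserWarning, match="collinear"):
        nnls_solve([1.0, 2.0], [2.0, 4.0], [1.0, 1.0])


# ---------------------------------------------------------------- proportion

def test_proportion_values():
    assert proportion(1.0, 0.0) == 0.0
    assert proportion(1.0, 1.0) == 0.5
    assert proportion(0.99, 0.01) == pytest.approx(0.01, abs=1e-12)
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(proportion(0.0, 0.0))


# ---------------------------------------------------------------- summaries

def test_evaluate_estimates_degenerate():
    m = evaluate_estimates([0.5, 0.5, 0.5], 0.5)
    assert m.mean == 0.5 and m.rmse == 0.0 and m.bias == 0.0 and m.var == 0.0


def test_evaluate_estimates_identity_random():
    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, size=24)
    m = evaluate_estimates(p, 0.4)
    assert m.rmse**2 - m.bias**2 - m.var == pytest.approx(0.0, abs=1e-12)
    assert m.bias == pytest.approx(p.mean() - 0.4, abs=1e-12)


def test_evaluate_estimates_excludes_missing():
    with pytest.warns(UserWarning, match="excluded"):
        m = evaluate_estimates([0.5, np.nan, 0.7], 0.6)
    assert m.n == 2 and m.n_missing == 1


# ---------------------------------------------------------------- end to end

def test_zero_noise_chain_recovers_inclusion_exactly(noiseless_study):
    b = noiseless_study
    groups = b.animals["diet_group"]
    _, adjusted, est = _chain(b)
    control = est.loc[groups[groups == CONTROL].index, "p"]
    mixed = est.loc[groups[groups == ALFALFA].index, "p"]
    assert control.abs().max() < 1e-10
    assert (mixed - b.design.alfalfa_inclusion).abs().max() < 1e-10


def test_combination_search_structure_and_zero_noise(noiseless_study):
    b = noiseless_study
    groups = b.animals["diet_group"]
    _, adjusted, _ = _chain(b)
    mixed = groups[groups == ALFALFA].index
    table = combination_search(
        b.feed, b.alfalfa, adjusted.loc[mixed], b.design.alfalfa_inclusion
    )
    assert len(table) == 26  # C(5,2)+C(5,3)+C(5,4)+C(5,5)
    labels = set(table["subset"])
    for wanted in ("C25-C27-C29-C31-C33", "C25-C27-C29-C33", "C25-C29-C33", "C25-C29"):
        assert wanted in labels
    assert table["RMSE"].max() < 1e-12
    assert list(table["RMSE"]) == sorted(table["RMSE"])


def test_noise_monotonicity(design):
    """Scaling the analytic CVs up never lowers the median full-subset RMSE."""
    medians = []
    for factor in (0.5, 1.0, 3.0):
        d = dataclasses.replace(
            design, analytic_cv={a: factor * v for a, v in design.analytic_cv.items()}
        )
        rmses = []
        for seed in range(20):
            b = simulate_study(d, seed=300 + seed, with_spectra=False)
            groups = b.animals["diet_group"]
            _, _, est = _chain(b)
            mixed = est.loc[groups[groups == ALFALFA].index, "p"]
            m = evaluate_estimates(mixed.to_numpy(), d.alfalfa_inclusion)
            rmses.append(m.rmse)
        medians.append(np.median(rmses))
    assert medians[0] <= medians[1] <= medians[2]
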