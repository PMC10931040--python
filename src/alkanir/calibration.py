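"""PLS calibration of excreta spectra against reference alkane concentrations.

Covers the stratified calibration/validation split, NIPALS PLS1 regression,
leave-one-out cross-validation with the full learnable pipeline refit inside
each fold, external validation with a leakage guard, and the per-alkane model
selection across the preprocessing treatment grid.

Conventions: RMSE uses divisor n on every set (calibration, CV, external) for
cross-set comparability; R^2 is the coefficient of determination
1 - SS_res/SS_tot with the mean taken on the evaluation set itself (a squared
Pearson variant is available separately).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    PreprocessContext,
    TreatmentSpec,
    apply_treatment,
    fit_context,
    select_window,
)
from .spectra import SpectraSet

DEFAULT_WINDOW = (4000.0, 7500.0)


# ----------------------------------------------------------------------------
# stratified calibration/validation split
# ----------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Calibration/validation split stratified by diet group and reference
    quartile: within each group samples are ranked by reference value, cut
    into ``n_intervals`` equal-count intervals, and one id per interval is
    drawn into the validation set."""

    calibration_ids: np.ndarray
    validation_ids: np.ndarray
    strata: dict            # group -> list of (interval_ids, chosen_id)
    seed: int


def stratified_split(
    refs: pd.Series, groups: pd.Series, n_intervals: int = 4, seed: int = 0
) -> SplitPlan:
    """Split samples into calibration and validation sets.

    ``refs`` are the reference concentrations (index = sample ids), ``groups``
    the diet label per sample.  Sorting is stable, remainders go to the lower
    intervals, and the same seed always reproduces the same plan.
    """
    refs = refs.astype(float)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    strata: dict = {}
    validation: list = []
    for group in sorted(groups.unique()):
        ids = refs.index[groups.loc[refs.index] == group]
        if len(ids) < n_intervals:
            raise ValueError(
                f"group {group!r} has {len(ids)} samples, needs >= {n_intervals}"
            )
        order = np.argsort(refs.loc[ids].to_numpy(), kind="stable")
        ranked = np.asarray(ids, dtype=object)[order]
        base, rem = divmod(len(ranked), n_intervals)
        sizes = [base + 1 if k < rem else base for k in range(n_intervals)]
        cells = []
        start = 0
        for size in sizes:
            interval = list(ranked[start : start + size])
            chosen = interval[int(rng.integers(len(interval)))]
            cells.append({"interval_ids": interval, "chosen": chosen})
            validation.append(chosen)
            start += size
        strata[group] = cells
    validation = np.asarray(validation, dtype=object)
    calibration = np.asarray(
        [s for s in refs.index if s not in set(validation)], dtype=object
    )
    return SplitPlan(
        calibration_ids=calibration,
        validation_ids=validation,
        strata=strata,
        seed=seed,
    )


# ----------------------------------------------------------------------------
# NIPALS PLS1
# ----------------------------------------------------------------------------

@dataclass
class PLSModel:
    """PLS1 regression model with per-component coefficient paths.

    ``coef_path[A-1]`` is the coefficient vector using the first A components;
    prediction is ``y_mean + (x - x_mean) @ coef_path[n_components - 1]``.
    ``n_components_effective`` may be smaller than requested when the residual
    degenerates (exact fit reached); coefficient paths beyond it are constant.
    """

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (A_eff, p)
    x_loadings: np.ndarray    # (A_eff, p)
    y_loadings: np.ndarray    # (A_eff,)
    coef_path: np.ndarray     # (a_max, p)
    n_components: int
    n_components_effective: int
    treatment: TreatmentSpec | None = None
    ctx: PreprocessContext | None = None
    window: tuple | None = None
    calibration_ids: np.ndarray | None = None

    @property
    def coefficients(self) -> np.ndarray:
        return self.coef_path[self.n_components - 1]

    def predict_matrix(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        return self.y_mean + (np.asarray(X, dtype=float) - self.x_mean) @ self.coef_path[a - 1]

    def predict(self, spectra: SpectraSet) -> np.ndarray:
        """Predict from raw spectra, applying the stored window and treatment."""
        if self.treatment is None or self.window is None:
            raise ValueError("model carries no preprocessing pipeline")
        s = select_window(spectra, *self.window)
        s = apply_treatment(s, self.treatment, self.ctx)
        return self.predict_matrix(s.absorbance)


def _nipals(Xc: np.ndarray, yc: np.ndarray, a_max: int):
    """NIPALS for a single response on pre-centered data (deterministic)."""
    n, p = Xc.shape
    cap = min(a_max, n - 1, p)
    X = Xc.copy()
    y = yc.copy()
    scale = max(float(np.abs(Xc).max()) * float(np.abs(yc).max()), 1e-300)
    W, P, Q, R = [], [], [], []
    coef = np.zeros(p)
    coef_path = np.zeros((a_max, p))
    a_eff = 0
    for a in range(cap):
        w = X.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= 1e-13 * scale:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= 1e-26 * scale:
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        r = w.copy()
        for pj, rj in zip(P, R):
            r -= float(pj @ w) * rj
        W.append(w)
        P.append(p_a)
        Q.append(q_a)
        R.append(r)
        coef = coef + q_a * r
        coef_path[a] = coef
        a_eff = a + 1
    for a in range(a_eff, a_max):
        coef_path[a] = coef
    return (
        np.asarray(W).reshape(a_eff, p),
        np.asarray(P).reshape(a_eff, p),
        np.asarray(Q),
        coef_path,
        a_eff,
    )


def pls_fit(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 (NIPALS) on mean-centered X and y, no variance scaling."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1, p)="
            f"{min(X.shape[0] - 1, X.shape[1])}"
        )
    if np.var(y) == 0:
        raise ValueError("y has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, coef_path, a_eff = _nipals(X - x_mean, y - y_mean, n_components)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        coef_path=coef_path,
        n_components=n_components,
        n_components_effective=a_eff,
    )


# ----------------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------------

def metrics(yhat: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(RMSE, R^2) with RMSE divisor n and R^2 = 1 - SS_res/SS_tot.

    The mean in SS_tot comes from the evaluation set itself.  Zero variance in
    ``y`` leaves R^2 undefined (NaN, with a warning).
    """
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if yhat.shape != y.shape or y.size < 2:
        raise ValueError("metrics requires two equal-length vectors of size >= 2")
    ss_res = float(np.sum((yhat - y) ** 2))
    rmse = float(np.sqrt(ss_res / y.size))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("R^2 undefined: zero variance in reference values")
        return rmse, float("nan")
    return rmse, 1.0 - ss_res / ss_tot


def r2_pearson(yhat: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation (alternative R^2 reading)."""
    yhat = np.asarray(yhat, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    return float(np.corrcoef(yhat, y)[0, 1] ** 2)


# ----------------------------------------------------------------------------
# leave-one-out cross-validation
# ----------------------------------------------------------------------------

def loocv(
    spectra: SpectraSet, y: pd.Series, treatment: TreatmentSpec, a_max: int
) -> np.ndarray:
    """RMSECV for each component count 1..a_max.

    ``spectra`` must already be restricted to the calibration samples and the
    spectral window.  For every left-out sample the entire learnable pipeline
    (MSC reference, centering, PLS) is refit on the remaining samples.
    Treatments whose preprocessing learns nothing from the data (SNV, plain
    derivative) are transformed once up front — per-spectrum operations give
    identical fold results.
    """
    y_arr = y.loc[spectra.sample_ids].to_numpy(dtype=float)
    n = spectra.n_samples
    sq_err = np.zeros((a_max, n))
    if treatment.scatter != "MSC":
        X = apply_treatment(spectra, treatment).absorbance
        for i in range(n):
            keep = np.arange(n) != i
            model = pls_fit(X[keep], y_arr[keep], min(a_max, n - 2, X.shape[1]))
            for a in range(1, a_max + 1):
                pred = model.predict_matrix(X[i][None, :], min(a, model.coef_path.shape[0]))
                sq_err[a - 1, i] = (pred[0] - y_arr[i]) ** 2
    else:
        ids = spectra.sample_ids
        for i in range(n):
            train = spectra.subset([s for j, s in enumerate(ids) if j != i])
            test = spectra.subset([ids[i]])
            ctx = fit_context(train, treatment)
            Xtr = apply_treatment(train, treatment, ctx).absorbance
            Xte = apply_treatment(test, treatment, ctx).absorbance
            model = pls_fit(Xtr, y_arr[np.arange(n) != i], min(a_max, n - 2, Xtr.shape[1]))
            for a in range(1, a_max + 1):
                pred = model.predict_matrix(Xte, min(a, model.coef_path.shape[0]))
                sq_err[a - 1, i] = (pred[0] - y_arr[i]) ** 2
    return np.sqrt(sq_err.mean(axis=1))


def loocv_matrix(X: np.ndarray, y: np.ndarray, a_max: int) -> np.ndarray:
    """LOOCV on a fixed preprocessed matrix (no learnable preprocessing)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    sq_err = np.zeros((a_max, n))
    for i in range(n):
        keep = np.arange(n) != i
        cap = min(a_max, n - 2, X.shape[1])
        model = pls_fit(X[keep], y[keep], cap)
        for a in range(1, a_max + 1):
            pred = model.predict_matrix(X[i][None, :], min(a, cap))
            sq_err[a - 1, i] = (pred[0] - y[i]) ** 2
    return np.sqrt(sq_err.mean(axis=1))


# ----------------------------------------------------------------------------
# model selection and external validation
# ----------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Per-alkane outcome of the treatment-grid search."""

    alkane: str
    treatment: TreatmentSpec
    n_components: int
    rmsec: float
    r2c: float
    rmsecv: float
    r2cv: float
    rmsev: float
    r2v: float
    candidates: pd.DataFrame = field(repr=False, default=None)

    def to_row(self) -> dict:
        return {
            "alkane": self.alkane,
            "treatment": self.treatment.code,
            "components": self.n_components,
            "RMSEC": self.rmsec,
            "R2c": self.r2c,
            "RMSECV": self.rmsecv,
            "R2cv": self.r2cv,
            "RMSEV": self.rmsev,
            "R2v": self.r2v,
        }


def break_ties(candidates) -> tuple:
    """Pick the minimal (RMSECV, components, grid_index) candidate.

    Ties on RMSECV break toward fewer components, then earlier grid order.
    """
    return min(candidates)


def external_validation(
    model: PLSModel, spectra: SpectraSet, refs: pd.Series
) -> tuple[float, float]:
    """Metrics on untouched samples; errors out on calibration overlap."""
    if model.calibration_ids is not None:
        overlap = set(spectra.sample_ids) & set(model.calibration_ids)
        if overlap:
            raise ValueError(f"validation samples overlap calibration set: {sorted(overlap)}")
    yhat = model.predict(spectra)
    return metrics(yhat, refs.loc[spectra.sample_ids].to_numpy(dtype=float))


def select_model(
    spectra: SpectraSet,
    refs: pd.Series,
    plan: SplitPlan,
    grid: list[TreatmentSpec],
    a_max: int = 10,
    alkane: str = "",
    window: tuple = DEFAULT_WINDOW,
) -> tuple[CalibrationResult, PLSModel]:
    """Exhaustive treatment x component-count search by minimum RMSECV.

    Ties break by fewer components, then by grid order.  The winning pipeline
    is refit on all calibration samples, and reported with calibration,
    cross-validation and external-validation statistics.
    """
    if not grid:
        raise ValueError("treatment grid is empty")
    windowed = select_window(spectra, *window)
    cal = windowed.subset(plan.calibration_ids)
    y_cal = refs.loc[plan.calibration_ids].astype(float)

    rows = []
    candidates = []  # (rmsecv, n_components, grid_index)
    for gi, t in enumerate(grid):
        rmsecv = loocv(cal, y_cal, t, a_max)
        for a in range(1, a_max + 1):
            rows.append({"treatment": t.code, "components": a, "RMSECV": rmsecv[a - 1]})
            candidates.append((float(rmsecv[a - 1]), a, gi))
    rmsecv_best, n_comp, gi_best = break_ties(candidates)
    t_best = grid[gi_best]

    ctx = fit_context(cal, t_best)
    X_cal = apply_treatment(cal, t_best, ctx).absorbance
    y_arr = y_cal.loc[cal.sample_ids].to_numpy(dtype=float)
    model = pls_fit(X_cal, y_arr, n_comp)
    model.treatment = t_best
    model.ctx = ctx
    model.window = tuple(window)
    model.calibration_ids = np.asarray(plan.calibration_ids, dtype=object)

    rmsec, r2c = metrics(model.predict_matrix(X_cal), y_arr)
    ss_tot = float(np.sum((y_arr - y_arr.mean()) ** 2))
    r2cv = 1.0 - len(y_arr) * rmsecv_best**2 / ss_tot

    # external path goes through the raw-spectra predict (stored window,
    # treatment and context), guarding against calibration overlap
    rmsev, r2v = external_validation(model, spectra.subset(plan.validation_ids), refs)

    result = CalibrationResult(
        alkane=alkane,
        treatment=t_best,
        n_components=n_comp,
        rmsec=rmsec,
        r2c=r2c,
        rmsecv=float(rmsecv_best),
        r2cv=float(r2cv),
        rmsev=float(rmsev),
        r2v=float(r2v),
        candidates=pd.DataFrame(rows),
    )
    return result, model
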