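"""Spectral preprocessing: window selection, SNV, MSC, Savitzky-Golay second
derivative, and the treatment grid the calibration search iterates over.

A treatment is encoded the way chemometric reports write it: a math-treatment
code ``d,w1,w2`` (derivative order, first smoothing window, second smoothing —
always 1 here) plus a scatter-correction name, e.g. ``"2,13,1+SNV"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectraSet

SCATTER_OPTIONS = ("none", "SNV", "MSC")
SG_WINDOWS = tuple(range(3, 22, 2))  # odd smoothing windows 3..21


@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the preprocessing grid.

    deriv_order 0 (none) or 2; ``window`` is the Savitzky-Golay smoothing
    window in points (odd, 3-21; ignored when deriv_order == 0); ``scatter``
    one of none/SNV/MSC; ``order`` whether scatter correction is applied
    before or after the derivative.
    """

    deriv_order: int = 0
    window: int = 1
    scatter: str = "none"
    order: str = "scatter_first"

    def __post_init__(self):
        if self.deriv_order not in (0, 2):
            raise ValueError("deriv_order must be 0 or 2")
        if self.deriv_order == 2 and (
            self.window % 2 == 0 or not 3 <= self.window <= 21
        ):
            raise ValueError("window must be odd and in 3..21 for a second derivative")
        if self.scatter not in SCATTER_OPTIONS:
            raise ValueError(f"scatter must be one of {SCATTER_OPTIONS}")
        if self.order not in ("scatter_first", "derivative_first"):
            raise ValueError("order must be scatter_first or derivative_first")

    @property
    def code(self) -> str:
        """Report code, e.g. '2,13,1+SNV' or '0,1,1'."""
        base = f"{self.deriv_order},{self.window if self.deriv_order else 1},1"
        return base if self.scatter == "none" else f"{base}+{self.scatter}"


@dataclass
class PreprocessContext:
    """Quantities learned from calibration samples only (prevents leakage).

    Holds the MSC reference spectrum (mean calibration spectrum at the stage
    where MSC is applied); absent for treatments without MSC.
    """

    msc_reference: np.ndarray | None = None
    fitted: bool = False


def select_window(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Retain exactly the grid points with lo <= wavenumber <= hi."""
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    keep = (spectra.wavenumbers >= lo) & (spectra.wavenumbers <= hi)
    if not keep.any():
        raise ValueError(f"window [{lo}, {hi}] retains no grid points")
    return spectra.with_absorbance(
        spectra.absorbance[:, keep], wavenumbers=spectra.wavenumbers[keep]
    )


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum to mean 0, sample SD 1 (n-1)."""
    x = spectra.absorbance
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        raise ValueError(
            f"SNV undefined for constant spectrum: {list(spectra.sample_ids[zero])}"
        )
    return spectra.with_absorbance((x - mean) / sd)


def msc_fit(calibration_spectra: SpectraSet) -> PreprocessContext:
    """Learn the MSC reference (mean calibration spectrum)."""
    return PreprocessContext(
        msc_reference=calibration_spectra.absorbance.mean(axis=0), fitted=True
    )


def msc_apply(spectra: SpectraSet, ctx: PreprocessContext) -> SpectraSet:
    """Per spectrum OLS fit s = a + b*r against the reference; corrected (s-a)/b."""
    if not ctx.fitted or ctx.msc_reference is None:
        raise ValueError("MSC context not fitted")
    r = ctx.msc_reference
    if r.shape[0] != spectra.absorbance.shape[1]:
        raise ValueError("MSC reference grid length does not match spectra")
    rc = r - r.mean()
    denom = float(rc @ rc)
    s = spectra.absorbance
    b = (s - s.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < 1e-12):
        bad = spectra.sample_ids[np.abs(b) < 1e-12]
        raise ValueError(f"degenerate MSC slope for samples: {list(bad)}")
    a = s.mean(axis=1) - b * r.mean()
    return spectra.with_absorbance((s - a[:, None]) / b[:, None])


def sg_second_derivative(spectra: SpectraSet, window: int, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay second derivative, scaled by 1/step^2 via ``delta``.

    Edges are trimmed, not padded: the output grid loses (window-1)/2 points
    at each end so no fabricated values enter the regression.
    """
    if window % 2 == 0 or not 3 <= window <= 21:
        raise ValueError("window must be odd and in 3..21")
    step = spectra.step
    d2 = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder, deriv=2,
        delta=step, axis=1,
    )
    half = (window - 1) // 2
    return spectra.with_absorbance(
        d2[:, half:-half], wavenumbers=spectra.wavenumbers[half:-half]
    )


def fit_context(calibration_spectra: SpectraSet, t: TreatmentSpec) -> PreprocessContext:
    """Fit the learnable part of a treatment on calibration spectra only.

    For MSC the reference is the mean calibration spectrum at the stage where
    MSC acts (raw for scatter_first, derivative for derivative_first).
    """
    if t.scatter != "MSC":
        return PreprocessContext(fitted=True)
    stage = calibration_spectra
    if t.order == "derivative_first" and t.deriv_order == 2:
        stage = sg_second_derivative(stage, t.window)
    return msc_fit(stage)


def apply_treatment(
    spectra: SpectraSet, t: TreatmentSpec, ctx: PreprocessContext | None = None
) -> SpectraSet:
    """Compose scatter correction and derivative in the order ``t.order``.

    Window selection is not part of the treatment; callers apply it first.
    """
    if t.scatter == "MSC" and (ctx is None or not ctx.fitted):
        raise ValueError("MSC treatment requires a fitted PreprocessContext")

    def scatter(s: SpectraSet) -> SpectraSet:
        if t.scatter == "SNV":
            return snv(s)
        if t.scatter == "MSC":
            return msc_apply(s, ctx)
        return s

    def derivative(s: SpectraSet) -> SpectraSet:
        if t.deriv_order == 2:
            return sg_second_derivative(s, t.window)
        return s

    if t.order == "scatter_first":
        return derivative(scatter(spectra))
    return scatter(derivative(spectra))


def treatment_grid(order: str = "scatter_first") -> list[TreatmentSpec]:
    """The 33-cell search grid: {none, SNV, MSC} x {no derivative, (2, w) for
    odd w in 3..21}; deterministic order (scatter-major)."""
    grid = []
    for scatter in SCATTER_OPTIONS:
        grid.append(TreatmentSpec(deriv_order=0, window=1, scatter=scatter, order=order))
        for w in SG_WINDOWS:
            grid.append(TreatmentSpec(deriv_order=2, window=w, scatter=scatter, order=order))
    return grid
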