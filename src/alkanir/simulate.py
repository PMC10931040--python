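"""Synthetic study generator: concentrations, intakes/outputs, spectra, truth.

Emulates a marker study on 48 laying hens in two diet groups (24 on a
commercial feed, 24 on the same feed with a 1% alfalfa inclusion).  Five
odd-chain plant-wax n-alkanes (C25..C33) act as dietary markers.  The
generative chain is an exact mass balance

    output_a * E[i, a] = intake_a * D[i, a] * R[i, g(a)]

where ``D = (1 - q) * F + q * A`` is the diet concentration (alfalfa replacing
feed mass), ``R`` the marker recovery fraction per alkane and diet group, and
``E`` the true excreta concentration.  A multiplicative lognormal "laboratory"
term with per-alkane CV stands in for analytic error plus residual
animal-level variation; it is the only per-alkane noise source, so at zero
analytic CV every downstream identity (recovery inversion, NNLS proportion
recovery) is exact.

Default feed/alfalfa profiles and analytic CVs are solved in closed form so
that the pooled excreta concentrations (n = 48) reproduce the target marginal
means/SDs of the emulated study population, with the alfalfa group elevated in
C29/C31 (the bimodality that drives those alkanes' large pooled SDs).

NIR spectra are a linear forward model: per-alkane Gaussian absorption bands
in the C-H combination/first-overtone regions plus a common matrix background,
distorted by a per-sample multiplicative scatter factor, a random quadratic
baseline, and white noise — the artifacts that scatter correction and the
second derivative are meant to remove.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import ALKANES, ALFALFA, CONTROL, SpectraSet, write_alkane_csv

# Pooled excreta concentration targets (mg/kg DM): mean, SD over both groups.
EXCRETA_TARGETS = {
    "C25": (1.98, 0.18),
    "C27": (2.46, 0.39),
    "C29": (4.97, 2.21),
    "C31": (4.71, 2.87),
    "C33": (1.76, 0.33),
}

# Recovery fractions per alkane, per diet group (fecal-marker mass balance).
RECOVERY_CONTROL = {"C25": 0.439, "C27": 0.369, "C29": 0.302, "C31": 0.297, "C33": 0.339}
RECOVERY_ALFALFA = {"C25": 0.479, "C27": 0.375, "C29": 0.372, "C31": 0.437, "C33": 0.409}

# Chosen between-group half-separations (mg/kg DM) for the alkanes whose
# pooled distribution stays unimodal; C29/C31 separations are solved from the
# pooled-SD budget instead (alfalfa dominates those two).
_UNIMODAL_HALF_SHIFT = {"C25": 0.08, "C27": 0.15, "C33": 0.17}

# Analytic CV for the two alfalfa-dominated alkanes; the other three are
# solved from the pooled-SD budget.
_BIMODAL_ANALYTIC_CV = 0.03


@dataclass
class StudyDesign:
    """Parameters of the simulated feeding study.

    All concentrations in mg/kg DM, intakes/outputs in g DM/day.
    ``true_recovery[group][alkane]`` is the marker recovery fraction in (0, 1];
    ``analytic_cv[alkane]`` the relative SD of the simulated laboratory
    concentration measurement (aggregating analytic and residual animal
    variation).
    """

    n_per_group: int = 24
    alkanes: tuple = ALKANES
    feed_profile: dict = field(default_factory=dict)
    alfalfa_profile: dict = field(default_factory=dict)
    alfalfa_inclusion: float = 0.01
    true_recovery: dict = field(default_factory=dict)
    intake_mean_sd: tuple = (110.0, 5.0)
    output_mean_sd: tuple = (30.0, 1.2)
    analytic_cv: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> "StudyDesign":
        if self.n_per_group < 5:
            raise ValueError("n_per_group must be >= 5 (4 strata plus 1)")
        if not 0.0 <= self.alfalfa_inclusion < 1.0:
            raise ValueError("alfalfa_inclusion must be in [0, 1)")
        for prof, name in ((self.feed_profile, "feed"), (self.alfalfa_profile, "alfalfa")):
            for a in self.alkanes:
                if prof.get(a, 0.0) < 0:
                    raise ValueError(f"{name} concentration for {a} must be >= 0")
        for group, rec in self.true_recovery.items():
            for a, r in rec.items():
                if not 0.0 < r <= 1.0:
                    raise ValueError(f"recovery {group}/{a} must be in (0, 1]")
        for a, cv in self.analytic_cv.items():
            if cv < 0:
                raise ValueError(f"analytic_cv for {a} must be >= 0")
        return self


def _ratio_moments(design: StudyDesign) -> tuple[float, float]:
    """Mean and squared CV of the intake/output ratio (second-order delta)."""
    mi, si = design.intake_mean_sd
    mo, so = design.output_mean_sd
    cvi2 = (si / mi) ** 2
    cvo2 = (so / mo) ** 2
    r_mean = (mi / mo) * (1.0 + cvo2)
    cv_r2 = (1.0 + cvi2) * (1.0 + 3.0 * cvo2) / (1.0 + cvo2) ** 2 - 1.0
    return r_mean, cv_r2


def default_design(targets: dict = EXCRETA_TARGETS, seed: int = 0) -> StudyDesign:
    """Design whose pooled excreta statistics match the study targets.

    Feed/alfalfa profiles and per-alkane analytic CVs are solved in closed
    form from the target pooled means/SDs given the recovery fractions and the
    intake/output distributions.  For C29/C31 the between-group separation is
    solved from the SD budget at a 3% analytic CV; for C25/C27/C33 a small
    fixed separation is imposed and the analytic CV absorbs the remaining
    within-group variance.
    """
    design = StudyDesign(seed=seed)
    q = design.alfalfa_inclusion
    r_mean, cv_r2 = _ratio_moments(design)

    feed, alfalfa, cvs = {}, {}, {}
    for a in design.alkanes:
        mean_t, sd_t = targets[a]
        if a in _UNIMODAL_HALF_SHIFT:
            delta = _UNIMODAL_HALF_SHIFT[a]
            cv_w2 = (sd_t**2 - delta**2) / (mean_t**2 + delta**2)
            cv_a2 = (1.0 + cv_w2) / (1.0 + cv_r2) - 1.0
            if cv_a2 < 0:
                raise ValueError(
                    f"{a}: intake/output variability alone exceeds the SD target"
                )
            cvs[a] = float(np.sqrt(cv_a2))
        else:
            cvs[a] = _BIMODAL_ANALYTIC_CV
            cv_w2 = (1.0 + cv_r2) * (1.0 + cvs[a] ** 2) - 1.0
            delta = float(
                np.sqrt((sd_t**2 - cv_w2 * mean_t**2) / (1.0 + cv_w2))
            )
        mu_c, mu_m = mean_t - delta, mean_t + delta
        rc = RECOVERY_CONTROL[a]
        rm = RECOVERY_ALFALFA[a]
        feed[a] = mu_c / (r_mean * rc)
        alfalfa[a] = ((mu_m / (r_mean * rm)) - (1.0 - q) * feed[a]) / q
        if alfalfa[a] < 0:
            raise ValueError(f"{a}: solved alfalfa concentration negative")

    design.feed_profile = feed
    design.alfalfa_profile = alfalfa
    design.true_recovery = {
        CONTROL: dict(RECOVERY_CONTROL),
        ALFALFA: dict(RECOVERY_ALFALFA),
    }
    design.analytic_cv = cvs
    return design.validate()


@dataclass
class SpectralLibrary:
    """Forward model of the NIR spectrometer output.

    ``component_bands[alkane]`` is a list of Gaussian bands
    (center cm^-1, width cm^-1, amplitude per mg/kg DM); ``matrix_bands`` are
    background bands common to all samples (amplitude in absorbance units).
    Per-sample artifacts: quadratic baseline with coefficient SDs
    ``baseline_coeffs_sd`` (on a grid normalised to [-1, 1]), log-multiplicative
    scatter with SD ``scatter_sd``, and additive white noise ``noise_sd``.
    """

    grid: np.ndarray = field(
        default_factory=lambda: np.arange(4000.0, 10000.0 + 1e-9, 2.0)
    )
    component_bands: dict = field(default_factory=dict)
    matrix_bands: list = field(default_factory=list)
    baseline_coeffs_sd: tuple = (0.01, 0.005, 0.002)
    scatter_sd: float = 0.05
    noise_sd: float = 2e-5

    def validate(self) -> "SpectralLibrary":
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        lo, hi = self.grid[0], self.grid[-1]
        for a, bands in self.component_bands.items():
            for c, w, amp in bands:
                if not lo <= c <= hi:
                    raise ValueError(f"band center {c} for {a} outside grid [{lo}, {hi}]")
                if w <= 0:
                    raise ValueError(f"band width must be > 0 ({a})")
                if amp < 0:
                    raise ValueError(f"band amplitude must be >= 0 ({a})")
        for c, w, amp in self.matrix_bands:
            if not lo <= c <= hi:
                raise ValueError(f"matrix band center {c} outside grid")
            if w <= 0:
                raise ValueError("matrix band width must be > 0")
        return self


def default_library() -> SpectralLibrary:
    """Bands in the C-H combination (~4200-4400) and first-overtone
    (~5600-6100) regions; each alkane gets three shifted Gaussians so the five
    signatures are linearly independent."""
    centers = {"C25": 0.0, "C27": 35.0, "C29": 70.0, "C31": 105.0, "C33": 140.0}
    bands = {
        a: [
            (4250.0 + off, 30.0, 3.0e-3),
            (5650.0 + off, 35.0, 4.0e-3),
            (5900.0 + off, 28.0, 2.0e-3),
        ]
        for a, off in centers.items()
    }
    matrix = [
        (4400.0, 150.0, 0.10),
        (4800.0, 250.0, 0.20),
        (5200.0, 180.0, 0.35),
        (6900.0, 220.0, 0.15),
        (8500.0, 400.0, 0.05),
    ]
    return SpectralLibrary(component_bands=bands, matrix_bands=matrix).validate()


def _gaussians(grid: np.ndarray, bands) -> np.ndarray:
    out = np.zeros_like(grid)
    for c, w, amp in bands:
        out += amp * np.exp(-0.5 * ((grid - c) / w) ** 2)
    return out


def component_signatures(library: SpectralLibrary, alkanes=ALKANES) -> np.ndarray:
    """Matrix (n_alkanes, p): absorbance per mg/kg DM of each alkane."""
    return np.vstack([_gaussians(library.grid, library.component_bands[a]) for a in alkanes])


def matrix_spectrum(library: SpectralLibrary) -> np.ndarray:
    return _gaussians(library.grid, library.matrix_bands)


def simulate_spectra(
    excreta: pd.DataFrame,
    library: SpectralLibrary,
    seed: int,
    diet_group: np.ndarray | None = None,
) -> SpectraSet:
    """Forward-model NIR spectra of excreta samples.

    spectrum_s = m_s * (sum_i c[i, s] * band_i + matrix) + baseline_s + eps_s
    with log m_s ~ N(0, scatter_sd^2).  Deterministic under ``seed``; the
    noise-free component depends only on concentrations and the library.
    """
    library.validate()
    conc = excreta.to_numpy(dtype=float)
    if not np.all(np.isfinite(conc)) or (conc < 0).any():
        raise ValueError("excreta concentrations must be finite and >= 0")
    alkanes = list(excreta.columns)
    sig = component_signatures(library, alkanes)
    clean = conc @ sig + matrix_spectrum(library)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, p = clean.shape
    m = np.exp(rng.normal(0.0, library.scatter_sd, size=(n, 1))) if library.scatter_sd > 0 \
        else np.ones((n, 1))
    grid = library.grid
    u = (grid - grid.mean()) / ((grid[-1] - grid[0]) / 2.0)
    coeff_sd = np.asarray(library.baseline_coeffs_sd, dtype=float)
    coeffs = rng.normal(0.0, 1.0, size=(n, coeff_sd.size)) * coeff_sd
    baseline = coeffs @ np.vstack([u**k for k in range(coeff_sd.size)])
    eps = rng.normal(0.0, library.noise_sd, size=(n, p)) if library.noise_sd > 0 \
        else np.zeros((n, p))

    return SpectraSet(
        wavenumbers=grid,
        absorbance=m * clean + baseline + eps,
        sample_ids=excreta.index.to_numpy(dtype=object),
        diet_group=diet_group,
    )


@dataclass
class StudyBundle:
    """Everything one simulated study produces."""

    design: StudyDesign
    feed: pd.Series            # source profile F (mg/kg DM)
    alfalfa: pd.Series         # source profile A (mg/kg DM)
    diet: pd.DataFrame         # per-animal diet concentration D
    excreta_true: pd.DataFrame
    excreta_lab: pd.DataFrame  # D-driven mass balance + analytic noise
    animals: pd.DataFrame      # diet_group, intake_g_dm_d, output_g_dm_d
    spectra: SpectraSet | None
    truth: dict

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_alkane_csv(self.feed.to_frame().T, out / "feed.csv")
        write_alkane_csv(self.alfalfa.to_frame().T, out / "alfalfa.csv")
        write_alkane_csv(self.diet, out / "diet.csv")
        write_alkane_csv(self.excreta_lab, out / "excreta_lab.csv")
        write_alkane_csv(self.excreta_true, out / "excreta_true.csv")
        self.animals.rename_axis("sample_id").to_csv(out / "animals.csv")
        if self.spectra is not None:
            self.spectra.to_csv(out / "spectra.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _positive_normal(rng, mean, sd, size):
    """Normal draws with non-positive values redrawn (never emitted)."""
    x = rng.normal(mean, sd, size=size)
    while (x <= 0).any():
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def simulate_study(
    design: StudyDesign,
    library: SpectralLibrary | None = None,
    seed: int | None = None,
    with_spectra: bool = True,
) -> StudyBundle:
    """Simulate one complete study (concentrations, intakes, spectra, truth).

    Identical seed implies an identical bundle.  ``with_spectra=False`` skips
    the spectral forward model (used for concentration-only experiments).
    """
    design.validate()
    if seed is None:
        seed = design.seed
    # independent substreams: animal-level draws vs spectral noise
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    spectra_seed = int(
        np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,))).integers(2**31)
    )

    n = design.n_per_group
    groups = [CONTROL] * n + [ALFALFA] * n
    ids = [f"H{i + 1:03d}" for i in range(2 * n)]
    alk = list(design.alkanes)
    q = design.alfalfa_inclusion

    intake = _positive_normal(rng, *design.intake_mean_sd, size=2 * n)
    output = _positive_normal(rng, *design.output_mean_sd, size=2 * n)

    feed = pd.Series({a: design.feed_profile[a] for a in alk}, name="feed")
    alfalfa = pd.Series({a: design.alfalfa_profile[a] for a in alk}, name="alfalfa")

    q_by_group = {CONTROL: 0.0, ALFALFA: q}
    diet_rows = np.array(
        [
            (1.0 - q_by_group[g]) * feed.to_numpy() + q_by_group[g] * alfalfa.to_numpy()
            for g in groups
        ]
    )
    recovery = np.array([[design.true_recovery[g][a] for a in alk] for g in groups])
    ratio = (intake / output)[:, None]
    e_true = ratio * diet_rows * recovery

    cv = np.array([design.analytic_cv.get(a, 0.0) for a in alk])
    sigma = np.sqrt(np.log1p(cv**2))
    noise = np.exp(rng.normal(0.0, 1.0, size=e_true.shape) * sigma - 0.5 * sigma**2)
    e_lab = e_true * noise

    index = pd.Index(ids, name="sample_id")
    diet = pd.DataFrame(diet_rows, index=index, columns=alk)
    excreta_true = pd.DataFrame(e_true, index=index, columns=alk)
    excreta_lab = pd.DataFrame(e_lab, index=index, columns=alk)
    animals = pd.DataFrame(
        {"diet_group": groups, "intake_g_dm_d": intake, "output_g_dm_d": output},
        index=index,
    )

    spectra = None
    if with_spectra:
        if library is None:
            library = default_library()
        spectra = simulate_spectra(
            excreta_true, library, spectra_seed, diet_group=np.asarray(groups, dtype=object)
        )

    truth = {
        "seed": int(seed),
        "alfalfa_inclusion": {CONTROL: 0.0, ALFALFA: float(q)},
        "recoveries": {g: dict(design.true_recovery[g]) for g in (CONTROL, ALFALFA)},
        "design": {
            "n_per_group": design.n_per_group,
            "alkanes": list(design.alkanes),
            "feed_profile": {a: float(v) for a, v in design.feed_profile.items()},
            "alfalfa_profile": {a: float(v) for a, v in design.alfalfa_profile.items()},
            "alfalfa_inclusion": float(q),
            "intake_mean_sd": list(design.intake_mean_sd),
            "output_mean_sd": list(design.output_mean_sd),
            "analytic_cv": {a: float(v) for a, v in design.analytic_cv.items()},
        },
    }
    return StudyBundle(
        design=design,
        feed=feed,
        alfalfa=alfalfa,
        diet=diet,
        excreta_true=excreta_true,
        excreta_lab=excreta_lab,
        animals=animals,
        spectra=spectra,
        truth=truth,
    )
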