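"""End-to-end reproducible pipeline: simulate -> calibrate -> predict ->
agreement -> recovery -> diet estimation, with CSV report contracts.

One master seed feeds independent per-stage substreams (simulation, per-alkane
splits) so stages can be re-run in isolation reproducibly.  All tabular output
is plain CSV with a header row, deterministic column order, and full-precision
values; report tables add display-rounded columns (3 significant figures).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_report
from .calibration import (
    DEFAULT_WINDOW,
    CalibrationResult,
    PLSModel,
    SplitPlan,
    select_model,
    stratified_split,
)
from .diet import (
    RecoveryTable,
    adjust_excreta,
    combination_search,
    estimate_per_animal,
    evaluate_estimates,
    recovery_rates,
    subset_label,
)
from .preprocess import treatment_grid
from .simulate import (
    SpectralLibrary,
    StudyBundle,
    StudyDesign,
    default_design,
    default_library,
    simulate_study,
)
from .spectra import ALKANES, ALFALFA, CONTROL

logger = logging.getLogger("alkanir")

SOURCES = ("lab", "nirs")


def _stage_seed(master: int, *key: int) -> int:
    """Deterministic per-stage integer seed (< 2**31) from the master seed."""
    rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=tuple(key)))
    return int(rng.integers(2**31))


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``true_inclusion`` defaults to the design's alfalfa inclusion; the spectral
    window is the informative 4000-7500 cm^-1 interval.
    """

    seed: int
    design: StudyDesign | None = None
    library: SpectralLibrary | None = None
    window: tuple = DEFAULT_WINDOW
    a_max: int = 10
    alkanes: tuple = ALKANES
    treatments: list | None = None   # None -> the full 33-cell grid
    report_precision: int = 3

    def validate(self) -> "PipelineConfig":
        if not self.alkanes:
            raise ValueError("alkane list is empty")
        if self.window[0] >= self.window[1]:
            raise ValueError("window lo must be < hi")
        if self.a_max < 1:
            raise ValueError("a_max must be >= 1")
        return self

    def resolved(self) -> "PipelineConfig":
        cfg = dataclasses.replace(self)
        if cfg.design is None:
            cfg.design = default_design(seed=cfg.seed)
        if cfg.library is None:
            cfg.library = default_library()
        return cfg.validate()

    def hash(self) -> str:
        cfg = self.resolved()
        payload = {
            "seed": cfg.seed,
            "window": list(cfg.window),
            "a_max": cfg.a_max,
            "alkanes": list(cfg.alkanes),
            "treatments": None if cfg.treatments is None
            else [t.code for t in cfg.treatments],
            "design": cfg.design.__dict__ | {"alkanes": list(cfg.design.alkanes)},
            "library": {
                "grid": [float(cfg.library.grid[0]), float(cfg.library.grid[-1]),
                         float(cfg.library.grid[1] - cfg.library.grid[0])],
                "component_bands": cfg.library.component_bands,
                "matrix_bands": cfg.library.matrix_bands,
                "baseline_coeffs_sd": list(cfg.library.baseline_coeffs_sd),
                "scatter_sd": cfg.library.scatter_sd,
                "noise_sd": cfg.library.noise_sd,
            },
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class PipelineResult:
    config: PipelineConfig
    bundle: StudyBundle
    plans: dict
    calibrations: dict
    models: dict
    predicted: pd.DataFrame          # NIRS-predicted concentrations, all samples
    descriptives: pd.DataFrame
    calibration_table: pd.DataFrame
    candidates: pd.DataFrame
    agreement_table: pd.DataFrame
    recovery: dict                   # source -> RecoveryTable
    estimates: dict                  # source -> per-animal full-subset estimates
    inclusion_table: pd.DataFrame    # source x diet group, full subset
    combination_table: pd.DataFrame  # source x subset (mixed-diet group)
    manifest: dict


def calibrate_all(
    bundle: StudyBundle, config: PipelineConfig
) -> tuple[dict, dict, dict, pd.DataFrame]:
    """Per-alkane split + treatment-grid model selection + prediction.

    Returns (plans, calibrations, models, predicted) where ``predicted`` holds
    NIRS predictions for every sample (calibration samples through their
    alkane's model, validation samples through the same frozen external path).
    """
    grid = treatment_grid() if config.treatments is None else list(config.treatments)
    groups = bundle.animals["diet_group"]
    plans: dict = {}
    calibrations: dict = {}
    models: dict = {}
    predicted = {}
    for k, alkane in enumerate(config.alkanes):
        refs = bundle.excreta_lab[alkane]
        plan = stratified_split(
            refs, groups, n_intervals=4, seed=_stage_seed(config.seed, 1, k)
        )
        result, model = select_model(
            bundle.spectra,
            refs,
            plan,
            grid,
            a_max=config.a_max,
            alkane=alkane,
            window=config.window,
        )
        logger.info(
            "selected %s: treatment=%s components=%d RMSECV=%.6g",
            alkane, result.treatment.code, result.n_components, result.rmsecv,
        )
        plans[alkane] = plan
        calibrations[alkane] = result
        models[alkane] = model
        predicted[alkane] = pd.Series(
            model.predict(bundle.spectra), index=bundle.spectra.sample_ids
        )
    pred = pd.DataFrame(predicted).loc[bundle.excreta_lab.index]
    pred.index.name = "sample_id"
    return plans, calibrations, models, pred


def descriptives_table(bundle: StudyBundle, plans: dict) -> pd.DataFrame:
    """Calibration/validation reference statistics per alkane."""
    rows = []
    for alkane, plan in plans.items():
        refs = bundle.excreta_lab[alkane]
        cal = refs.loc[plan.calibration_ids]
        val = refs.loc[plan.validation_ids]
        rows.append(
            {
                "alkane": alkane,
                "cal_n": len(cal), "cal_mean": cal.mean(), "cal_sd": cal.std(ddof=1),
                "val_n": len(val), "val_mean": val.mean(), "val_sd": val.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def agreement_table(
    bundle: StudyBundle, predicted: pd.DataFrame, plans: dict
) -> pd.DataFrame:
    """Bland-Altman + SSEP decomposition per alkane on the validation samples."""
    rows = []
    for alkane, plan in plans.items():
        ids = plan.validation_ids
        rep = agreement_report(
            predicted.loc[ids, alkane].to_numpy(),
            bundle.excreta_lab.loc[ids, alkane].to_numpy(),
        )
        rows.append(
            {
                "alkane": alkane,
                "n": rep.n,
                "SSEP": rep.ssep,
                "pct_bias": rep.pct_bias,
                "pct_slope": rep.pct_slope,
                "pct_residual": rep.pct_residual,
                "bias": rep.bias,
                "sd_d": rep.sd_d,
                "loa_low": rep.loa_low,
                "loa_high": rep.loa_high,
                "ci_bias_low": rep.ci_bias[0],
                "ci_bias_high": rep.ci_bias[1],
                "ci_loa_low_low": rep.ci_loa_low[0],
                "ci_loa_low_high": rep.ci_loa_low[1],
                "ci_loa_high_low": rep.ci_loa_high[0],
                "ci_loa_high_high": rep.ci_loa_high[1],
            }
        )
    return pd.DataFrame(rows)


def diet_stage(
    bundle: StudyBundle, excreta: pd.DataFrame, p_true_mixed: float
) -> tuple[RecoveryTable, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Recovery rates, full-subset estimates, group summaries, subset search.

    ``excreta`` is either the laboratory table or the NIRS-predicted table;
    negative predictions are floored at zero before the mixing model.
    Proportions in the returned summaries are in percent.
    """
    exc = excreta.clip(lower=0.0)
    groups = bundle.animals["diet_group"]
    rec = recovery_rates(
        bundle.animals["intake_g_dm_d"],
        bundle.animals["output_g_dm_d"],
        bundle.diet,
        exc,
        groups,
    )
    adjusted = adjust_excreta(exc, rec.group_means, groups)
    estimates = estimate_per_animal(bundle.feed, bundle.alfalfa, adjusted)
    estimates["diet_group"] = groups.loc[estimates.index]

    p_true = {CONTROL: 0.0, ALFALFA: p_true_mixed}
    rows = []
    for group in (CONTROL, ALFALFA):
        p = estimates.loc[estimates["diet_group"] == group, "p"].to_numpy()
        m = evaluate_estimates(p, p_true[group], subset=bundle.design.alkanes)
        rows.append(
            {
                "diet_group": group,
                "mean_pct": 100 * m.mean,
                "RMSE_pct": 100 * m.rmse,
                "bias_pct": 100 * m.bias,
                "var_pct2": 1e4 * m.var,
                "n": m.n,
            }
        )
    summary = pd.DataFrame(rows)

    mixed_ids = groups.index[groups == ALFALFA]
    combos = combination_search(
        bundle.feed,
        bundle.alfalfa,
        adjusted.loc[mixed_ids],
        p_true_mixed,
        alkanes=tuple(excreta.columns),
    )
    combos = combos.assign(
        mean_pct=100 * combos["mean"],
        RMSE_pct=100 * combos["RMSE"],
        bias_pct=100 * combos["bias"],
        var_pct2=1e4 * combos["var"],
    ).drop(columns=["mean", "RMSE", "bias", "var"])
    return rec, estimates, summary, combos


def run_full_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage on one simulated study and assemble the report bundle."""
    config.validate()
    cfg = config.resolved()
    bundle = simulate_study(cfg.design, cfg.library, seed=_stage_seed(cfg.seed, 0))

    plans, calibrations, models, predicted = calibrate_all(bundle, cfg)
    desc = descriptives_table(bundle, plans)
    cal_table = pd.DataFrame([calibrations[a].to_row() for a in cfg.alkanes])
    candidates = pd.concat(
        [calibrations[a].candidates.assign(alkane=a) for a in cfg.alkanes],
        ignore_index=True,
    )[["alkane", "treatment", "components", "RMSECV"]]
    agree = agreement_table(bundle, predicted, plans)

    q = cfg.design.alfalfa_inclusion
    recovery, estimates, inclusion_rows, combo_rows = {}, {}, [], []
    sources = {"lab": bundle.excreta_lab, "nirs": predicted}
    for source, table in sources.items():
        rec, est, summary, combos = diet_stage(bundle, table, q)
        recovery[source] = rec
        estimates[source] = est
        inclusion_rows.append(summary.assign(source=source))
        combo_rows.append(combos.assign(source=source))
    inclusion = pd.concat(inclusion_rows, ignore_index=True)[
        ["source", "diet_group", "mean_pct", "RMSE_pct", "bias_pct", "var_pct2", "n"]
    ]
    combos = pd.concat(combo_rows, ignore_index=True)[
        ["source", "subset", "size", "mean_pct", "RMSE_pct", "bias_pct", "var_pct2", "n"]
    ]

    manifest = {
        "seed": int(cfg.seed),
        "config_hash": cfg.hash(),
        "alkanir_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "alkanes": list(cfg.alkanes),
        "true_inclusion": float(q),
        "selected_models": {
            a: {
                "treatment": calibrations[a].treatment.code,
                "components": calibrations[a].n_components,
                "RMSECV": calibrations[a].rmsecv,
            }
            for a in cfg.alkanes
        },
    }
    return PipelineResult(
        config=cfg,
        bundle=bundle,
        plans=plans,
        calibrations=calibrations,
        models=models,
        predicted=predicted,
        descriptives=desc,
        calibration_table=cal_table,
        candidates=candidates,
        agreement_table=agree,
        recovery=recovery,
        estimates=estimates,
        inclusion_table=inclusion,
        combination_table=combos,
        manifest=manifest,
    )


def _round_sig(x: float, sig: int) -> float:
    if x == 0 or not np.isfinite(x):
        return x
    return float(np.round(x, -int(np.floor(np.log10(abs(x)))) + sig - 1))


def _with_display(frame: pd.DataFrame, columns, sig: int) -> pd.DataFrame:
    out = frame.copy()
    for c in columns:
        out[c + "_display"] = out[c].map(lambda v: _round_sig(float(v), sig))
    return out


def write_outputs(result: PipelineResult, outdir) -> None:
    """Write the report CSVs, data CSVs and the run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sig = result.config.report_precision
    result.bundle.write(out / "study")
    result.predicted.rename_axis("sample_id").to_csv(out / "predicted_nirs.csv")
    result.descriptives.to_csv(out / "descriptives.csv", index=False)
    _with_display(
        result.calibration_table,
        ["RMSEC", "R2c", "RMSECV", "R2cv", "RMSEV", "R2v"],
        sig,
    ).to_csv(out / "calibration_summary.csv", index=False)
    result.candidates.to_csv(out / "calibration_candidates.csv", index=False)
    _with_display(
        result.agreement_table, ["SSEP", "pct_bias", "pct_slope", "pct_residual"], sig
    ).to_csv(out / "agreement.csv", index=False)
    recovery_rows = []
    for source, rec in result.recovery.items():
        recovery_rows.append(rec.group_means.reset_index().assign(source=source))
    pd.concat(recovery_rows, ignore_index=True).to_csv(
        out / "recovery_group_means.csv", index=False
    )
    for source, est in result.estimates.items():
        est.rename_axis("sample_id").to_csv(out / f"estimates_{source}.csv")
    _with_display(
        result.inclusion_table, ["mean_pct", "RMSE_pct", "bias_pct", "var_pct2"], sig
    ).to_csv(out / "inclusion_full_subset.csv", index=False)
    _with_display(
        result.combination_table, ["mean_pct", "RMSE_pct", "bias_pct", "var_pct2"], sig
    ).to_csv(out / "inclusion_combinations.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
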