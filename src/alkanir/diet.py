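"""Recovery-corrected estimation of the dietary alfalfa proportion.

The fecal-marker mass balance gives a per-animal, per-alkane recovery rate

    R[i, a] = (output_a * E[i, a]) / (intake_a * D[i, a])

(E = excreta concentration, D = diet concentration, both mg/kg DM).  Excreta
concentrations are adjusted by the diet-group mean recovery, E* = E / Rbar,
restoring proportionality to the dietary pattern.  The two-source mixing model

    x_f * F_i + x_a * A_i = E*_i      (i over a chosen alkane subset)

is solved per animal by non-negative least squares (Lawson-Hanson); the
dietary dry-matter proportion supplied by alfalfa is p = x_a / (x_a + x_f).
Estimates are summarised per alkane subset by mean, bias, population variance
and RMSE (MSE = bias^2 + variance decomposition), and all subsets of sizes
2..5 of the five alkanes are searched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _lawson_hanson_nnls

from .spectra import ALKANES


# ----------------------------------------------------------------------------
# recovery rates and adjustment
# ----------------------------------------------------------------------------

@dataclass
class RecoveryTable:
    per_animal: pd.DataFrame   # R[i, a], animals x alkanes
    group_means: pd.DataFrame  # diet groups x alkanes


def recovery_rates(
    intake: pd.Series,
    output: pd.Series,
    diet_conc: pd.DataFrame,
    excreta_conc: pd.DataFrame,
    groups: pd.Series,
) -> RecoveryTable:
    """Per-animal recoveries R = (output * E) / (intake * D) and their
    per-diet-group means."""
    ids = excreta_conc.index
    intake_v = intake.loc[ids].to_numpy(dtype=float)
    output_v = output.loc[ids].to_numpy(dtype=float)
    d = diet_conc.loc[ids, excreta_conc.columns].to_numpy(dtype=float)
    e = excreta_conc.to_numpy(dtype=float)
    denom = intake_v[:, None] * d
    if (denom <= 0).any():
        bad = np.argwhere(denom <= 0)[0]
        raise ValueError(
            f"nonpositive intake*diet for animal {ids[bad[0]]!r}, "
            f"alkane {excreta_conc.columns[bad[1]]!r}"
        )
    if (intake_v <= 0).any() or (output_v <= 0).any():
        raise ValueError("intake and output must be > 0")
    r = (output_v[:, None] * e) / denom
    per_animal = pd.DataFrame(r, index=ids, columns=excreta_conc.columns)
    group_means = per_animal.groupby(groups.loc[ids]).mean()
    group_means.index.name = "diet_group"
    return RecoveryTable(per_animal=per_animal, group_means=group_means)


def adjust_excreta(
    excreta: pd.DataFrame, group_means: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """E* = E / Rbar[group(animal), alkane]."""
    ids = excreta.index
    missing = set(groups.loc[ids]) - set(group_means.index)
    if missing:
        raise ValueError(f"missing recovery group means for groups: {sorted(missing)}")
    rbar = group_means.loc[groups.loc[ids], excreta.columns].to_numpy(dtype=float)
    if (rbar <= 0).any():
        raise ValueError("group mean recoveries must be > 0")
    return pd.DataFrame(
        excreta.to_numpy(dtype=float) / rbar, index=ids, columns=excreta.columns
    )


# ----------------------------------------------------------------------------
# mixing model
# ----------------------------------------------------------------------------

def nnls_solve(
    feed: np.ndarray, alfalfa: np.ndarray, excreta_adj: np.ndarray
) -> tuple[float, float]:
    """Minimise ||x_f*F + x_a*A - E*||^2 subject to x_f, x_a >= 0."""
    f = np.asarray(feed, dtype=float).ravel()
    a = np.asarray(alfalfa, dtype=float).ravel()
    e = np.asarray(excreta_adj, dtype=float).ravel()
    if not (f.size == a.size == e.size) or f.size < 2:
        raise ValueError("nnls_solve requires equal-length vectors over >= 2 alkanes")
    if not f.any() and not a.any():
        raise ValueError("feed and alfalfa patterns are both zero")
    m = np.column_stack([f, a])
    nf, na = np.linalg.norm(f), np.linalg.norm(a)
    if nf > 0 and na > 0 and abs(float(f @ a)) >= nf * na * (1.0 - 1e-12):
        warnings.warn("feed and alfalfa patterns are collinear; solution non-unique")
    x, _ = _lawson_hanson_nnls(m, e)
    return float(x[0]), float(x[1])


def proportion(x_f: float, x_a: float) -> float:
    """Dietary DM fraction supplied by alfalfa, p = x_a / (x_a + x_f)."""
    total = x_f + x_a
    if total <= 0:
        warnings.warn("proportion undefined: both mixing coefficients are zero")
        return float("nan")
    return x_a / total


def estimate_per_animal(
    feed: pd.Series,
    alfalfa: pd.Series,
    excreta_adj: pd.DataFrame,
    subset=ALKANES,
) -> pd.DataFrame:
    """Solve the mixing model per animal over an alkane subset.

    Returns a frame with columns x_f, x_a, p (fraction; NaN when degenerate).
    """
    subset = list(subset)
    f = feed.loc[subset].to_numpy(dtype=float)
    a = alfalfa.loc[subset].to_numpy(dtype=float)
    rows = []
    for sid, e in excreta_adj.loc[:, subset].iterrows():
        x_f, x_a = nnls_solve(f, a, e.to_numpy(dtype=float))
        rows.append((sid, x_f, x_a, proportion(x_f, x_a)))
    return pd.DataFrame(rows, columns=["sample_id", "x_f", "x_a", "p"]).set_index(
        "sample_id"
    )


# ----------------------------------------------------------------------------
# error summaries and the combination search
# ----------------------------------------------------------------------------

@dataclass
class CombinationMetrics:
    """Summary of proportion estimates for one alkane subset.

    ``var`` is the population variance of the estimates (divisor n), so
    RMSE^2 = bias^2 + var holds as an identity.
    """

    subset: tuple
    mean: float
    rmse: float
    bias: float
    var: float
    n: int
    n_missing: int = 0


def evaluate_estimates(p_hat, p_true: float, subset=()) -> CombinationMetrics:
    """MSE decomposition of proportion estimates against the true inclusion."""
    p = np.asarray(p_hat, dtype=float).ravel()
    missing = int(np.isnan(p).sum())
    p = p[~np.isnan(p)]
    if p.size < 2:
        raise ValueError("evaluate_estimates requires >= 2 non-missing estimates")
    if missing:
        warnings.warn(f"{missing} undefined proportion estimate(s) excluded")
    mean = float(p.mean())
    bias = mean - float(p_true)
    var = float(p.var(ddof=0))
    return CombinationMetrics(
        subset=tuple(subset),
        mean=mean,
        rmse=float(np.sqrt(bias**2 + var)),
        bias=bias,
        var=var,
        n=int(p.size),
        n_missing=missing,
    )


def subset_label(subset) -> str:
    return "-".join(subset)


def combination_search(
    feed: pd.Series,
    alfalfa: pd.Series,
    excreta_adj: pd.DataFrame,
    p_true: float,
    sizes=(2, 3, 4, 5),
    alkanes=ALKANES,
) -> pd.DataFrame:
    """Evaluate every alkane subset of the given sizes, sorted by RMSE.

    With the default five alkanes and sizes 2..5 this is 26 subsets.  Returns
    a frame with columns subset, mean, RMSE, bias, var, n (one row per
    subset).  ``p_true`` must be on the same scale as the estimates (a
    fraction); reports convert to percent at render time.
    """
    rows = []
    for k in sizes:
        for subset in combinations(alkanes, k):
            est = estimate_per_animal(feed, alfalfa, excreta_adj, subset)
            m = evaluate_estimates(est["p"].to_numpy(), p_true, subset)
            rows.append(
                {
                    "subset": subset_label(subset),
                    "size": k,
                    "mean": m.mean,
                    "RMSE": m.rmse,
                    "bias": m.bias,
                    "var": m.var,
                    "n": m.n,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["RMSE", "size", "subset"], kind="stable")
        .reset_index(drop=True)
    )
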