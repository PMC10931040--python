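"""Agreement between NIRS-predicted and laboratory alkane concentrations.

Two complementary views of the prediction error d = predicted - reference
(positive bias = overprediction):

* Bland-Altman statistics — mean difference (bias), 95% limits of agreement
  bias +/- 1.96*SD(d), and t-based confidence intervals for both, with the
  classic approximation SE(LOA) = SD(d)*sqrt(1/n + 1.96^2 / (2(n-1))).
* SSEP decomposition — the sum of squared prediction errors split into the
  share due to mean bias, the share due to the regression of d on the
  predicted values having a nonzero slope, and the residual share.  The three
  shares sum to 100% exactly (analysis-of-variance identity
  SSEP = n*mean(d)^2 + slope^2*S_PP + SSE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AgreementReport:
    n: int
    bias: float
    sd_d: float
    loa_low: float
    loa_high: float
    ci_bias: tuple
    ci_loa_low: tuple
    ci_loa_high: tuple
    ssep: float | None = None
    pct_bias: float | None = None
    pct_slope: float | None = None
    pct_residual: float | None = None


def bland_altman(predicted, reference, level: float = 0.95) -> AgreementReport:
    """Bland-Altman bias and limits of agreement with t-based CIs.

    Differences are taken as predicted - reference (plotted against predicted
    values in the companion figure convention).
    """
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.shape != r.shape:
        raise ValueError("predicted and reference must have equal length")
    n = p.size
    if n < 3:
        raise ValueError("Bland-Altman confidence intervals require n >= 3")
    d = p - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = stats.norm.ppf(0.5 + level / 2.0)
    loa_low, loa_high = bias - z * sd, bias + z * sd
    tq = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + z**2 / (2.0 * (n - 1)))
    return AgreementReport(
        n=n,
        bias=bias,
        sd_d=sd,
        loa_low=float(loa_low),
        loa_high=float(loa_high),
        ci_bias=(bias - tq * se_bias, bias + tq * se_bias),
        ci_loa_low=(loa_low - tq * se_loa, loa_low + tq * se_loa),
        ci_loa_high=(loa_high - tq * se_loa, loa_high + tq * se_loa),
    )


def ssep_decompose(predicted, reference) -> tuple[float, float, float, float]:
    """(SSEP, pct_bias, pct_slope, pct_residual) of the prediction error.

    The slope term comes from the OLS regression of d = predicted - reference
    on the predicted values; the percentages sum to 100 exactly.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.shape != r.shape or p.size < 3:
        raise ValueError("ssep_decompose requires equal-length vectors, n >= 3")
    d = p - r
    ssep = float(d @ d)
    if ssep == 0:
        return 0.0, 0.0, 0.0, 0.0
    n = p.size
    pc = p - p.mean()
    s_pp = float(pc @ pc)
    if s_pp == 0:
        raise ValueError("slope undefined: predicted values have zero variance")
    slope = float(pc @ (d - d.mean())) / s_pp
    sse = float(np.sum((d - d.mean() - slope * pc) ** 2))
    pct_bias = 100.0 * n * d.mean() ** 2 / ssep
    pct_slope = 100.0 * slope**2 * s_pp / ssep
    pct_residual = 100.0 * sse / ssep
    return ssep, float(pct_bias), float(pct_slope), float(pct_residual)


def agreement_report(predicted, reference, level: float = 0.95) -> AgreementReport:
    """Bland-Altman statistics plus the SSEP decomposition in one report."""
    rep = bland_altman(predicted, reference, level)
    ssep, pb, ps, pr = ssep_decompose(predicted, reference)
    rep.ssep, rep.pct_bias, rep.pct_slope, rep.pct_residual = ssep, pb, ps, pr
    return rep
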