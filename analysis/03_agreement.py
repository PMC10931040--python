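"""Agreement between NIRS-predicted and laboratory concentrations.

For each alkane's 8 validation samples: Bland-Altman bias and limits of
agreement, and the SSEP split into bias/slope/residual shares.  Writes
results/agreement.csv.
"""

import json
from pathlib import Path

import pandas as pd

from alkanir import agreement_report
from alkanir.spectra import ALKANES, read_alkane_csv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    lab = read_alkane_csv(RESULTS / "study" / "excreta_lab.csv")
    pred = pd.read_csv(RESULTS / "predicted_nirs.csv", index_col="sample_id")
    splits = json.loads((RESULTS / "splits.json").read_text())

    rows = []
    for alkane in ALKANES:
        ids = splits[alkane]["validation_ids"]
        rep = agreement_report(
            pred.loc[ids, alkane].to_numpy(), lab.loc[ids, alkane].to_numpy()
        )
        rows.append(
            {
                "alkane": alkane, "n": rep.n, "SSEP": rep.ssep,
                "pct_bias": rep.pct_bias, "pct_slope": rep.pct_slope,
                "pct_residual": rep.pct_residual, "bias": rep.bias,
                "loa_low": rep.loa_low, "loa_high": rep.loa_high,
                "ci_bias_low": rep.ci_bias[0], "ci_bias_high": rep.ci_bias[1],
            }
        )
        print(f"{alkane}: SSEP={rep.ssep:.3f}  bias {rep.pct_bias:.1f}%  "
              f"slope {rep.pct_slope:.1f}%  residual {rep.pct_residual:.1f}%")
    pd.DataFrame(rows).to_csv(RESULTS / "agreement.csv", index=False)
    print(f"wrote {RESULTS / 'agreement.csv'}")


if __name__ == "__main__":
    main()
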