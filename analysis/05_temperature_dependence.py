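"""Turnover time vs in-situ temperature across all stations.

Pools the per-horizon inversions and regresses log10(T_NM) and log10(T_b)
on temperature; the steady-state model inherits the Arrhenius law, so both
are close to log-linear across the 9-74 degC span with R^2 near 1.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from dlamino.profiles_io import read_results

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frames = []
    for path in sorted(ROOT.glob("turnover_*.csv")):
        results = read_results(path)
        frames.append(
            pd.DataFrame(
                {
                    "station": path.stem.removeprefix("turnover_"),
                    "temperature_c": [r.temperature for r in results],
                    "t_nm_yr": [r.t_nm for r in results],
                    "t_b_yr": [r.t_b for r in results],
                }
            )
        )
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled[np.isfinite(pooled.t_nm_yr) & (pooled.t_b_yr > 0)]

    rows = []
    for column in ("t_nm_yr", "t_b_yr"):
        fit = stats.linregress(pooled.temperature_c, np.log10(pooled[column]))
        rows.append(
            {
                "quantity": column,
                "slope_log10_per_degC": fit.slope,
                "intercept_log10": fit.intercept,
                "r_squared": fit.rvalue**2,
                "n": len(pooled),
            }
        )
        print(
            f"log10({column}) vs T: slope {fit.slope:.4f} /degC, "
            f"R2 {fit.rvalue ** 2:.3f}, n {len(pooled)}"
        )
    pd.DataFrame(rows).to_csv(ROOT / "temperature_dependence.csv", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
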