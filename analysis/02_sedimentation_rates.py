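"""Estimate sedimentation rates from the excess Pb-210 profiles (CF-CS model).

Reads the radionuclide CSVs written by 01_generate_stations.py, fits
ln(excess Pb-210) against depth, and tabulates the recovered rates next to
the configured truth. Noise-free profiles invert essentially exactly; the
5 %-noise profiles land within a few percent.
"""

from pathlib import Path

import pandas as pd

from dlamino.chronology import excess_pb210, sed_rate_from_pb210
from dlamino.profiles_io import read_radionuclide, read_station

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for station_dir in sorted((ROOT / "stations").iterdir()):
        meta, _ = read_station(station_dir / "samples.csv", station_dir / "metadata.csv")
        profile = excess_pb210(read_radionuclide(station_dir / "radionuclide.csv"))
        fit = sed_rate_from_pb210(profile)
        rows.append(
            {
                "station": station_dir.name,
                "true_rate_mm_yr": meta.sedimentation_rate,
                "fitted_rate_mm_yr": fit.rate,
                "r_squared": fit.r_squared,
                "n_intervals": fit.n,
            }
        )
        print(
            f"{station_dir.name}: CF-CS rate {fit.rate:.4f} mm/yr "
            f"(true {meta.sedimentation_rate}, R2 {fit.r_squared:.4f}, n {fit.n})"
        )
    pd.DataFrame(rows).to_csv(ROOT / "sedimentation_rates.csv", index=False, float_format="%.6g")


if __name__ == "__main__":
    main()
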