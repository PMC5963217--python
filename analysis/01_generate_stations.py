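"""Generate the three template stations, noise-free and with 5 % measurement noise.

Writes each station's samples/metadata/radionuclide CSVs under
results/stations/<id>[_noisy]/ so the downstream drivers (and anyone
re-running the pipeline by hand) have concrete inputs.
"""

from dataclasses import replace
from pathlib import Path

from dlamino.profiles_io import write_radionuclide, write_station
from dlamino.synthetic import default_configs, generate_station

OUT = Path(__file__).resolve().parents[1] / "results" / "stations"


def main() -> None:
    for name, config in default_configs().items():
        for label, cfg in (
            (name, config),
            (f"{name}_noisy", replace(config, noise_sigma=0.05, seed=1)),
        ):
            out = OUT / label
            out.mkdir(parents=True, exist_ok=True)
            meta, horizons, radio = generate_station(cfg)
            write_station(meta, horizons, out / "samples.csv", out / "metadata.csv")
            write_radionuclide(radio, out / "radionuclide.csv")
            dl = [h.isomers.dl_ratio for h in horizons]
            print(
                f"{label}: {len(horizons)} horizons, THAA "
                f"{horizons[0].sample.thaa:.1f} -> {horizons[-1].sample.thaa:.2f} umol/gdw, "
                f"D:L {dl[0]:.3f} -> {dl[-1]:.3f}"
            )


if __name__ == "__main__":
    main()
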