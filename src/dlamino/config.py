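"""YAML run configuration: model constants plus the active racemization calibration.

Layout::

    constants:
      dl_live: 0.014
      hydrolysis_induced_pct_d: 4.4
      ...                       # any ModelConstants field
    calibration:
      ln_a: 38.9474
      ea: 113907.0
      k_eq: 1.0
      source_tag: anchor-fit-v1
    hydrolysis_correction: ratio   # or "subtract"
    steady_state: true
    seed: 0

Omitted blocks fall back to the package defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .profiles_io import ModelConstants
from .racemization import RacemizationCalibration, default_calibration


@dataclass(frozen=True)
class RunConfig:
    constants: ModelConstants
    calibration: RacemizationCalibration
    hydrolysis_correction: str = "ratio"  # "ratio" (inverse map) or "subtract"
    steady_state: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hydrolysis_correction not in ("ratio", "subtract"):
            raise ValueError("hydrolysis_correction must be 'ratio' or 'subtract'")

    def digest(self) -> str:
        """Stable hash of the full configuration, for run logs."""
        payload = {
            "constants": dataclasses.asdict(self.constants),
            "calibration": dataclasses.asdict(self.calibration),
            "hydrolysis_correction": self.hydrolysis_correction,
            "steady_state": self.steady_state,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig(constants=ModelConstants(), calibration=default_calibration())


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    constants = ModelConstants(**raw.get("constants", {}))
    calib_block = raw.get("calibration")
    calibration = (
        RacemizationCalibration(**calib_block) if calib_block else default_calibration()
    )
    return RunConfig(
        constants=constants,
        calibration=calibration,
        hydrolysis_correction=raw.get("hydrolysis_correction", "ratio"),
        steady_state=bool(raw.get("steady_state", True)),
        seed=int(raw.get("seed", 0)),
    )
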