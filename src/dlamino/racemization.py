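"""Aspartic-acid racemization kinetics.

Racemization interconverts the L- and D-isomers reversibly and first-order:

    dD/dt = k*L - (k/K_eq)*D,    dL/dt = (k/K_eq)*D - k*L

with forward rate constant k (Arrhenius in temperature) and equilibrium
constant K_eq = (D:L at equilibrium), 1.0 for Asp by symmetry. In D-fraction
space d = D/(D+L) the closed-system solution is

    d(t) = d_eq + (d0 - d_eq) * exp(-k * (1 + 1/K_eq) * t),    d_eq = K_eq/(1+K_eq)

which for K_eq = 1 reduces to d(t) = 0.5 + (d0 - 0.5) exp(-2kt).

The default Arrhenius calibration is fit through two turnover-time anchors
back-solved with the steady-state inversion (see :mod:`dlamino.turnover`):
Ea = 113907 J/mol, ln A = 38.9474 (source_tag "anchor-fit-v1"). Alternative
literature calibrations can be swapped in via the config file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chronology import age_at_depth, temperature_at_depth
from .profiles_io import ModelConstants, StationMetadata

#: molar gas constant, J / (mol K)
R_GAS = 8.31446261815324

ZERO_C_IN_K = 273.15


@dataclass(frozen=True)
class RacemizationCalibration:
    """Arrhenius parameters and equilibrium constant for one amino acid."""

    ln_a: float  # ln(1/yr), pre-exponential
    ea: float  # J / mol, activation energy
    k_eq: float = 1.0  # equilibrium D:L
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.ea <= 0:
            raise ValueError("activation energy must be > 0")
        if self.k_eq <= 0:
            raise ValueError("equilibrium constant must be > 0")

    @property
    def d_eq(self) -> float:
        """Equilibrium D fraction, K_eq/(1+K_eq)."""
        return self.k_eq / (1.0 + self.k_eq)


def default_calibration() -> RacemizationCalibration:
    """Package default Asp calibration (anchor-fit, 6 significant digits)."""
    return RacemizationCalibration(ln_a=38.9474, ea=113907.0, k_eq=1.0, source_tag="anchor-fit-v1")


def k_asp(temperature: float, calib: RacemizationCalibration) -> float:
    """Racemization rate constant (1/yr) at ``temperature`` (degC)."""
    if temperature <= -ZERO_C_IN_K:
        raise ValueError("temperature must be above absolute zero")
    t_kelvin = temperature + ZERO_C_IN_K
    return float(np.exp(calib.ln_a - calib.ea / (R_GAS * t_kelvin)))


def racemize_closed(d0: float, k: float, t: float, k_eq: float = 1.0) -> float:
    """Closed-system D fraction after time ``t`` (yr), starting from ``d0``."""
    if not 0 <= d0 < 1:
        raise ValueError("d0 must be in [0, 1)")
    if k < 0 or t < 0:
        raise ValueError("k and t must be >= 0")
    d_eq = k_eq / (1.0 + k_eq)
    rate = k * (1.0 + 1.0 / k_eq)
    # -expm1 form is exact at t = 0 and saturates cleanly at d_eq
    return d0 + (d_eq - d0) * (-float(np.expm1(-rate * t)))


def forward_hydrolysis(d_true: float, h: float = 0.044) -> float:
    """Measured D fraction after hydrolysis adds an induced fraction ``h``."""
    return d_true + h * (1.0 - d_true)


def correct_hydrolysis(d_measured: float, h: float = 0.044) -> tuple[float, bool]:
    """Remove hydrolysis-induced racemization from a measured D fraction.

    Inverts d_m = d_t + h*(1 - d_t): d_t = (d_m - h)/(1 - h), so a pure-L
    standard reading exactly ``h`` maps to zero. Readings below ``h``
    (measurement noise) clamp to 0 with the below-blank flag. Returns
    (corrected fraction, clamped?).
    """
    if not 0 <= d_measured < 1:
        raise ValueError("d_measured must be in [0, 1)")
    if d_measured < h * (1.0 - 1e-9):
        return 0.0, True
    return max((d_measured - h) / (1.0 - h), 0.0), False


def expected_dl_profile(
    meta: StationMetadata,
    calib: RacemizationCalibration,
    constants: ModelConstants,
    depths: Sequence[float],
) -> list[float]:
    """No-renewal expected D:L ratios from pure chemical racemization.

    For each depth, material is assumed deposited at the living-cell ratio
    and racemized closed-system for the sediment age at the local in-situ
    temperature — the reference curve a measured profile is compared to:
    measured ratios below it imply ongoing necromass production.
    """
    out = []
    f0 = constants.live_d_fraction
    for z in depths:
        k = k_asp(temperature_at_depth(meta, z), calib)
        d = racemize_closed(f0, k, age_at_depth(meta, z), calib.k_eq)
        out.append(d / (1.0 - d))
    return out
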