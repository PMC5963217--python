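"""Steady-state inversion of necromass D:L-Asp to microbial turnover times.

The sedimentary Asp pool is split into living biomass (held at the low
living-cell D fraction f — cells repair or replace racemized residues) and
necromass, which racemizes freely while being degraded and replenished by
fresh biomass at rate F = A/T_NM (quasi-steady cell numbers mean necromass
degraded equals biomass produced). Degradation removes D and L
proportionally. The necromass pool then obeys

    dD/dt = k*L - (k/K)*D - D/T_NM + F*f
    dL/dt = (k/K)*D - k*L - L/T_NM + F*(1-f)

whose steady state, for equilibrium constant K = 1, inverts to

    T_NM = (d - f) / (k * (1 - 2d)),        d = D/(D+L) of necromass

and in general T_NM = (d - f) / (k * (1 - d*(1 + 1/K))). The biomass
turnover time follows from flux balance through the shared throughput:
T_b = T_NM * Asp_bio / Asp_necro.

`forward_necromass` integrates the ODEs numerically and serves as the
independent oracle for the analytic inversion.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import pools
from .chronology import temperature_at_depth
from .profiles_io import Horizon, ModelConstants, StationMetadata, TurnoverResult
from .racemization import RacemizationCalibration, correct_hydrolysis, k_asp

__all__ = [
    "BelowLiveRatioError",
    "NearEquilibriumError",
    "tnm_steady_state",
    "forward_necromass",
    "tb_from_tnm",
    "invert_station",
]


class BelowLiveRatioError(ValueError):
    """Measured D fraction at or below the living-cell ratio: zero-age necromass."""


class NearEquilibriumError(ValueError):
    """Measured D fraction at or above equilibrium: turnover time unbounded."""


def _live_fraction(dl_live: float) -> float:
    return dl_live / (1.0 + dl_live)


def tnm_steady_state(d_necro: float, k: float, dl_live: float, k_eq: float = 1.0) -> float:
    """Necromass turnover time (yr) from its steady-state D fraction.

    Strictly increasing in ``d_necro`` on (f, d_eq) and strictly decreasing
    in ``k``.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    f = _live_fraction(dl_live)
    d_eq = k_eq / (1.0 + k_eq)
    if d_necro <= f:
        raise BelowLiveRatioError(
            f"d_necro {d_necro:.6g} <= living fraction {f:.6g}: necromass is fresh"
        )
    if d_necro >= d_eq:
        raise NearEquilibriumError(
            f"d_necro {d_necro:.6g} >= equilibrium fraction {d_eq:.6g}"
        )
    return (d_necro - f) / (k * (1.0 - d_necro * (1.0 + 1.0 / k_eq)))


def forward_necromass(
    t_nm: float,
    k: float,
    dl_live: float,
    total_asp: float = 1.0,
    horizon: float | None = None,
    tol: float = 1e-9,
    k_eq: float = 1.0,
) -> float:
    """Steady-state necromass D fraction by direct ODE integration.

    Independent numerical oracle for :func:`tnm_steady_state`: integrates the
    production/degradation/racemization ODEs from fresh necromass (d = f)
    until the relative change per characteristic time drops below ``tol``,
    and returns D/(D+L). The pool size settles at F*T_NM = ``total_asp``.
    """
    if t_nm <= 0 or k < 0 or total_asp <= 0:
        raise ValueError("t_nm and total_asp must be > 0, k >= 0")
    f = _live_fraction(dl_live)
    flux = total_asp / t_nm
    k_back = k / k_eq

    def rhs(_t, y):
        d_pool, l_pool = y
        return [
            k * l_pool - k_back * d_pool - d_pool / t_nm + flux * f,
            k_back * d_pool - k * l_pool - l_pool / t_nm + flux * (1.0 - f),
        ]

    # slowest relaxation time of the linear system
    tau = 1.0 / (k * (1.0 + 1.0 / k_eq) + 1.0 / t_nm)
    t_end = 60.0 * tau if horizon is None else min(horizon, 60.0 * tau)
    y0 = [f * total_asp, (1.0 - f) * total_asp]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="Radau", rtol=1e-10, atol=1e-12 * total_asp)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y_final = sol.y[:, -1]
    drift = np.abs(rhs(sol.t[-1], y_final))
    if np.max(drift) * tau > tol * total_asp:
        raise RuntimeError(
            f"did not reach steady state within horizon {t_end:.3g} yr "
            f"(residual {np.max(drift) * tau / total_asp:.3g} > tol {tol:.3g})"
        )
    return float(y_final[0] / (y_final[0] + y_final[1]))


def tb_from_tnm(t_nm: float, asp_bio: float, asp_necro: float) -> float:
    """Biomass turnover time (yr): T_b = T_NM * Asp_bio / Asp_necro."""
    if asp_necro <= 0:
        raise ValueError("asp_necro must be > 0")
    if asp_bio < 0:
        raise ValueError("asp_bio must be >= 0")
    return t_nm * asp_bio / asp_necro


def _biomass_split(horizon: Horizon, constants: ModelConstants) -> float:
    """Biomass Asp (umol/gdw) for one horizon; 0 when no cell data."""
    cells = horizon.cells
    if cells is None or cells.total_cells is None:
        return 0.0
    if cells.bac_copies is not None and cells.arc_copies is not None and (
        cells.bac_copies + cells.arc_copies
    ) > 0:
        bac, arc = pools.cells_from_copies(cells.bac_copies, cells.arc_copies, constants)
        frac_bac = bac / (bac + arc)
    elif cells.pct_bacteria is not None:
        frac_bac = cells.pct_bacteria / 100.0
    else:
        frac_bac = 0.5
    total_gdw = pools.cells_per_gdw(cells.total_cells, constants.porosity, constants.grain_density)
    return pools.biomass_asp(total_gdw * frac_bac, total_gdw * (1.0 - frac_bac), constants)


def invert_station(
    meta: StationMetadata,
    horizons: Sequence[Horizon],
    calib: RacemizationCalibration,
    constants: ModelConstants,
) -> list[TurnoverResult]:
    """Run the full inversion for every horizon with an isomer measurement.

    Per horizon: hydrolysis-correct the measured D fraction (unless already
    corrected), resolve the in-situ temperature, subtract the
    living-biomass D and L contribution to get the necromass D fraction,
    invert to T_NM, and scale to T_b by the pool ratio. Failures are flagged
    per horizon and never abort the station.
    """
    results: list[TurnoverResult] = []
    for h in horizons:
        if h.isomers is None:
            continue
        flags: set[str] = set()
        depth = h.depth
        if h.sample.temperature is not None:
            temp = h.sample.temperature
        else:
            temp = temperature_at_depth(meta, depth)
            if depth > meta.core_recovery:
                flags.add("extrapolated")

        d_meas = h.isomers.d_fraction
        if h.isomers.hydrolysis_corrected:
            d_total = d_meas
        else:
            d_total, clamped = correct_hydrolysis(
                d_meas, constants.hydrolysis_induced_fraction
            )
            if clamped:
                flags.add("below_blank")

        total_asp = (h.isomers.d_asp + h.isomers.l_asp) / 1000.0  # nmol -> umol
        asp_bio = _biomass_split(h, constants)
        asp_necro, clamped = pools.necromass_asp(total_asp, asp_bio)
        if clamped:
            flags.add("clamped")

        k = k_asp(temp, calib)
        f = constants.live_d_fraction
        if asp_necro > 0:
            d_necro = max((d_total * total_asp - f * asp_bio) / asp_necro, 0.0)
        else:
            d_necro = d_total

        t_nm = math.nan
        t_b = math.nan
        try:
            t_nm = tnm_steady_state(d_necro, k, constants.dl_live, calib.k_eq)
            t_b = tb_from_tnm(t_nm, asp_bio, asp_necro) if asp_necro > 0 else math.nan
        except BelowLiveRatioError:
            flags.add("below_live_ratio")
        except NearEquilibriumError:
            flags.add("near_equilibrium")
            t_nm = math.inf
            t_b = math.inf if asp_bio > 0 else 0.0

        results.append(
            TurnoverResult(
                depth=depth,
                temperature=temp,
                k_asp=k,
                d_necro=d_necro,
                t_nm=t_nm,
                t_b=t_b,
                asp_bio=asp_bio,
                asp_necro=asp_necro,
                flags=frozenset(flags),
            )
        )
    return results
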