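"""Synthetic station generator.

Builds complete stations with the statistical structure the analysis
assumes: exponentially depth-decaying THAA with a fixed Asp mole fraction
(so Asp is exactly linear in THAA), D- and L-Asp produced by running the
necromass ODE forward at a configured true T_NM(z) profile, total cells tied
to %TAA-C through a power law, qPCR copies from a linear archaeal-fraction
ramp, and an exponential excess-Pb-210 profile from the configured
sedimentation rate. Multiplicative lognormal noise is applied last, from a
single seed; with sigma = 0 the output is a deterministic function of the
configuration.

Three templates mirror the study sites: a cold oxygen-minimum-zone station
(2.10 mm/yr, 8.83 degC at 10 m, 0.13 degC/m) and two hydrothermally heated
stations (0.79 mm/yr; 74.27 and 65.51 degC at the base of ~5 m cores,
gradients 11.44 and 9.86 degC/m). Their true T_NM profiles are log-linear
in depth between the published top/bottom turnover times and are
illustrative, not a reconstruction of the real per-horizon data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .chronology import PB210_LAMBDA, temperature_at_depth
from .indicators import pct_taa_c
from .pools import biomass_asp, cells_per_gdw, gdw_to_cm3
from .profiles_io import (
    AminoAcidComposition,
    CellAbundance,
    GeochemSample,
    Horizon,
    IsomerMeasurement,
    ModelConstants,
    RadionuclideProfile,
    StationMetadata,
)
from .racemization import RacemizationCalibration, default_calibration, forward_hydrolysis, k_asp
from .turnover import forward_necromass

# base mole-fraction weights of the protein amino acids other than Asp;
# renormalized to (1 - asp_mole_fraction). Gly:Ser comes out ~2.9,
# within the prokaryote-like range.
_BASE_WEIGHTS = {
    "gly": 20.0,
    "glu": 10.0,
    "ala": 14.0,
    "ser": 7.0,
    "thr": 6.0,
    "val": 6.0,
    "leu": 7.0,
    "ile": 4.0,
    "pro": 5.0,
    "phe": 3.0,
    "tyr": 2.0,
    "met": 1.0,
    "lys": 5.0,
    "his": 2.0,
    "arg": 4.0,
}


@dataclass(frozen=True)
class SyntheticStationConfig:
    """Everything needed to generate one station deterministically."""

    meta: StationMetadata
    depth_start: float  # cmbsf of the shallowest horizon
    depth_step: float  # cm between horizons
    n_horizons: int
    thaa_surface: float  # umol/gdw at z = 0
    thaa_decay_length: float  # cm
    asp_mole_fraction: float = 0.075
    true_tnm: tuple[float, ...] | None = None  # yr, one per horizon
    tnm_rule_c: float | None = None  # T_NM(z) = c / k_asp(T(z)) when no explicit profile
    cell_coefficient: float = 8.94e6  # cells/cm^3 at %TAA-C = 1
    cell_exponent: float = 1.44
    toc_level: float = 2000.0  # umol C / gdw
    tn_level: float = 200.0  # umol N / gdw
    arc_frac_surface: float = 0.5
    arc_frac_deep: float = 0.5
    asp_bala_surface: float = 8.0  # Asp:beta-Ala ratio at the top horizon
    asp_bala_deep: float = 2.0
    glcn_frac_of_thaa: float = 0.05
    glcn_galn_ratio: float = 1.5
    vfa_range: tuple[float, float] = (0.3, 3.0)  # uM, uniform
    pb_surface_excess: float = 100.0  # activity units at z = 0
    pb_supported: float = 20.0
    emit_hydrolysis_corrected: bool = False
    noise_sigma: float = 0.0  # lognormal sigma per measured quantity
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "depth_step",
            "n_horizons",
            "thaa_surface",
            "thaa_decay_length",
            "asp_mole_fraction",
            "toc_level",
            "tn_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.true_tnm is not None and len(self.true_tnm) != self.n_horizons:
            raise ValueError("true_tnm must have one value per horizon")
        if self.true_tnm is None and self.tnm_rule_c is None:
            raise ValueError("provide either true_tnm or tnm_rule_c")

    @property
    def depths(self) -> np.ndarray:
        return self.depth_start + self.depth_step * np.arange(self.n_horizons)

    def tnm_at(
        self, index: int, calib: RacemizationCalibration
    ) -> float:
        if self.true_tnm is not None:
            return self.true_tnm[index]
        temp = temperature_at_depth(self.meta, float(self.depths[index]))
        return self.tnm_rule_c / k_asp(temp, calib)


def _log_interp(top: float, bottom: float, n: int) -> tuple[float, ...]:
    return tuple(np.exp(np.linspace(np.log(top), np.log(bottom), n)))


def default_configs() -> dict[str, SyntheticStationConfig]:
    """The three study-site templates, metadata matching the published site table."""
    so46 = SyntheticStationConfig(
        meta=StationMetadata(
            station_id="SO241-46",
            latitude=27.7069,
            longitude=-111.2275,
            water_depth=664.0,
            core_recovery=1000.0,
            sedimentation_rate=2.10,
            temp_deepest=8.83,
            temp_gradient=0.13,
            location_type="Marine, with minimal terrestrial influence, OMZ",
        ),
        depth_start=250.0,
        depth_step=100.0,
        n_horizons=10,
        thaa_surface=94.9,
        thaa_decay_length=862.2,
        true_tnm=_log_interp(1731.0, 2572.0, 10),
        toc_level=2800.0,
        tn_level=230.0,
        arc_frac_surface=0.40,
        arc_frac_deep=0.55,
        asp_bala_surface=8.0,
        asp_bala_deep=5.0,
    )
    so51 = SyntheticStationConfig(
        meta=StationMetadata(
            station_id="SO241-51",
            latitude=27.4079,
            longitude=-111.3896,
            water_depth=1840.0,
            core_recovery=487.0,
            sedimentation_rate=0.79,
            temp_deepest=74.27,
            temp_gradient=11.44,
            location_type="Hydrothermal",
        ),
        depth_start=37.0,
        depth_step=50.0,
        n_horizons=10,
        thaa_surface=34.8,
        thaa_decay_length=170.5,
        true_tnm=_log_interp(182.0, 8.0, 10),
        toc_level=1500.0,
        tn_level=120.0,
        arc_frac_surface=0.5,
        arc_frac_deep=0.9,
    )
    so58 = SyntheticStationConfig(
        meta=StationMetadata(
            station_id="SO241-58",
            latitude=27.4081,
            longitude=-111.3896,
            water_depth=1845.0,
            core_recovery=498.0,
            sedimentation_rate=0.79,
            temp_deepest=65.51,
            temp_gradient=9.86,
            location_type="Hydrothermal",
        ),
        depth_start=48.0,
        depth_step=50.0,
        n_horizons=10,
        thaa_surface=71.3,
        thaa_decay_length=104.2,
        true_tnm=_log_interp(63.0, 4.0, 10),
        toc_level=1900.0,
        tn_level=120.0,
        arc_frac_surface=0.5,
        arc_frac_deep=0.9,
    )
    return {"SO241-46": so46, "SO241-51": so51, "SO241-58": so58}


def _noise(rng: np.random.Generator, sigma: float) -> float:
    return float(rng.lognormal(0.0, sigma)) if sigma > 0 else 1.0


def generate_station(
    config: SyntheticStationConfig,
    constants: ModelConstants | None = None,
    calib: RacemizationCalibration | None = None,
) -> tuple[StationMetadata, list[Horizon], RadionuclideProfile]:
    """Generate one station's horizons and its radionuclide profile."""
    constants = constants or ModelConstants()
    calib = calib or default_calibration()
    rng = np.random.default_rng(config.seed)
    f = constants.live_d_fraction

    non_asp = {k: v / sum(_BASE_WEIGHTS.values()) * (1.0 - config.asp_mole_fraction) for k, v in _BASE_WEIGHTS.items()}

    horizons: list[Horizon] = []
    n = config.n_horizons
    for i, depth in enumerate(config.depths):
        depth = float(depth)
        temp = temperature_at_depth(config.meta, depth)
        k = k_asp(temp, calib)
        ramp = i / (n - 1) if n > 1 else 0.0

        thaa_true = config.thaa_surface * np.exp(-depth / config.thaa_decay_length)
        fractions = dict(non_asp)
        fractions["asp"] = config.asp_mole_fraction
        conc = {name: frac * thaa_true for name, frac in fractions.items()}

        # degradation products ramp up relative to their precursors down-core
        asp_bala = config.asp_bala_surface + (config.asp_bala_deep - config.asp_bala_surface) * ramp
        conc["bala"] = conc["asp"] / asp_bala
        conc["gaba"] = conc["glu"] / asp_bala
        conc["glcn"] = config.glcn_frac_of_thaa * thaa_true
        conc["galn"] = conc["glcn"] / config.glcn_galn_ratio

        # cells from the quality power law on the noise-free %TAA-C
        taac, _ = pct_taa_c(AminoAcidComposition(conc), config.toc_level)
        cells_cm3 = config.cell_coefficient * taac**config.cell_exponent
        arc_frac = config.arc_frac_surface + (config.arc_frac_deep - config.arc_frac_surface) * ramp
        bac_cells = cells_cm3 * (1.0 - arc_frac)
        arc_cells = cells_cm3 * arc_frac

        # isomers: necromass at the steady state of the forward ODE, biomass at f
        asp_total = conc["asp"]
        cells_gdw = cells_per_gdw(cells_cm3, constants.porosity, constants.grain_density)
        asp_bio = biomass_asp(cells_gdw * (1.0 - arc_frac), cells_gdw * arc_frac, constants)
        asp_necro = asp_total - asp_bio
        if asp_necro <= 0:
            raise ValueError("configured biomass exceeds the total Asp pool")
        t_nm = config.tnm_at(i, calib)
        d_necro = forward_necromass(t_nm, k, constants.dl_live, asp_necro, k_eq=calib.k_eq)
        d_total = (d_necro * asp_necro + f * asp_bio) / asp_total
        if not config.emit_hydrolysis_corrected:
            d_total = forward_hydrolysis(d_total, constants.hydrolysis_induced_fraction)
        d_nmol = d_total * asp_total * 1000.0
        l_nmol = (1.0 - d_total) * asp_total * 1000.0

        # measurement noise, applied independently per measured quantity
        sigma = config.noise_sigma
        conc = {name: v * _noise(rng, sigma) for name, v in conc.items()}
        composition = AminoAcidComposition(conc)
        sample = GeochemSample(
            depth=depth,
            toc=config.toc_level * _noise(rng, sigma),
            tn=config.tn_level * _noise(rng, sigma),
            thaa=composition.protein_thaa(),
            composition=composition,
            formate=float(rng.uniform(*config.vfa_range)),
            acetate=float(rng.uniform(*config.vfa_range)),
            propionate=float(rng.uniform(*config.vfa_range)),
        )
        isomers = IsomerMeasurement(
            d_asp=d_nmol * _noise(rng, sigma),
            l_asp=l_nmol * _noise(rng, sigma),
            hydrolysis_corrected=config.emit_hydrolysis_corrected,
        )
        cells = CellAbundance(
            total_cells=cells_cm3 * _noise(rng, sigma),
            bac_copies=bac_cells * constants.copies_per_cell_bacteria * _noise(rng, sigma),
            arc_copies=arc_cells * constants.copies_per_cell_archaea * _noise(rng, sigma),
            copies_basis="per_cm3",
        )
        horizons.append(Horizon(sample=sample, isomers=isomers, cells=cells))

    radionuclide = _radionuclide_profile(config, rng)
    return config.meta, horizons, radionuclide


def _radionuclide_profile(config: SyntheticStationConfig, rng: np.random.Generator) -> RadionuclideProfile:
    """Multi-core intervals: 1-cm steps to 4 cm, 2-cm to 20 cm, 4-cm to 40 cm."""
    tops = np.concatenate([np.arange(0, 4, 1), np.arange(4, 20, 2), np.arange(20, 40, 4)]).astype(float)
    bottoms = np.concatenate([tops[1:], [40.0]])
    mid_mm = 0.5 * (tops + bottoms) * 10.0
    excess = config.pb_surface_excess * np.exp(-PB210_LAMBDA * mid_mm / config.meta.sedimentation_rate)
    sigma = config.noise_sigma
    if sigma > 0:
        excess = excess * rng.lognormal(0.0, sigma, size=excess.shape)
    total = excess + config.pb_supported
    return RadionuclideProfile(
        depth_top=tops,
        depth_bottom=bottoms,
        total_pb210=total,
        total_pb210_sd=0.05 * total,
        pb214=np.full_like(total, config.pb_supported),
        pb214_sd=np.full_like(total, 0.05 * config.pb_supported),
    )
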