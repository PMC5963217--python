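"""Domain types and tabular IO for station depth profiles.

All readers and writers are name-keyed CSV: column order never carries
meaning. Units are fixed at the schema level and spelled out in the column
names (depths in cmbsf, amino acids in umol per gram dry weight, isomers in
nmol per gram dry weight, cells per cm^3 wet sediment, temperatures in
degrees C). Missing optional quantities are empty cells and come back as
absent fields, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import AMINO_SUGARS, ATOM_COUNTS, PROTEIN_AMINO_ACIDS

__all__ = [
    "StationMetadata",
    "AminoAcidComposition",
    "GeochemSample",
    "IsomerMeasurement",
    "CellAbundance",
    "RadionuclideProfile",
    "TurnoverResult",
    "ModelConstants",
    "Horizon",
    "read_station",
    "write_station",
    "write_results",
    "read_results",
    "read_radionuclide",
    "write_radionuclide",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationMetadata:
    """Site descriptors anchoring the age and temperature models.

    ``temp_deepest`` is the in-situ temperature at ``core_recovery`` depth;
    the linear thermal gradient (degrees C per metre) extrapolates upward
    from that anchor.
    """

    station_id: str
    latitude: float
    longitude: float
    water_depth: float  # m
    core_recovery: float  # cm
    sedimentation_rate: float  # mm / yr
    temp_deepest: float  # degC at depth == core_recovery
    temp_gradient: float  # degC / m
    location_type: str = ""

    def __post_init__(self) -> None:
        if self.sedimentation_rate <= 0:
            raise ValueError("sedimentation_rate must be > 0")
        if self.core_recovery <= 0:
            raise ValueError("core_recovery must be > 0")
        if self.temp_gradient < 0:
            raise ValueError("temp_gradient must be >= 0")
        if self.water_depth <= 0:
            raise ValueError("water_depth must be > 0")


@dataclass(frozen=True)
class AminoAcidComposition:
    """Mapping species name -> concentration (umol / g dry weight).

    Species names follow :mod:`dlamino.chemistry`; beta-Ala, gamma-Aba and
    the amino sugars are carried but excluded from the protein-THAA sum.
    """

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if name not in ATOM_COUNTS:
                raise ValueError(f"unknown amino acid or sugar: {name!r}")
            if value < 0:
                raise ValueError(f"negative concentration for {name!r}: {value}")

    def get(self, name: str, default: float = 0.0) -> float:
        return float(self.concentrations.get(name, default))

    def protein_thaa(self) -> float:
        """Sum of protein amino acids (the THAA pool), umol/gdw."""
        return float(
            sum(v for k, v in self.concentrations.items() if k in PROTEIN_AMINO_ACIDS)
        )

    def amino_sugars(self) -> float:
        return float(sum(v for k, v in self.concentrations.items() if k in AMINO_SUGARS))

    def items(self):
        return self.concentrations.items()


@dataclass(frozen=True)
class GeochemSample:
    """One depth horizon's bulk chemistry. Optional fields are None when absent."""

    depth: float  # cmbsf, sample midpoint
    toc: float | None = None  # umol C / gdw
    tn: float | None = None  # umol N / gdw
    thaa: float | None = None  # umol / gdw
    composition: AminoAcidComposition | None = None
    formate: float | None = None  # uM pore water
    acetate: float | None = None
    propionate: float | None = None
    temperature: float | None = None  # degC, in situ

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        for name in ("toc", "tn", "thaa", "formate", "acetate", "propionate"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"negative {name}: {value}")
        if self.composition is not None and self.thaa is not None and self.thaa > 0:
            total = self.composition.protein_thaa()
            if abs(total - self.thaa) > 0.01 * self.thaa:
                raise ValueError(
                    f"THAA {self.thaa} inconsistent with composition sum {total} "
                    "(tolerance 1%)"
                )


@dataclass(frozen=True)
class IsomerMeasurement:
    """D- and L-aspartic acid amounts (nmol / gdw) for one horizon."""

    d_asp: float
    l_asp: float
    hydrolysis_corrected: bool = False

    def __post_init__(self) -> None:
        if self.d_asp < 0:
            raise ValueError("d_asp must be >= 0")
        if self.l_asp <= 0:
            raise ValueError("l_asp must be > 0")

    @property
    def d_fraction(self) -> float:
        """D / (D + L), in [0, 1)."""
        return self.d_asp / (self.d_asp + self.l_asp)

    @property
    def dl_ratio(self) -> float:
        return self.d_asp / self.l_asp


@dataclass(frozen=True)
class CellAbundance:
    """Cell counts and 16S gene copies for one horizon.

    ``copies_basis`` records whether qPCR copies are per cm^3 wet sediment or
    per gram dry weight — the source data leave this ambiguous, so the schema
    carries it explicitly.
    """

    total_cells: float | None = None  # cells / cm^3 wet sediment
    bac_copies: float | None = None
    arc_copies: float | None = None
    copies_basis: str = "per_cm3"  # or "per_gdw"
    pct_bacteria: float | None = None  # % of (Bacteria + Archaea)

    def __post_init__(self) -> None:
        if self.total_cells is not None and self.total_cells < 0:
            raise ValueError("total_cells must be >= 0")
        for name in ("bac_copies", "arc_copies"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"negative {name}")
        if self.copies_basis not in ("per_cm3", "per_gdw"):
            raise ValueError(f"unknown copies_basis {self.copies_basis!r}")
        if self.pct_bacteria is not None and not 0 <= self.pct_bacteria <= 100:
            raise ValueError("pct_bacteria must be in [0, 100]")


@dataclass
class RadionuclideProfile:
    """Per-interval total Pb-210 and Pb-214 (supported Pb-210 index) activities.

    Activities are per dry salt-free mass with 1-sigma uncertainties. The
    ``excess`` array is populated by :func:`dlamino.chronology.excess_pb210`;
    NaN marks intervals where the excess is undefined (clamped), with the
    interval index recorded in ``flags``.
    """

    depth_top: np.ndarray  # cmbsf
    depth_bottom: np.ndarray
    total_pb210: np.ndarray
    total_pb210_sd: np.ndarray
    pb214: np.ndarray
    pb214_sd: np.ndarray
    excess: np.ndarray | None = None
    flags: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (
                self.depth_top,
                self.depth_bottom,
                self.total_pb210,
                self.total_pb210_sd,
                self.pb214,
                self.pb214_sd,
            )
        ]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("all radionuclide columns must have equal length")
        (
            self.depth_top,
            self.depth_bottom,
            self.total_pb210,
            self.total_pb210_sd,
            self.pb214,
            self.pb214_sd,
        ) = arrays
        if np.any(self.depth_bottom <= self.depth_top):
            raise ValueError("intervals must have depth_bottom > depth_top")
        if np.any(np.diff(self.depth_top) <= 0):
            raise ValueError("intervals must be increasing")
        if np.any(self.depth_top[1:] < self.depth_bottom[:-1] - 1e-9):
            raise ValueError("intervals must not overlap")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.depth_top + self.depth_bottom)

    def __len__(self) -> int:
        return len(self.depth_top)


@dataclass(frozen=True)
class TurnoverResult:
    """Per-horizon model output.

    ``t_nm`` is math.inf when the horizon is flagged near_equilibrium, and
    NaN when the inversion was impossible (below_live_ratio).
    """

    depth: float  # cmbsf
    temperature: float  # degC
    k_asp: float  # 1/yr
    d_necro: float  # D fraction of necromass
    t_nm: float  # yr
    t_b: float  # yr
    asp_bio: float  # umol / gdw
    asp_necro: float  # umol / gdw
    flags: frozenset[str] = frozenset()

    _ALLOWED_FLAGS = frozenset(
        {"clamped", "near_equilibrium", "below_live_ratio", "extrapolated", "below_blank"}
    )

    def __post_init__(self) -> None:
        unknown = set(self.flags) - self._ALLOWED_FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")


@dataclass(frozen=True)
class ModelConstants:
    """Fixed model constants, all exposed through the config file.

    Defaults: living-cell D:L-Asp 0.014; hydrolysis-induced D 4.4 %;
    GlcN/GalN hydrolysis losses 25.5 %/21.6 %; 4.0 and 1.6 16S copies per
    bacterial and archaeal cell; per-cell Asp content 3e-17 mol (typical
    deep-biosphere cell, ~30 fg C, ~55 % amino-acid C, Asp ~8 mol% of
    protein); porosity 0.8, grain density 2.5 g/cm^3; Pb-210 decay constant
    0.03114 /yr.
    """

    dl_live: float = 0.014  # D:L ratio of living cells
    hydrolysis_induced_pct_d: float = 4.4  # % D produced during hydrolysis
    glcn_loss_frac: float = 0.255
    galn_loss_frac: float = 0.216
    copies_per_cell_bacteria: float = 4.0
    copies_per_cell_archaea: float = 1.6
    asp_per_cell_bacteria: float = 3e-17  # mol / cell
    asp_per_cell_archaea: float = 3e-17
    porosity: float = 0.8
    grain_density: float = 2.5  # g / cm^3
    pb210_decay_const: float = 0.03114  # 1 / yr

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.glcn_loss_frac >= 1 or self.galn_loss_frac >= 1:
            raise ValueError("loss fractions must be < 1")
        if not 0 < self.porosity < 1:
            raise ValueError("porosity must be in (0, 1)")

    @property
    def live_d_fraction(self) -> float:
        """dl_live expressed as D/(D+L)."""
        return self.dl_live / (1.0 + self.dl_live)

    @property
    def hydrolysis_induced_fraction(self) -> float:
        return self.hydrolysis_induced_pct_d / 100.0


@dataclass(frozen=True)
class Horizon:
    """Everything measured at one depth: chemistry plus optional isomers/cells."""

    sample: GeochemSample
    isomers: IsomerMeasurement | None = None
    cells: CellAbundance | None = None

    @property
    def depth(self) -> float:
        return self.sample.depth


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_META_COLUMNS = {
    "station_id": "station_id",
    "latitude_deg": "latitude",
    "longitude_deg": "longitude",
    "water_depth_m": "water_depth",
    "core_recovery_cm": "core_recovery",
    "sedimentation_rate_mm_yr": "sedimentation_rate",
    "temp_deepest_c": "temp_deepest",
    "temp_gradient_c_per_m": "temp_gradient",
    "location_type": "location_type",
}

_SAMPLE_FIXED = [
    "depth_cmbsf",
    "temperature_c",
    "toc_umol_gdw",
    "tn_umol_gdw",
    "thaa_umol_gdw",
    "formate_um",
    "acetate_um",
    "propionate_um",
    "d_asp_nmol_gdw",
    "l_asp_nmol_gdw",
    "hydrolysis_corrected",
    "total_cells_cm3",
    "bac_copies",
    "arc_copies",
    "copies_basis",
]

_RESULT_COLUMNS = [
    "depth_cmbsf",
    "temperature_c",
    "k_asp_yr",
    "d_necro",
    "t_nm_yr",
    "t_b_yr",
    "asp_bio_umol_gdw",
    "asp_necro_umol_gdw",
    "flags",
]

_RADIO_COLUMNS = [
    "depth_top_cm",
    "depth_bottom_cm",
    "pb210_total",
    "pb210_total_sd",
    "pb214",
    "pb214_sd",
]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or value == ""


def _opt(row: pd.Series, column: str) -> float | None:
    if column not in row.index:
        return None
    value = row[column]
    if _is_missing(value):
        return None
    return float(value)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_station(table_path, metadata_path) -> tuple[StationMetadata, list[Horizon]]:
    """Read a station: Table-1-style metadata plus one row per depth horizon.

    Horizons come back sorted by depth. Unknown columns, negative
    concentrations and duplicate depths are rejected with the offending
    column name or row index.
    """
    meta_df = pd.read_csv(metadata_path)
    unknown = set(meta_df.columns) - set(_META_COLUMNS)
    if unknown:
        raise ValueError(f"unknown metadata column(s): {sorted(unknown)}")
    row = meta_df.iloc[0]
    kwargs = {}
    for col, attr in _META_COLUMNS.items():
        if col in meta_df.columns and not _is_missing(row[col]):
            kwargs[attr] = row[col] if attr in ("station_id", "location_type") else float(row[col])
    meta = StationMetadata(**kwargs)

    df = pd.read_csv(table_path)
    known = set(_SAMPLE_FIXED) | set(ATOM_COUNTS)
    unknown = set(df.columns) - known
    if unknown:
        raise ValueError(f"unknown sample column(s): {sorted(unknown)}")
    if "depth_cmbsf" not in df.columns:
        raise ValueError("samples table must have a depth_cmbsf column")

    numeric = [c for c in df.columns if c not in ("hydrolysis_corrected", "copies_basis")]
    for i, r in df.iterrows():
        for col in numeric:
            v = r[col]
            if not _is_missing(v) and float(v) < 0:
                raise ValueError(f"negative value in column {col!r} at row {i}")
    depths = df["depth_cmbsf"].astype(float)
    if depths.duplicated().any():
        dupes = sorted(depths[depths.duplicated()].unique())
        raise ValueError(f"duplicate depth(s): {dupes}")

    horizons: list[Horizon] = []
    for _, r in df.sort_values("depth_cmbsf").iterrows():
        comp_values = {
            name: float(r[name]) for name in ATOM_COUNTS if name in df.columns and not _is_missing(r[name])
        }
        composition = AminoAcidComposition(comp_values) if comp_values else None
        sample = GeochemSample(
            depth=float(r["depth_cmbsf"]),
            toc=_opt(r, "toc_umol_gdw"),
            tn=_opt(r, "tn_umol_gdw"),
            thaa=_opt(r, "thaa_umol_gdw"),
            composition=composition,
            formate=_opt(r, "formate_um"),
            acetate=_opt(r, "acetate_um"),
            propionate=_opt(r, "propionate_um"),
            temperature=_opt(r, "temperature_c"),
        )
        d_asp = _opt(r, "d_asp_nmol_gdw")
        l_asp = _opt(r, "l_asp_nmol_gdw")
        isomers = None
        if d_asp is not None and l_asp is not None:
            corrected = False
            if "hydrolysis_corrected" in df.columns and not _is_missing(r["hydrolysis_corrected"]):
                corrected = bool(int(r["hydrolysis_corrected"]))
            isomers = IsomerMeasurement(d_asp, l_asp, hydrolysis_corrected=corrected)
        cells = None
        cell_fields = {
            "total_cells": _opt(r, "total_cells_cm3"),
            "bac_copies": _opt(r, "bac_copies"),
            "arc_copies": _opt(r, "arc_copies"),
        }
        if any(v is not None for v in cell_fields.values()):
            basis = "per_cm3"
            if "copies_basis" in df.columns and not _is_missing(r["copies_basis"]):
                basis = str(r["copies_basis"])
            cells = CellAbundance(copies_basis=basis, **cell_fields)
        horizons.append(Horizon(sample=sample, isomers=isomers, cells=cells))
    return meta, horizons


def write_station(meta: StationMetadata, horizons: Sequence[Horizon], table_path, metadata_path) -> None:
    """Write a station in the schema :func:`read_station` consumes."""
    meta_row = {
        "station_id": meta.station_id,
        "latitude_deg": meta.latitude,
        "longitude_deg": meta.longitude,
        "water_depth_m": meta.water_depth,
        "core_recovery_cm": meta.core_recovery,
        "sedimentation_rate_mm_yr": meta.sedimentation_rate,
        "temp_deepest_c": meta.temp_deepest,
        "temp_gradient_c_per_m": meta.temp_gradient,
        "location_type": meta.location_type,
    }
    pd.DataFrame([meta_row]).to_csv(metadata_path, index=False)

    species = sorted({name for h in horizons if h.sample.composition for name, _ in h.sample.composition.items()})
    rows = []
    for h in horizons:
        s = h.sample
        row: dict[str, object] = {
            "depth_cmbsf": s.depth,
            "temperature_c": s.temperature,
            "toc_umol_gdw": s.toc,
            "tn_umol_gdw": s.tn,
            "thaa_umol_gdw": s.thaa,
            "formate_um": s.formate,
            "acetate_um": s.acetate,
            "propionate_um": s.propionate,
        }
        for name in species:
            row[name] = s.composition.get(name) if s.composition else None
        if h.isomers is not None:
            row["d_asp_nmol_gdw"] = h.isomers.d_asp
            row["l_asp_nmol_gdw"] = h.isomers.l_asp
            row["hydrolysis_corrected"] = int(h.isomers.hydrolysis_corrected)
        if h.cells is not None:
            row["total_cells_cm3"] = h.cells.total_cells
            row["bac_copies"] = h.cells.bac_copies
            row["arc_copies"] = h.cells.arc_copies
            row["copies_basis"] = h.cells.copies_basis
        rows.append(row)
    pd.DataFrame(rows).to_csv(table_path, index=False, float_format="%.12g")


def _format_tnm(value: float) -> str:
    if math.isinf(value):
        return "inf"
    if math.isnan(value):
        return ""
    return f"{value:.12g}"


def write_results(results: Sequence[TurnoverResult], path) -> None:
    """Write turnover results; round-trips through :func:`read_results` at 12 sig digits.

    Unbounded t_nm (near-equilibrium horizons) is serialized as the "inf"
    sentinel; an impossible inversion leaves the cell empty.
    """
    if not results:
        raise ValueError("results must be nonempty")
    rows = []
    for r in results:
        rows.append(
            {
                "depth_cmbsf": f"{r.depth:.12g}",
                "temperature_c": f"{r.temperature:.12g}",
                "k_asp_yr": f"{r.k_asp:.12g}",
                "d_necro": _format_tnm(r.d_necro),
                "t_nm_yr": _format_tnm(r.t_nm),
                "t_b_yr": _format_tnm(r.t_b),
                "asp_bio_umol_gdw": f"{r.asp_bio:.12g}",
                "asp_necro_umol_gdw": f"{r.asp_necro:.12g}",
                "flags": ";".join(sorted(r.flags)),
            }
        )
    pd.DataFrame(rows, columns=_RESULT_COLUMNS).to_csv(path, index=False)


def read_results(path) -> list[TurnoverResult]:
    df = pd.read_csv(path, keep_default_na=False)
    unknown = set(df.columns) - set(_RESULT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown results column(s): {sorted(unknown)}")

    def parse(value) -> float:
        if _is_missing(value):
            return math.nan
        if str(value).strip() == "inf":
            return math.inf
        return float(value)

    out = []
    for _, r in df.iterrows():
        flags = frozenset(f for f in str(r["flags"]).split(";") if f)
        out.append(
            TurnoverResult(
                depth=float(r["depth_cmbsf"]),
                temperature=float(r["temperature_c"]),
                k_asp=float(r["k_asp_yr"]),
                d_necro=parse(r["d_necro"]),
                t_nm=parse(r["t_nm_yr"]),
                t_b=parse(r["t_b_yr"]),
                asp_bio=float(r["asp_bio_umol_gdw"]),
                asp_necro=float(r["asp_necro_umol_gdw"]),
                flags=flags,
            )
        )
    return out


def read_radionuclide(path) -> RadionuclideProfile:
    df = pd.read_csv(path)
    unknown = set(df.columns) - set(_RADIO_COLUMNS)
    if unknown:
        raise ValueError(f"unknown radionuclide column(s): {sorted(unknown)}")
    missing = set(_RADIO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing radionuclide column(s): {sorted(missing)}")
    df = df.sort_values("depth_top_cm")
    return RadionuclideProfile(
        depth_top=df["depth_top_cm"].to_numpy(float),
        depth_bottom=df["depth_bottom_cm"].to_numpy(float),
        total_pb210=df["pb210_total"].to_numpy(float),
        total_pb210_sd=df["pb210_total_sd"].to_numpy(float),
        pb214=df["pb214"].to_numpy(float),
        pb214_sd=df["pb214_sd"].to_numpy(float),
    )


def write_radionuclide(profile: RadionuclideProfile, path) -> None:
    pd.DataFrame(
        {
            "depth_top_cm": profile.depth_top,
            "depth_bottom_cm": profile.depth_bottom,
            "pb210_total": profile.total_pb210,
            "pb210_total_sd": profile.total_pb210_sd,
            "pb214": profile.pb214,
            "pb214_sd": profile.pb214_sd,
        }
    ).to_csv(path, index=False, float_format="%.12g")
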