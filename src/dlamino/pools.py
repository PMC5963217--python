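"""Cell observations to model pools.

Gene copies become cells through fixed per-cell 16S copy numbers; total cell
counts (per cm^3 wet sediment) become per-gram-dry-weight through the
porosity/grain-density bridge; cells become biomass Asp through a per-cell
Asp content. Total counts set the biomass size; qPCR sets only the
Bacteria/Archaea split.
"""

from __future__ import annotations

from .profiles_io import ModelConstants

MOL_TO_UMOL = 1e6


def cells_from_copies(
    bac_copies: float, arc_copies: float, constants: ModelConstants
) -> tuple[float, float]:
    """Convert 16S gene copies to cell numbers (4.0 copies/Bacteria, 1.6/Archaea)."""
    if bac_copies < 0 or arc_copies < 0:
        raise ValueError("copies must be >= 0")
    return (
        bac_copies / constants.copies_per_cell_bacteria,
        arc_copies / constants.copies_per_cell_archaea,
    )


def pct_bacteria(bac_cells: float, arc_cells: float) -> float:
    """Relative contribution of Bacteria to (Bacteria + Archaea), percent."""
    total = bac_cells + arc_cells
    if total <= 0:
        raise ValueError("need at least one cell")
    return 100.0 * bac_cells / total


def cells_per_gdw(cells_per_cm3: float, porosity: float, grain_density: float) -> float:
    """Convert cells per cm^3 wet sediment to cells per gram dry weight.

    One cm^3 of wet sediment holds (1 - porosity) * grain_density grams of
    dry solids.
    """
    if not 0 < porosity < 1:
        raise ValueError("porosity must be in (0, 1)")
    if grain_density <= 0:
        raise ValueError("grain density must be > 0")
    return cells_per_cm3 / ((1.0 - porosity) * grain_density)


def gdw_to_cm3(cells_gdw: float, porosity: float, grain_density: float) -> float:
    """Inverse of :func:`cells_per_gdw`."""
    return cells_gdw * (1.0 - porosity) * grain_density


def biomass_asp(bac_cells_gdw: float, arc_cells_gdw: float, constants: ModelConstants) -> float:
    """Living-biomass Asp pool, umol/gdw, from per-gdw cell numbers."""
    if bac_cells_gdw < 0 or arc_cells_gdw < 0:
        raise ValueError("cell numbers must be >= 0")
    mol = (
        bac_cells_gdw * constants.asp_per_cell_bacteria
        + arc_cells_gdw * constants.asp_per_cell_archaea
    )
    return mol * MOL_TO_UMOL


def necromass_asp(total_asp: float, asp_bio: float) -> tuple[float, bool]:
    """Necromass Asp = total - biomass, clamped at zero. Returns (value, clamped?)."""
    if total_asp < 0:
        raise ValueError("total_asp must be >= 0")
    value = total_asp - asp_bio
    if value < 0:
        return 0.0, True
    return value, False
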