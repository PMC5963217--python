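"""Organic-matter source and diagenesis indices from amino-acid composition.

%TAA-C and %TAA-N express how much of the bulk organic carbon and nitrogen
is still present as (labile) amino acids; both fall as organic matter
degrades. Asp:beta-Ala and Glu:gamma-Aba are precursor-to-degradation-product
ratios that also fall with diagenesis, while Gly:Ser and GlcN:GalN
distinguish prokaryotic from planktonic sources. The cells-vs-%TAA-C power
law links community size to organic-matter quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .chemistry import AMINO_SUGARS, NON_PROTEIN, carbon_atoms, nitrogen_atoms
from .profiles_io import AminoAcidComposition, ModelConstants


def _amino_acid_items(composition: AminoAcidComposition):
    # amino sugars are excluded from the %TAA indices; the non-protein
    # degradation products beta-Ala and gamma-Aba do carry amino-acid C and N
    return ((k, v) for k, v in composition.items() if k not in AMINO_SUGARS)


def pct_taa_c(composition: AminoAcidComposition, toc: float) -> tuple[float, bool]:
    """Percent of TOC present as amino-acid carbon. Returns (value, inconsistent?).

    Values above 100 % are physically impossible and flagged, not clipped.
    """
    if toc <= 0:
        raise ValueError("toc must be > 0")
    carbon = sum(carbon_atoms(name) * conc for name, conc in _amino_acid_items(composition))
    value = 100.0 * carbon / toc
    return value, value > 100.0


def pct_taa_n(composition: AminoAcidComposition, tn: float) -> tuple[float, bool]:
    """Percent of total nitrogen present as amino-acid nitrogen."""
    if tn <= 0:
        raise ValueError("tn must be > 0")
    nitrogen = sum(nitrogen_atoms(name) * conc for name, conc in _amino_acid_items(composition))
    value = 100.0 * nitrogen / tn
    return value, value > 100.0


def diagenetic_ratios(composition: AminoAcidComposition) -> dict[str, float]:
    """Mole ratios Asp:beta-Ala, Glu:gamma-Aba, Gly:Ser, GlcN:GalN.

    A ratio whose denominator is zero or absent is NaN (flagged by absence,
    never infinity).
    """
    pairs = {
        "asp_bala": ("asp", "bala"),
        "glu_gaba": ("glu", "gaba"),
        "gly_ser": ("gly", "ser"),
        "glcn_galn": ("glcn", "galn"),
    }
    out = {}
    for key, (num, den) in pairs.items():
        denominator = composition.get(den)
        out[key] = composition.get(num) / denominator if denominator > 0 else math.nan
    return out


def correct_amino_sugar(measured: float, which: str, constants: ModelConstants) -> float:
    """Correct an amino-sugar concentration for losses during acid hydrolysis.

    GlcN loses 25.5 % and GalN 21.6 % during 6 M HCl hydrolysis; the true
    concentration is measured/(1 - loss).
    """
    if measured < 0:
        raise ValueError("measured must be >= 0")
    key = which.lower()
    if key == "glcn":
        loss = constants.glcn_loss_frac
    elif key == "galn":
        loss = constants.galn_loss_frac
    else:
        raise ValueError(f"unknown amino sugar {which!r}")
    return measured / (1.0 - loss)


def apply_amino_sugar_loss(true_value: float, which: str, constants: ModelConstants) -> float:
    """Forward loss map, inverse of :func:`correct_amino_sugar`."""
    key = which.lower()
    loss = {"glcn": constants.glcn_loss_frac, "galn": constants.galn_loss_frac}[key]
    return true_value * (1.0 - loss)


def indicator_table(horizons, constants: ModelConstants) -> "pd.DataFrame":
    """Per-horizon indicator CSV table: depth, %TAA-C/N, the four ratios, flags."""
    import pandas as pd

    rows = []
    for h in horizons:
        s = h.sample
        flags = []
        row: dict[str, float | str] = {"depth_cmbsf": s.depth}
        if s.composition is not None and s.toc is not None and s.toc > 0:
            value, inconsistent = pct_taa_c(s.composition, s.toc)
            row["pct_taa_c"] = value
            if inconsistent:
                flags.append("taa_c_gt_100")
        if s.composition is not None and s.tn is not None and s.tn > 0:
            value, inconsistent = pct_taa_n(s.composition, s.tn)
            row["pct_taa_n"] = value
            if inconsistent:
                flags.append("taa_n_gt_100")
        if s.composition is not None:
            ratios = diagenetic_ratios(s.composition)
            for key, value in ratios.items():
                if math.isnan(value):
                    flags.append(f"{key}_undefined")
                else:
                    row[key] = value
        row["flags"] = ";".join(flags)
        rows.append(row)
    columns = [
        "depth_cmbsf",
        "pct_taa_c",
        "pct_taa_n",
        "asp_bala",
        "glu_gaba",
        "gly_ser",
        "glcn_galn",
        "flags",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


@dataclass(frozen=True)
class PowerLawFit:
    coefficient: float
    exponent: float
    r: float  # correlation of the log-log fit
    n: int


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> PowerLawFit:
    """Fit y = a * x^b by OLS on (ln x, ln y); r is the log-log correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive values")
    fit = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        coefficient=float(np.exp(fit.intercept)),
        exponent=float(fit.slope),
        r=float(fit.rvalue),
        n=len(x),
    )
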