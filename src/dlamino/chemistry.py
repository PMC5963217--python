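"""Per-species atom counts for hydrolysable amino acids and amino sugars.

Counts are for the free molecules released by 6 M HCl hydrolysis. Keys are the
short lowercase names used throughout the tabular schemas; ``bala`` and
``gaba`` are the non-protein degradation products beta-alanine and
gamma-aminobutyric acid, ``glcn``/``galn`` the amino sugars.
"""

from __future__ import annotations

from types import MappingProxyType

#: (carbon atoms, nitrogen atoms) per molecule
ATOM_COUNTS = MappingProxyType(
    {
        "asp": (4, 1),
        "glu": (5, 1),
        "gly": (2, 1),
        "ser": (3, 1),
        "ala": (3, 1),
        "thr": (4, 1),
        "val": (5, 1),
        "leu": (6, 1),
        "ile": (6, 1),
        "pro": (5, 1),
        "phe": (9, 1),
        "tyr": (9, 1),
        "met": (5, 1),
        "lys": (6, 2),
        "his": (6, 3),
        "arg": (6, 4),
        "bala": (3, 1),
        "gaba": (4, 1),
        "glcn": (6, 1),
        "galn": (6, 1),
    }
)

#: non-protein amino acids, excluded from the protein-THAA sum
NON_PROTEIN = frozenset({"bala", "gaba"})

#: amino sugars, excluded from THAA and from the %TAA indices
AMINO_SUGARS = frozenset({"glcn", "galn"})

#: names that count toward total hydrolysable (protein) amino acids
PROTEIN_AMINO_ACIDS = frozenset(ATOM_COUNTS) - NON_PROTEIN - AMINO_SUGARS


def carbon_atoms(name: str) -> int:
    return ATOM_COUNTS[name][0]


def nitrogen_atoms(name: str) -> int:
    return ATOM_COUNTS[name][1]
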