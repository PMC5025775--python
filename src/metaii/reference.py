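"""Published retinal-pocket distances and synthetic stand-in models.

Reference distances (Å) reported for the deposited bovine rhodopsin crystal
structures (PDB entries 1U19 and 1GZM), for the NMR-derived Meta-II
geometry, and for the Meta-II crystal structures, kept here as documented
constants.  ``synthetic_pocket_model`` builds a toy coordinate model that
encodes a chosen distance set exactly — a synthetic stand-in for the real
deposition, useful offline and for ground-truthed tests; fetch the real
entries with :func:`metaii.structure.read_structure` ("1U19"/"1GZM") to
measure the deposited coordinates themselves.
"""

from __future__ import annotations

from .structure import CoordinateModel
from .synthetic import generate_toy_structure

__all__ = [
    "TYR_GLY_CONTACTS_1U19",
    "POCKET_DISTANCES_1U19",
    "ORIENTATION_1GZM",
    "META_II_NMR_DISTANCES",
    "META_II_CRYSTAL_DISTANCES",
    "synthetic_pocket_model",
]

#: The six extracellular Tyr(CZ)-Gly(CA) contacts of dark-state rhodopsin
#: (1U19) under the 6 Å DARR cutoff.
TYR_GLY_CONTACTS_1U19 = {
    ("TYR10:CZ", "GLY3:CA"): 3.9,
    ("TYR10:CZ", "GLY280:CA"): 4.4,
    ("TYR29:CZ", "GLY101:CA"): 4.0,
    ("TYR178:CZ", "GLY114:CA"): 4.5,
    ("TYR191:CZ", "GLY188:CA"): 5.2,
    ("TYR268:CZ", "GLY188:CA"): 5.3,
}

#: Other dark-state (1U19) pocket distances used by the analysis: the
#: retinal C19 methyl to the EL2/H6 tyrosines, the EL2 backbone control
#: pair, the two sub-6 Å Tyr-Cys(C=O) pairs, and the C18 methyl to the
#: Phe261 ring carbons (4.9-5.4 Å).
POCKET_DISTANCES_1U19 = {
    ("RET:C19", "TYR268:CZ"): 4.3,
    ("RET:C19", "TYR191:CZ"): 4.7,
    ("CYS187:C", "GLY188:CA"): 2.4,
    ("TYR136:CZ", "CYS140:C"): 5.1,
    ("TYR206:CZ", "CYS167:C"): 5.9,
    ("RET:C18", "PHE261:CG"): 4.9,
    ("RET:C18", "PHE261:CD1"): 5.0,
    ("RET:C18", "PHE261:CD2"): 5.1,
    ("RET:C18", "PHE261:CE1"): 5.2,
    ("RET:C18", "PHE261:CE2"): 5.3,
    ("RET:C18", "PHE261:CZ"): 5.4,
}

#: Dark-state retinal-Tyr268 distances from the 1GZM rhodopsin structure.
ORIENTATION_1GZM = {
    ("RET:C20", "TYR268:CZ"): 4.1,
    ("RET:C12", "TYR268:CZ"): 4.5,
}

#: NMR-derived Meta-II geometry: C20 swings toward Tyr268 while C12 moves
#: away; the C19-tyrosine crosspeaks are lost (> 6-6.5 Å).
META_II_NMR_DISTANCES = {
    ("RET:C20", "TYR268:CZ"): 4.4,
    ("RET:C12", "TYR268:CZ"): 5.6,
}

#: Meta-II crystal structures place the retinal the other way around.
META_II_CRYSTAL_DISTANCES = {
    ("RET:C12", "TYR268:CZ"): 3.9,
    ("RET:C20", "TYR268:CZ"): 5.9,
}


def synthetic_pocket_model(distances: dict, source: str = "synthetic-pocket",
                           path=None) -> CoordinateModel:
    """Toy coordinate model realizing a reference distance set exactly.

    This is a synthetic construct, not deposited coordinates: atoms are
    placed so every listed pair distance holds, with unrelated groups laid
    out far apart.
    """
    spec = [(a, b, d) for (a, b), d in distances.items()]
    return CoordinateModel(generate_toy_structure(spec, path=path), source=source)
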