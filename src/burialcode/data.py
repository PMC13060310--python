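"""Built-in constant tables: residue codes, atomic radii, reference areas,
hydrophobicity scales and side-chain volumes.

All tables are plain dictionaries so they can be copied, edited and passed
back into the API; file-based overrides are handled in :mod:`burialcode.io`.
"""

from __future__ import annotations

STANDARD_AA: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

#: Common non-standard residues mapped to their parent standard type.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "KCX": "LYS", "CME": "CYS", "CSD": "CYS",
}

#: Element-based van der Waals radii (Angstrom). This is the shipped
#: stand-in radii set; a custom (residue, atom) table can be layered on top.
ELEMENT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "SE": 1.90,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_RADIUS: float = 1.80

#: Theoretical maximum accessible surface areas (Angstrom^2) from
#: Tien et al. (2013) PLoS ONE 8:e80635 — loadable literature override for
#: the runtime Gly-X-Gly reference state.
TIEN_2013_MAX_ASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Eisenberg, Schwarz, Komaromy & Wall (1984) normalized consensus
#: hydrophobicity scale — the default h_i table.
EISENBERG_CONSENSUS: dict[str, float] = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}

#: Kyte & Doolittle (1982) hydropathy — alternate scale.
KYTE_DOOLITTLE: dict[str, float] = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "eisenberg_consensus": EISENBERG_CONSENSUS,
    "kyte_doolittle": KYTE_DOOLITTLE,
}

#: Mean residue volumes (Angstrom^3), Zamyatnin (1972) — used to size the
#: single pseudo-side-chain sphere of the coarse synthetic representation.
RESIDUE_VOLUME: dict[str, float] = {
    "GLY": 60.1, "ALA": 88.6, "SER": 89.0, "CYS": 108.5, "ASP": 111.1,
    "PRO": 112.7, "ASN": 114.1, "THR": 116.1, "GLU": 138.4, "VAL": 140.0,
    "GLN": 143.8, "HIS": 153.2, "MET": 162.9, "ILE": 166.7, "LEU": 166.7,
    "LYS": 168.6, "ARG": 173.4, "PHE": 189.9, "TYR": 193.6, "TRP": 227.8,
}


def pseudo_sidechain_radius(res_type: str) -> float:
    """Radius of a single sphere holding the side-chain volume beyond glycine.

    Glycine itself has no pseudo-atom (returns 0.0).
    """
    import math

    dv = RESIDUE_VOLUME[res_type] - RESIDUE_VOLUME["GLY"]
    if dv <= 0.0:
        return 0.0
    return max(1.0, (3.0 * dv / (4.0 * math.pi)) ** (1.0 / 3.0))
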