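"""Idealized backbone geometry: internal-coordinate chain building.

Backbones are grown atom by atom with the natural-extension reference frame
(NeRF) construction from ideal bond lengths/angles and supplied (phi, psi)
torsions; omega is fixed trans.  A single residue-typed pseudo-atom at the
C-beta position stands in for the side chain when requested, sized from the
residue's mean volume.
"""

from __future__ import annotations

import numpy as np

from .data import pseudo_sidechain_radius
from .io import RadiiTable, DEFAULT_RADII
from .structures import AtomRecord, ResidueRecord, Structure

# Engh & Huber-style ideal backbone parameters (lengths A, angles deg)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

#: canonical (phi, psi) in degrees
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 120.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom D given A-B-C, |CD|, angle(BCD) and dihedral(ABCD)."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-bond * np.cos(ang),
         bond * np.sin(ang) * np.cos(tor),
         bond * np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                length: float = 1.521) -> np.ndarray:
    """Idealized C-beta position from the backbone N, CA, C atoms."""
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    v = -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc
    return ca + v


def build_chain(
    sequence: list[str],
    phi: np.ndarray,
    psi: np.ndarray,
    sidechain_mode: str = "pseudo",
    radii: RadiiTable | None = None,
    chain_id: str = "A",
    name: str = "",
) -> Structure:
    """Build an N/CA/C/O backbone from per-residue (phi, psi) torsions.

    phi[0] is unused (no preceding carbonyl).  ``sidechain_mode``:
    ``none`` (backbone only), ``cbeta`` (plain carbon at the C-beta
    position), ``pseudo`` (volume-scaled typed sphere at C-beta; glycine
    gets none).
    """
    radii = radii or DEFAULT_RADII
    nres = len(sequence)
    if not (len(phi) == len(psi) == nres):
        raise ValueError("phi/psi length must equal sequence length")

    N = np.zeros((nres, 3))
    CA = np.zeros((nres, 3))
    C = np.zeros((nres, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, nres):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          BOND_CA_C, ANGLE_N_CA_C, phi[i])

    residues = []
    for i, res_type in enumerate(sequence):
        # carbonyl O in the peptide plane, anti to the next N
        o = place_atom(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi[i] + 180.0)
        atoms = [
            AtomRecord("N", "N", N[i], radii.radius(res_type, "N", "N")),
            AtomRecord("CA", "C", CA[i], radii.radius(res_type, "CA", "C")),
            AtomRecord("C", "C", C[i], radii.radius(res_type, "C", "C")),
            AtomRecord("O", "O", o, radii.radius(res_type, "O", "O")),
        ]
        if sidechain_mode != "none" and res_type != "GLY":
            cb = ideal_cbeta(N[i], CA[i], C[i])
            if sidechain_mode == "cbeta":
                atoms.append(AtomRecord("CB", "C", cb, radii.radius(res_type, "CB", "C")))
            elif sidechain_mode == "pseudo":
                r = pseudo_sidechain_radius(res_type)
                if r > 0:
                    atoms.append(AtomRecord("CB", "C", cb, r))
            else:
                raise ValueError(f"unknown sidechain_mode {sidechain_mode!r}")
        residues.append(ResidueRecord(res_type, i, atoms))
    return Structure(residues, chain_id=chain_id, name=name)


def extended_tripeptide(
    center_type: str,
    sidechain_mode: str = "pseudo",
    radii: RadiiTable | None = None,
) -> Structure:
    """Extended Gly-X-Gly host peptide used as the rSASA reference state."""
    phi0, psi0 = STRAND_PHI_PSI
    phi = np.full(3, phi0)
    psi = np.full(3, psi0)
    return build_chain(["GLY", center_type, "GLY"], phi, psi,
                       sidechain_mode=sidechain_mode, radii=radii,
                       name=f"GXG-{center_type}")
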