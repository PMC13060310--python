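"""Core domain types: atoms, residues, chains and aligned target/model pairs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import STANDARD_AA, THREE_TO_ONE


class StructureError(ValueError):
    """Base class for structure-level errors."""


class EmptyStructureError(StructureError):
    """Raised when a file or selection yields no standard residues."""


class ChainNotFoundError(StructureError, LookupError):
    """Raised when a requested chain identifier is absent."""


class UngappablePairError(StructureError):
    """Raised when the optimal global alignment of a target/model pair
    contains interior gaps; only end-length differences are supported."""


@dataclass
class AtomRecord:
    """One heavy atom: name, element, position (A), radius (A), occupancy."""

    name: str
    element: str
    coords: np.ndarray
    radius: float
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be a finite 3-vector")
        if self.radius <= 0:
            raise StructureError(f"atom {self.name}: radius must be positive")


@dataclass
class ResidueRecord:
    """One amino-acid residue with its ordered heavy atoms.

    ``seq_index`` is the 0-based ordinal position in the chain; the original
    PDB residue number (and insertion code) is kept as metadata only.
    """

    type: str
    seq_index: int
    atoms: list[AtomRecord]
    pdb_number: int | None = None
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if self.type not in STANDARD_AA:
            raise StructureError(f"unknown residue type {self.type!r}")
        if not self.atoms:
            raise StructureError(f"residue {self.type}{self.seq_index}: no atoms")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE[self.type]


@dataclass
class Structure:
    """A single protein chain as an ordered list of residues."""

    residues: list[ResidueRecord]
    chain_id: str = "A"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyStructureError("structure must contain at least one residue")
        idx = [r.seq_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise StructureError("residue seq_index must be strictly increasing")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) array of all atom coordinates in residue/atom order."""
        return np.array([a.coords for r in self.residues for a in r.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for r in self.residues for a in r.atoms])

    def atom_residue_index(self) -> np.ndarray:
        """Residue ordinal for each atom, aligned with :meth:`coords`."""
        return np.array(
            [i for i, r in enumerate(self.residues) for _ in r.atoms], dtype=int
        )

    def atom_coords(self, name: str) -> np.ndarray:
        """(N, 3) coordinates of the named atom in every residue.

        Raises if any residue lacks the atom.
        """
        out = np.empty((len(self.residues), 3))
        for i, res in enumerate(self.residues):
            a = res.atom(name)
            if a is None:
                raise StructureError(
                    f"residue {res.type}{res.seq_index} has no atom {name!r}"
                )
            out[i] = a.coords
        return out

    def with_coords(self, coords: np.ndarray, name: str | None = None) -> "Structure":
        """Copy of the structure with all atom coordinates replaced."""
        coords = np.asarray(coords, dtype=float)
        residues = []
        k = 0
        for res in self.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(
                    AtomRecord(a.name, a.element, coords[k], a.radius, a.occupancy)
                )
                k += 1
            residues.append(
                ResidueRecord(res.type, res.seq_index, atoms, res.pdb_number,
                              res.insertion_code)
            )
        if k != len(coords):
            raise StructureError("coordinate array length does not match atom count")
        return Structure(residues, self.chain_id, name if name is not None else self.name)

    def subset(self, start: int, stop: int) -> "Structure":
        """Residues [start, stop) re-indexed to a contiguous 0-based chain."""
        sel = self.residues[start:stop]
        if not sel:
            raise EmptyStructureError("empty residue selection")
        residues = [
            ResidueRecord(r.type, i, list(r.atoms), r.pdb_number, r.insertion_code)
            for i, r in enumerate(sel)
        ]
        return Structure(residues, self.chain_id, self.name)


@dataclass
class AlignedPair:
    """A target/model pair trimmed so both chains have equal length.

    ``mapping`` pairs the retained positions in the *original* coordinates of
    each input structure; it is strictly increasing in both columns.
    """

    target: Structure
    model: Structure
    mapping: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.target.n_residues != self.model.n_residues:
            raise StructureError("aligned pair must have equal lengths after trimming")
        for (a0, b0), (a1, b1) in zip(self.mapping, self.mapping[1:]):
            if a1 <= a0 or b1 <= b0:
                raise StructureError("mapping must be strictly increasing")
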