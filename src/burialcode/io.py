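"""Reading and writing PDB structures and target/model pair alignment.

Parsing is delegated to biotite (altloc resolution by occupancy, gzip
support); the parsed chain is converted to the package's residue/atom model
with radii attached from the active radii table.  Global sequence alignment
uses Biopython's ``PairwiseAligner`` with BLOSUM62 and affine gap penalties
(open -10, extend -0.5, the first gap position charged open+extend).
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
import warnings
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from biotite.structure.io.pdb import PDBFile

from .data import DEFAULT_RADIUS, ELEMENT_RADII, NONSTANDARD_PARENT, STANDARD_AA
from .structures import (
    AlignedPair,
    AtomRecord,
    ChainNotFoundError,
    EmptyStructureError,
    ResidueRecord,
    Structure,
    StructureError,
    UngappablePairError,
)

logger = logging.getLogger(__name__)


class RadiiTable:
    """Atomic radii: per-(residue, atom-name) entries with element fallback.

    The override file format is JSON: ``{"element": {"C": 1.7, ...},
    "atoms": {"ALA CB": 1.88, ...}, "default": 1.8}``.  All radii in A.
    """

    def __init__(
        self,
        element: dict[str, float] | None = None,
        atoms: dict[tuple[str, str], float] | None = None,
        default: float = DEFAULT_RADIUS,
    ) -> None:
        self.element = dict(ELEMENT_RADII if element is None else element)
        self.atoms = dict(atoms or {})
        self.default = float(default)

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiiTable":
        with open(path) as fh:
            raw = json.load(fh)
        atoms = {}
        for key, r in raw.get("atoms", {}).items():
            res, name = key.split()
            atoms[(res, name)] = float(r)
        return cls(
            element=raw.get("element") or None,
            atoms=atoms,
            default=float(raw.get("default", DEFAULT_RADIUS)),
        )

    def radius(self, res_type: str, atom_name: str, element: str) -> float:
        r = self.atoms.get((res_type, atom_name))
        if r is not None:
            return r
        return self.element.get(element.upper(), self.default)

    def key(self) -> tuple:
        """Hashable identity used for cache invalidation."""
        return (
            tuple(sorted(self.element.items())),
            tuple(sorted(self.atoms.items())),
            self.default,
        )


DEFAULT_RADII = RadiiTable()

_BACKBONE_ONLY_ELEMENTS = {"H", "D"}


def read_structure(
    path: str | Path,
    chain: str | None = None,
    radii: RadiiTable | None = None,
) -> Structure:
    """Read the first (or named) protein chain from a PDB file.

    Hydrogens, waters and hetero-groups are excluded; alternate locations are
    resolved to the highest occupancy; common non-standard residues (MSE ...)
    are mapped to their parent standard type, unmappable residues dropped
    with a warning.  Gzipped files (``.gz``) are handled transparently.
    """
    radii = radii or DEFAULT_RADII
    path = Path(path)
    try:
        if path.suffix == ".gz":
            with gzip.open(path, "rt") as fh:
                pdb = PDBFile.read(fh)
        else:
            pdb = PDBFile.read(str(path))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            arr = pdb.get_structure(model=1, altloc="occupancy",
                                    extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises various parse errors
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    chains = list(dict.fromkeys(arr.chain_id))
    if chain is None:
        chain_id = chains[0]
    elif chain in chains:
        chain_id = chain
    else:
        raise ChainNotFoundError(f"chain {chain!r} not in {path} (has {chains})")

    sub = arr[arr.chain_id == chain_id]
    return _from_biotite(sub, chain_id, radii, name=path.stem)


def _from_biotite(arr, chain_id: str, radii: RadiiTable, name: str = "") -> Structure:
    residues: list[ResidueRecord] = []
    # group atoms by (res_id, ins_code) in file order
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * arr.array_length()
    for i in range(arr.array_length()):
        key = (int(arr.res_id[i]), str(ins[i]))
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(i)

    seq_index = 0
    for key in order:
        idx = groups[key]
        res_name = str(arr.res_name[idx[0]])
        std = res_name if res_name in STANDARD_AA else NONSTANDARD_PARENT.get(res_name)
        if std is None:
            if str(arr.hetero[idx[0]]) not in ("True", "1") or res_name not in ("HOH", "WAT"):
                logger.warning("dropping unmappable residue %s %s", res_name, key)
            continue
        atoms: list[AtomRecord] = []
        for i in idx:
            element = str(arr.element[i]).upper()
            if element in _BACKBONE_ONLY_ELEMENTS:
                continue
            atom_name = str(arr.atom_name[i])
            if res_name == "MSE" and atom_name == "SE":
                atom_name, element = "SD", "S"
            occ = float(arr.occupancy[i]) if "occupancy" in arr.get_annotation_categories() else 1.0
            atoms.append(
                AtomRecord(
                    name=atom_name,
                    element=element,
                    coords=np.array(arr.coord[i], dtype=float),
                    radius=radii.radius(std, atom_name, element),
                    occupancy=occ,
                )
            )
        if not atoms:
            continue
        residues.append(
            ResidueRecord(std, seq_index, atoms, pdb_number=key[0], insertion_code=key[1])
        )
        seq_index += 1

    if not residues:
        raise EmptyStructureError(f"no standard protein residues in chain {chain_id!r}")
    return Structure(residues, chain_id=chain_id, name=name)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure back to a minimal single-chain PDB file."""
    lines = []
    serial = 1
    for res in structure.residues:
        resnum = res.pdb_number if res.pdb_number is not None else res.seq_index + 1
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{res.type:>4s} {structure.chain_id:1s}"
                f"{resnum:4d}{res.insertion_code:1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _make_aligner(gap_open: float, gap_extend: float, substitution: str | object):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution, str):
        substitution = substitution_matrices.load(substitution)
    aligner.substitution_matrix = substitution
    # affine with first gap position charged open+extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_and_trim(
    target: Structure,
    model: Structure,
    substitution: str | object = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignedPair:
    """Globally align the two sequences and trim terminal overhangs so the
    lengths match exactly.

    Model and target chains from prediction experiments typically differ
    only by a few residues on the ends; an optimal alignment with *interior*
    gaps is rejected with :class:`UngappablePairError`.
    """
    aligner = _make_aligner(gap_open, gap_extend, substitution)
    aln = aligner.align(target.sequence, model.sequence)[0]
    blocks_t, blocks_m = aln.aligned
    if len(blocks_t) == 0:
        raise UngappablePairError("alignment has empty overlap")
    if len(blocks_t) > 1:
        raise UngappablePairError(
            "optimal global alignment contains interior gaps; "
            "only end-length differences are supported"
        )
    (t0, t1), (m0, m1) = blocks_t[0], blocks_m[0]
    if t1 - t0 < 1:
        raise UngappablePairError("alignment has empty overlap")
    mapping = [(int(t0 + k), int(m0 + k)) for k in range(t1 - t0)]
    return AlignedPair(target.subset(t0, t1), model.subset(m0, m1), mapping)


def alignment_score(
    seq_a: str,
    seq_b: str,
    substitution: str | object = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal global alignment score under the package's affine convention."""
    aligner = _make_aligner(gap_open, gap_extend, substitution)
    return float(aligner.score(seq_a, seq_b))
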