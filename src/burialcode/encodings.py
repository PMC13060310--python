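"""Label channels over structures: contact maps, hydrogen-bond satisfaction,
three-state secondary structure, and ingestion of external alphabet strings.

Every channel ends up as a :class:`LabelSet` — a sequence of categorical
labels over a finite alphabet, per residue or per residue pair — so that the
same agreement (phi) and information machinery applies uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .geometry import place_atom
from .structures import Structure, StructureError

DEFAULT_CONTACT_CUTOFF = 8.0

#: Kabsch-Sander electrostatic constant: q1*q2*f = 0.42*0.20*332 kcal*A/mol
KS_COUPLING = 27.888
DEFAULT_HBOND_ENERGY_CUTOFF = -0.5


@dataclass
class LabelSet:
    """Categorical labels over a finite alphabet.

    ``labels`` stores alphabet indices; ``kind`` is ``"residue"`` (length N)
    or ``"pair"`` (flattened upper triangle).
    """

    labels: np.ndarray
    alphabet: tuple
    kind: str = "residue"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.alphabet = tuple(self.alphabet)
        if self.kind not in ("residue", "pair"):
            raise ValueError("kind must be 'residue' or 'pair'")
        if len(self.alphabet) < 1:
            raise ValueError("alphabet must be non-empty")
        if self.labels.size and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.alphabet)):
            raise ValueError("label index outside alphabet")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.alphabet)

    def symbols(self) -> list:
        return [self.alphabet[i] for i in self.labels]


@dataclass
class ContactMap:
    """Symmetric binary contact matrix; the diagonal is always 0/excluded."""

    matrix: np.ndarray
    cutoff: float
    atom_mode: str = "CA"
    min_separation: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        n = len(self.matrix)
        if self.matrix.shape != (n, n):
            raise ValueError("contact matrix must be square")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_residues(self) -> int:
        return len(self.matrix)

    def n_contacts(self) -> int:
        return int(np.triu(self.matrix, 1).sum())


def _pair_index(n: int, min_separation: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-major upper-triangle (i, j) indices with |i-j| > min_separation."""
    iu, ju = np.triu_indices(n, k=1)
    keep = (ju - iu) > min_separation
    return iu[keep], ju[keep]


def contact_map(
    structure: Structure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    atom_mode: str = "CA",
    min_separation: int = 0,
) -> ContactMap:
    """Binary contact map: c_ij = 1 iff the atom-atom distance is strictly
    below the cutoff and |i-j| > min_separation.

    ``atom_mode`` is ``"CA"`` (default, the plain C-alpha definition) or
    ``"CB"`` (C-beta with C-alpha substituted for glycine — combined with
    ``min_separation=6`` this is the sequence-model contact convention).
    """
    if atom_mode == "CA":
        coords = structure.atom_coords("CA")
    elif atom_mode == "CB":
        coords = np.empty((structure.n_residues, 3))
        for i, res in enumerate(structure.residues):
            a = res.atom("CB") or res.atom("CA")
            if a is None:
                raise StructureError(f"residue {res.type}{i} lacks CB and CA")
            coords[i] = a.coords
    else:
        raise ValueError("atom_mode must be 'CA' or 'CB'")

    n = len(coords)
    mat = np.zeros((n, n), dtype=int)
    if n > 1:
        d = squareform(pdist(coords))
        mat = (d < cutoff).astype(int)
        np.fill_diagonal(mat, 0)
        if min_separation > 0:
            ii, jj = np.indices((n, n))
            mat[np.abs(ii - jj) <= min_separation] = 0
    return ContactMap(mat, cutoff, atom_mode, min_separation)


def flatten_pairs(cmap: ContactMap) -> LabelSet:
    """Flatten the upper triangle in fixed row-major (i<j) order into a
    binary pair-kind LabelSet; pairs at excluded separations are dropped."""
    iu, ju = _pair_index(cmap.n_residues, cmap.min_separation)
    return LabelSet(cmap.matrix[iu, ju], alphabet=(0, 1), kind="pair")


def unflatten_pairs(labels: LabelSet, n: int, min_separation: int = 0,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    atom_mode: str = "CA") -> ContactMap:
    """Inverse of :func:`flatten_pairs` for a known residue count."""
    iu, ju = _pair_index(n, min_separation)
    if len(labels) != len(iu):
        raise ValueError("label length does not match pair count")
    mat = np.zeros((n, n), dtype=int)
    mat[iu, ju] = labels.labels
    mat[ju, iu] = labels.labels
    return ContactMap(mat, cutoff, atom_mode, min_separation)


@dataclass
class HbondAssignment:
    """Backbone hydrogen bonds under the Kabsch-Sander criterion."""

    bonds: list[tuple[int, int]]          # donor residue -> acceptor residue
    energies: dict[tuple[int, int], float]  # kcal/mol per assigned bond
    satisfied: np.ndarray                 # 1 if residue takes part in >=1 bond

    def has_bond(self, donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in self.energies


def kabsch_sander_energy(c_prev: np.ndarray, o_prev_unused, n: np.ndarray,
                         h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    """Electrostatic H-bond energy (kcal/mol) between donor N-H and
    acceptor C=O:  E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN).
    """
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    return KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def reconstruct_amide_h(n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray,
                        length: float = 1.01) -> np.ndarray:
    """Place the amide H on the external bisector of C(i-1)-N-CA."""
    u = n - c_prev
    u /= np.linalg.norm(u)
    v = n - ca
    v /= np.linalg.norm(v)
    w = u + v
    norm = np.linalg.norm(w)
    if norm < 1e-8:  # degenerate collinear case
        w = np.cross(u, np.array([1.0, 0.0, 0.0]))
        norm = np.linalg.norm(w)
    return n + length * w / norm


def hbond_satisfaction(
    structure: Structure,
    energy_cutoff: float = DEFAULT_HBOND_ENERGY_CUTOFF,
) -> HbondAssignment:
    """Backbone H-bond assignment with reconstructed amide hydrogens.

    A bond i->j is assigned when the Kabsch-Sander energy between donor
    N-H(i) and acceptor C=O(j) is below ``energy_cutoff`` (default -0.5
    kcal/mol); candidates require |i-j| >= 3, since very-short-range pairs
    sit at near-threshold energies even in an isolated extended chain and
    excluding them keeps satisfaction meaning a genuine helix/turn/sheet
    partner.  A residue is *satisfied* when its N-H or C=O
    participates in at least one assigned bond.  Proline has no amide H and
    never donates; the N-terminal residue cannot donate either.
    """
    nres = structure.n_residues
    N = {}
    CA = {}
    C = {}
    O = {}
    for i, res in enumerate(structure.residues):
        for nm, store in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            a = res.atom(nm)
            if a is not None:
                store[i] = a.coords

    H = {}
    for i in range(1, nres):
        if structure.residues[i].type == "PRO":
            continue
        if i in N and i in CA and (i - 1) in C:
            H[i] = reconstruct_amide_h(N[i], CA[i], C[i - 1])

    bonds = []
    energies = {}
    satisfied = np.zeros(nres, dtype=int)
    for i in H:  # donor
        for j in range(nres):  # acceptor
            if abs(i - j) < 3 or j not in C or j not in O:
                continue
            e = kabsch_sander_energy(None, None, N[i], H[i], C[j], O[j])
            if e < energy_cutoff:
                bonds.append((i, j))
                energies[(i, j)] = float(e)
                satisfied[i] = 1
                satisfied[j] = 1
    return HbondAssignment(bonds, energies, satisfied)


def hbond_labels(hbonds: HbondAssignment) -> LabelSet:
    return LabelSet(hbonds.satisfied, alphabet=(0, 1), kind="residue")


def secondary_structure(structure: Structure,
                        hbonds: HbondAssignment | None = None) -> LabelSet:
    """Simplified three-state secondary structure {H, E, C}.

    H: residues covered by runs of at least two consecutive i->i+4 bonds;
    E: residues in parallel/antiparallel bridge patterns of (i, j) bonds;
    C: everything else.  Helix takes precedence over strand.
    """
    if hbonds is None:
        hbonds = hbond_satisfaction(structure)
    nres = structure.n_residues
    turn4 = np.zeros(nres, dtype=bool)
    for i in range(nres - 4):
        if hbonds.has_bond(i + 4, i):
            turn4[i] = True

    helix = np.zeros(nres, dtype=bool)
    for i in range(nres - 1):
        if turn4[i] and i + 1 < nres and turn4[i + 1]:
            helix[i + 1: i + 5] = True

    strand = np.zeros(nres, dtype=bool)
    hb = hbonds.has_bond
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            para = (hb(i, j) and hb(j, i + 2)) or (hb(j, i) and hb(i + 2, j)) \
                or (hb(i - 1, j) and hb(j, i + 1)) or (hb(j - 1, i) and hb(i, j + 1))
            anti = (hb(i, j) and hb(j, i)) or (hb(i - 1, j + 1) and hb(j - 1, i + 1))
            if para or anti:
                strand[i] = True
                strand[j] = True

    labels = np.zeros(nres, dtype=int)  # 0 = C
    labels[strand] = 2
    labels[helix] = 1
    alphabet = ("C", "H", "E")
    return LabelSet(labels, alphabet=alphabet, kind="residue")


def ingest_labels(text: str, alphabet) -> LabelSet:
    """Parse an external per-residue label string (e.g. a 20-letter 3Di
    string or a predicted burial string) into a residue-kind LabelSet."""
    alphabet = tuple(alphabet)
    index = {str(a): k for k, a in enumerate(alphabet)}
    labels = np.empty(len(text), dtype=int)
    for pos, ch in enumerate(text):
        if ch not in index:
            raise ValueError(
                f"character {ch!r} at position {pos} is not in the alphabet"
            )
        labels[pos] = index[ch]
    return LabelSet(labels, alphabet=alphabet, kind="residue")
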