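"""Synthetic targets and decoys: coarse idealized backbones plus
noise-perturbed models with a controlled LDDT spread.

These generated structures stand in for experimental target/model pairs so
that every pipeline stage — SASA/burial, contacts, H-bonds, phi, LDDT,
information curves — runs self-contained.  Targets mix helix, strand and
coil segments built from ideal torsions; compactness is enforced by
rejection sampling of the coil torsions (radius-of-gyration cap plus a
C-alpha clash check) so that a burial core actually forms.  Decoys add
isotropic Gaussian coordinate noise (or rigid sub-segment rotations) of
increasing magnitude, spanning low to high LDDT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benchmark import (
    CHANNELS,
    BenchmarkSet,
    BenchmarkTarget,
    ChannelConfig,
    compute_channels,
)
from .data import STANDARD_AA
from .geometry import HELIX_PHI_PSI, STRAND_PHI_PSI, build_chain
from .sasa import reference_areas
from .similarity import lddt
from .structures import Structure

#: decoy noise magnitudes (A) chosen to spread decoy LDDT over [~0.2, 1.0]
DEFAULT_SIGMAS = (0.05, 0.1, 0.2, 0.3, 0.45, 0.65, 0.9, 1.3, 1.9, 2.8)

#: (phi, psi) centers, half-widths and weights of the coil sampling regions
_COIL_REGIONS = (
    ((-63.0, -43.0), (12.0, 12.0), 0.30),   # alpha basin
    ((-120.0, 130.0), (18.0, 18.0), 0.35),  # beta basin
    ((-75.0, 150.0), (12.0, 12.0), 0.25),   # polyproline II
    ((57.0, 45.0), (10.0, 10.0), 0.10),     # left-handed alpha
)


@dataclass
class BackboneSpec:
    """Recipe for one idealized chain."""

    segments: list[tuple[str, int]]           # (kind in {helix,strand,coil}, length)
    sidechain_mode: str = "pseudo"
    seed: int = 0
    sequence: str | None = None               # one-letter codes; random if None

    def total_length(self) -> int:
        return sum(n for _, n in self.segments)


@dataclass
class DecoySpec:
    """Recipe for a set of noise-perturbed models of one target."""

    noise_sigmas: tuple = DEFAULT_SIGMAS
    n_per_sigma: int = 4
    perturbation: str = "gaussian"            # or "segment_rotate"
    seed: int = 0


def _segment_torsions(segments, rng) -> tuple[np.ndarray, np.ndarray]:
    phi = []
    psi = []
    for kind, length in segments:
        if length < 1:
            raise ValueError("segment lengths must be >= 1")
        if kind == "helix":
            phi += [HELIX_PHI_PSI[0]] * length
            psi += [HELIX_PHI_PSI[1]] * length
        elif kind == "strand":
            phi += [STRAND_PHI_PSI[0]] * length
            psi += [STRAND_PHI_PSI[1]] * length
        elif kind == "coil":
            centers = np.array([r[0] for r in _COIL_REGIONS])
            widths = np.array([r[1] for r in _COIL_REGIONS])
            weights = np.array([r[2] for r in _COIL_REGIONS])
            pick = rng.choice(len(_COIL_REGIONS), size=length, p=weights)
            jitter = rng.uniform(-1.0, 1.0, size=(length, 2)) * widths[pick]
            tors = centers[pick] + jitter
            phi += list(tors[:, 0])
            psi += list(tors[:, 1])
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
    return np.array(phi), np.array(psi)


def _is_acceptable(structure: Structure, rg_cap: float | None) -> bool:
    ca = structure.atom_coords("CA")
    n = len(ca)
    if n > 2:
        d2 = ((ca[:, None, :] - ca[None, :, :]) ** 2).sum(-1)
        ii, jj = np.triu_indices(n, k=2)
        if np.any(d2[ii, jj] < 3.2 ** 2):  # non-bonded C-alpha clash
            return False
    if rg_cap is not None:
        rg = float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(1).mean()))
        if rg > rg_cap:
            return False
    return True


def _radius_of_gyration(structure: Structure) -> float:
    ca = structure.atom_coords("CA")
    return float(np.sqrt(((ca - ca.mean(0)) ** 2).sum(1).mean()))


def _sample_coil_torsion(rng) -> tuple[float, float]:
    weights = np.array([r[2] for r in _COIL_REGIONS])
    pick = rng.choice(len(_COIL_REGIONS), p=weights)
    (c_phi, c_psi), (w_phi, w_psi), _ = _COIL_REGIONS[pick]
    return (c_phi + rng.uniform(-1.0, 1.0) * w_phi,
            c_psi + rng.uniform(-1.0, 1.0) * w_psi)


def build_backbone(
    spec: BackboneSpec,
    max_attempts: int = 200,
    rg_cap: float | None = None,
    compact: bool = False,
    compaction_iters: int = 400,
    name: str = "target",
) -> Structure:
    """Build an idealized N/CA/C/O(+pseudo-CB) chain from a segment spec.

    Coil torsions are sampled from allowed Ramachandran basins and the
    whole chain is resampled on C-alpha self-clashes.  With ``compact``,
    an additional greedy collapse refines the coil torsions one at a time,
    accepting proposals that shrink the C-alpha radius of gyration without
    introducing clashes — so generated targets fold back on themselves
    enough to develop a buried core.  A hard ``rg_cap`` raises when no
    clash-free sample satisfies it.  Deterministic for a fixed seed.
    """
    total = spec.total_length()
    if total < 3:
        raise ValueError("total chain length must be >= 3")
    rng = np.random.default_rng(spec.seed)
    if spec.sequence is not None:
        from .data import ONE_TO_THREE
        if len(spec.sequence) != total:
            raise ValueError("sequence length must match segment total")
        sequence = [ONE_TO_THREE[ch] for ch in spec.sequence]
    else:
        sequence = [STANDARD_AA[i] for i in rng.integers(0, 20, size=total)]

    has_coil = any(kind == "coil" for kind, _ in spec.segments)
    best: Structure | None = None
    best_tors: tuple[np.ndarray, np.ndarray] | None = None
    best_rg = np.inf
    n_initial = min(max_attempts, 30) if compact else max_attempts
    for _ in range(n_initial):
        phi, psi = _segment_torsions(spec.segments, rng)
        structure = build_chain(sequence, phi, psi,
                                sidechain_mode=spec.sidechain_mode, name=name)
        if _is_acceptable(structure, rg_cap):
            if not compact:
                return structure
            rg = _radius_of_gyration(structure)
            if rg < best_rg:
                best, best_tors, best_rg = structure, (phi, psi), rg
        if not has_coil:  # deterministic torsions cannot be resampled
            break
    if best is None:
        raise RuntimeError(
            "could not build a clash-free (and sufficiently compact) chain for "
            f"spec {spec.segments}; relax rg_cap or change the seed"
        )
    if not compact:
        return best

    kinds = [kind for kind, n in spec.segments for _ in range(n)]
    coil_pos = [i for i, k in enumerate(kinds) if k == "coil"]
    if coil_pos:
        phi, psi = best_tors
        for _ in range(compaction_iters):
            i = coil_pos[rng.integers(len(coil_pos))]
            new_phi, new_psi = phi.copy(), psi.copy()
            new_phi[i], new_psi[i] = _sample_coil_torsion(rng)
            cand = build_chain(sequence, new_phi, new_psi,
                               sidechain_mode=spec.sidechain_mode, name=name)
            if _is_acceptable(cand, rg_cap):
                rg = _radius_of_gyration(cand)
                if rg < best_rg:
                    best, best_rg, phi, psi = cand, rg, new_phi, new_psi
    return best


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def make_decoys(native: Structure, spec: DecoySpec) -> list[tuple[Structure, float]]:
    """Generate noise-perturbed decoys with their LDDT against the native.

    ``gaussian`` adds iid 3-D noise of the given sigma to every atom;
    ``segment_rotate`` rotates a random contiguous residue segment about a
    random axis by an angle proportional to sigma (geometry-preserving
    within the moved and fixed parts).
    """
    rng = np.random.default_rng(spec.seed)
    coords = native.coords()
    res_idx = native.atom_residue_index()
    out = []
    for sigma in spec.noise_sigmas:
        for k in range(spec.n_per_sigma):
            if spec.perturbation == "gaussian":
                new = coords + rng.normal(0.0, sigma, size=coords.shape) if sigma > 0 \
                    else coords.copy()
            elif spec.perturbation == "segment_rotate":
                new = coords.copy()
                if sigma > 0:
                    n = native.n_residues
                    start = int(rng.integers(0, n - 2))
                    stop = int(rng.integers(start + 2, n + 1))
                    mask = (res_idx >= start) & (res_idx < stop)
                    pivot = new[mask][0]
                    rot = _rotation_matrix(rng.normal(size=3),
                                           rng.normal(0.0, 0.15 * sigma))
                    new[mask] = (new[mask] - pivot) @ rot.T + pivot
            else:
                raise ValueError(f"unknown perturbation {spec.perturbation!r}")
            decoy = native.with_coords(new, name=f"{native.name}_s{sigma}_{k}")
            score = lddt(native, decoy).global_score
            out.append((decoy, score))
    return out


def _random_topology(length: int, rng) -> list[tuple[str, int]]:
    """Alternating secondary-structure segments joined by short coils."""
    segments: list[tuple[str, int]] = []
    remaining = length
    want_ss = True
    while remaining > 0:
        if want_ss:
            kind = "helix" if rng.random() < 0.5 else "strand"
            n = int(rng.integers(8, 14)) if kind == "helix" else int(rng.integers(5, 9))
        else:
            kind = "coil"
            n = int(rng.integers(2, 5))
        n = min(n, remaining)
        segments.append((kind, n))
        remaining -= n
        want_ss = not want_ss
    return segments


def make_benchmark(
    n_targets: int = 3,
    decoy_spec: DecoySpec | None = None,
    target_length_range: tuple[int, int] = (40, 60),
    seed: int = 0,
    config: ChannelConfig | None = None,
    channels=CHANNELS,
) -> BenchmarkSet:
    """Full synthetic benchmark: targets, scored decoys and all channels.

    All randomness flows from the master seed through named substreams
    (target topology/sequence, coil sampling, decoy noise).
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    config = config or ChannelConfig()
    master = np.random.SeedSequence(seed)
    target_stream, decoy_stream = master.spawn(2)
    t_seeds = target_stream.generate_state(n_targets)
    d_seeds = decoy_stream.generate_state(n_targets)

    refs = reference_areas(probe=config.probe, n_points=config.n_points,
                           sidechain_mode=config.sidechain_mode)
    targets = []
    for t in range(n_targets):
        rng = np.random.default_rng(int(t_seeds[t] % (2 ** 31)))
        length = int(rng.integers(target_length_range[0], target_length_range[1] + 1))
        spec = BackboneSpec(
            segments=_random_topology(length, rng),
            sidechain_mode=config.sidechain_mode,
            seed=int(rng.integers(2 ** 31)),
        )
        native = build_backbone(spec, max_attempts=80, compact=True,
                                name=f"target_{t:02d}")

        dspec = decoy_spec or DecoySpec()
        dspec = DecoySpec(dspec.noise_sigmas, dspec.n_per_sigma,
                          dspec.perturbation, seed=int(d_seeds[t] % (2 ** 31)))
        scored = make_decoys(native, dspec)
        decoys = [s for s, _ in scored]
        lddt_values = np.array([v for _, v in scored])

        native_channels, native_rsasa = compute_channels(native, config, refs, channels)
        decoy_channels: dict[str, list] = {ch: [] for ch in native_channels}
        decoy_rsasa = []
        for dec in decoys:
            ch_map, rv = compute_channels(dec, config, refs, channels)
            for ch in decoy_channels:
                decoy_channels[ch].append(ch_map[ch])
            decoy_rsasa.append(rv)
        targets.append(BenchmarkTarget(
            name=f"target_{t:02d}", native=native, decoys=decoys,
            lddt=lddt_values, native_channels=native_channels,
            decoy_channels=decoy_channels, native_rsasa=native_rsasa,
            decoy_rsasa=decoy_rsasa,
        ))
    return BenchmarkSet(targets, config)
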