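"""Information accounting for structural label channels.

Each label outcome x carries iota(x) = -log2 p(x) bits, with p(x) estimated
by pooled frequency over a reference corpus of native label sets.  Passing a
random fraction of native labels per target as restraints yields I, the
bits of information used per residue; correlating the resulting restricted
phi scores against decoy LDDT (with the flattened bootstrap Spearman)
traces rho-vs-I curves, and I* is the interpolated information at which rho
first reaches a quality threshold (0.9 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .benchmark import BenchmarkSet
from .encodings import LabelSet
from .similarity import phi_from_labels

PSEUDO_COUNT = 0.5
RHO_FOLD_THRESHOLD = 0.9


class DegenerateCorrelationWarning(UserWarning):
    pass


@dataclass
class InformationModel:
    """Empirical outcome probabilities and per-label information (bits)."""

    probabilities: np.ndarray
    alphabet: tuple
    source: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("probabilities must sum to 1")
        if np.any(self.probabilities <= 0):
            raise ValueError("every carried outcome needs p > 0")

    @property
    def information(self) -> np.ndarray:
        """iota(x) = -log2 p(x) per alphabet outcome, bits."""
        return -np.log2(self.probabilities)

    def iota(self, labels: np.ndarray) -> np.ndarray:
        return self.information[np.asarray(labels, dtype=int)]


def fit_information(corpus: list[LabelSet], source: str = "corpus") -> InformationModel:
    """Pooled outcome frequencies over a corpus of native label sets.

    Outcomes of the alphabet never observed in the corpus receive a
    pseudo-count of 0.5 (Jeffreys) so their information stays finite.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    alphabet = corpus[0].alphabet
    k = len(alphabet)
    counts = np.zeros(k, dtype=float)
    for ls in corpus:
        if ls.alphabet != alphabet:
            raise ValueError("corpus label sets must share one alphabet")
        counts += np.bincount(ls.labels, minlength=k)
    if counts.sum() == 0:
        raise ValueError("corpus carries no labels")
    counts[counts == 0] = PSEUDO_COUNT
    return InformationModel(counts / counts.sum(), alphabet, source)


def flattened_spearman(
    phi_values,
    lddt_values,
    n_bins: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Bootstrap Spearman correlation over a flattened LDDT distribution.

    LDDT is divided into ``n_bins`` equal-width bins on [0, 1]; each
    replicate draws an equal number of samples with replacement from every
    non-empty bin (the smallest non-empty bin count), and the median
    Spearman over ``n_boot`` replicates is returned.  Ties get average
    ranks; a replicate with zero rank variance contributes 0.
    """
    phi_values = np.asarray(phi_values, dtype=float)
    lddt_values = np.asarray(lddt_values, dtype=float)
    if len(phi_values) != len(lddt_values):
        raise ValueError("phi and LDDT lists must have equal length")
    if len(phi_values) < 3:
        raise ValueError("need at least 3 observations")

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(lddt_values, edges) - 1, 0, n_bins - 1)
    groups = [np.flatnonzero(which == b) for b in range(n_bins)]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty LDDT bins")
    if np.ptp(phi_values) == 0:
        warnings.warn("all phi values tied; flattened Spearman is degenerate",
                      DegenerateCorrelationWarning)
        return 0.0

    m = min(len(g) for g in groups)
    rng = np.random.default_rng(seed)
    sel = np.concatenate(
        [g[rng.integers(0, len(g), size=(n_boot, m))] for g in groups], axis=1
    )
    rp = rankdata(phi_values[sel], axis=1)
    rl = rankdata(lddt_values[sel], axis=1)
    rp = rp - rp.mean(axis=1, keepdims=True)
    rl = rl - rl.mean(axis=1, keepdims=True)
    denom = np.sqrt((rp * rp).sum(axis=1) * (rl * rl).sum(axis=1))
    rho = np.zeros(n_boot)
    ok = denom > 0
    rho[ok] = (rp * rl).sum(axis=1)[ok] / denom[ok]
    return float(np.median(rho))


@dataclass
class RestraintDraw:
    """One random restraint selection across the benchmark."""

    selections: list[np.ndarray]       # selected position indices per target
    n_restraints: int                  # total positions selected
    bits_per_residue: float            # I, averaged over targets
    phi_values: np.ndarray             # one phi per decoy (all targets pooled)
    lddt_values: np.ndarray


def subsample_restraints(
    benchmark: BenchmarkSet,
    channel: str,
    fraction: float,
    info: InformationModel,
    seed: int = 0,
    pooled_normalization: bool = False,
) -> RestraintDraw:
    """Pass a random fraction of native labels per target as restraints.

    Per target, a uniform random subset of positions (fraction rounded
    half-up, at least 1) is selected; phi for every decoy is computed over
    the selected positions only, and I sums iota of the selected *native*
    labels divided by the residue count N.  By default I is normalized per
    target and then averaged; ``pooled_normalization`` divides pooled bits
    by pooled N instead.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)

    selections = []
    phis = []
    lddts = []
    n_restraints = 0
    per_target_I = []
    pooled_bits = 0.0
    pooled_n = 0
    for t in benchmark.targets:
        native = t.native_channels[channel]
        n_pos = len(native)
        n_sel = max(1, int(np.floor(fraction * n_pos + 0.5)))
        sel = np.sort(rng.choice(n_pos, size=n_sel, replace=False))
        selections.append(sel)
        n_restraints += n_sel
        bits = float(info.iota(native.labels[sel]).sum())
        per_target_I.append(bits / t.n_residues)
        pooled_bits += bits
        pooled_n += t.n_residues
        nat_sel = native.labels[sel]
        k = native.n_classes
        for d, ls in enumerate(t.decoy_channels[channel]):
            phis.append(phi_from_labels(nat_sel, ls.labels[sel], n_classes=k))
            lddts.append(t.lddt[d])

    bits_per_residue = (pooled_bits / pooled_n if pooled_normalization
                        else float(np.mean(per_target_I)))
    return RestraintDraw(selections, n_restraints, bits_per_residue,
                         np.asarray(phis), np.asarray(lddts))


@dataclass
class CurvePoint:
    fraction: float
    bits_per_residue: float   # mean I over draws
    rho: float                # mean flattened Spearman over draws
    n_draws: int


def rho_vs_I_curve(
    benchmark: BenchmarkSet,
    channel: str,
    fractions,
    n_repeats: int = 25,
    seed: int = 0,
    info: InformationModel | None = None,
    n_bins: int = 20,
    n_boot: int = 1000,
    rel_tol: float = 0.01,
    pooled_normalization: bool = False,
) -> list[CurvePoint]:
    """rho versus bits-per-residue for one channel over a fraction grid.

    Each fraction is repeated up to ``n_repeats`` times; beyond 25 repeats
    the loop may stop early once the running mean of I moves by less than
    ``rel_tol`` between repeats.  Every fraction gets an independent seed
    stream derived from the master seed, so fractions can be computed in
    any order (or alone) with identical results.
    """
    fractions = list(fractions)
    if len(fractions) < 1:
        raise ValueError("need at least one fraction")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if info is None:
        info = fit_information(benchmark.native_label_sets(channel), source=channel)

    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(fractions))
    points = []
    for f_idx, fraction in enumerate(fractions):
        child_seeds = streams[f_idx].generate_state(2 * n_repeats)
        i_values = []
        rho_values = []
        for r in range(n_repeats):
            draw = subsample_restraints(
                benchmark, channel, fraction, info,
                seed=int(child_seeds[2 * r] % (2 ** 31)),
                pooled_normalization=pooled_normalization,
            )
            rho = flattened_spearman(
                draw.phi_values, draw.lddt_values, n_bins=n_bins,
                n_boot=n_boot, seed=int(child_seeds[2 * r + 1] % (2 ** 31)),
            )
            i_values.append(draw.bits_per_residue)
            rho_values.append(rho)
            if r + 1 >= 25:
                prev = np.mean(i_values[:-1])
                cur = np.mean(i_values)
                if prev > 0 and abs(cur - prev) / prev < rel_tol:
                    break
        points.append(CurvePoint(float(fraction), float(np.mean(i_values)),
                                 float(np.mean(rho_values)), len(i_values)))
    return points


def i_star(curve: list[CurvePoint], rho_threshold: float = RHO_FOLD_THRESHOLD) -> float | None:
    """Smallest I at which rho crosses the threshold, linearly interpolated
    between the bracketing curve points; ``None`` when never reached."""
    if not curve:
        raise ValueError("empty curve")
    pts = sorted(curve, key=lambda p: p.bits_per_residue)
    if pts[0].rho >= rho_threshold:
        return pts[0].bits_per_residue
    for lo, hi in zip(pts, pts[1:]):
        if lo.rho < rho_threshold <= hi.rho:
            span = hi.rho - lo.rho
            if span <= 0:
                return hi.bits_per_residue
            w = (rho_threshold - lo.rho) / span
            return lo.bits_per_residue + w * (hi.bits_per_residue - lo.bits_per_residue)
    return None
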