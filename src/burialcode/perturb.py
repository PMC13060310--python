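"""Label-noise robustness and core-hydrophobicity analyses.

Random flips of the native core-identity labels probe how fast the
phi-LDDT correlation degrades with labeling errors; external predictors
slot in as single (f_flip, rho) points.  Core hydrophobicity
H = (1/N) sum_i h_i b_i and its native-minus-model difference Delta-H test
whether hydrophobicity maximization identifies the native core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .benchmark import BenchmarkSet
from .data import HYDROPHOBICITY_SCALES, STANDARD_AA
from .encodings import LabelSet
from .info import flattened_spearman
from .sasa import BurialVector
from .similarity import phi_from_labels


@dataclass
class HydroScale:
    """Per-residue-type hydrophobicity values (dimensionless)."""

    values: dict[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = [t for t in STANDARD_AA if t not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r} missing residue types {missing}")

    @classmethod
    def named(cls, name: str) -> "HydroScale":
        try:
            return cls(dict(HYDROPHOBICITY_SCALES[name]), name)
        except KeyError:
            raise KeyError(
                f"unknown scale {name!r}; available: {sorted(HYDROPHOBICITY_SCALES)}"
            )

    def __getitem__(self, res_type: str) -> float:
        return self.values[res_type]


@dataclass
class FlipResult:
    perturbed: BurialVector
    f_flip: float            # realized fraction of flipped positions
    p: float                 # per-position flip probability


def flip_labels(native: BurialVector, p: float, seed: int = 0) -> FlipResult:
    """Independently flip each core-identity label with probability p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    flips = rng.random(len(native)) < p
    labels = np.where(flips, 1 - native.labels, native.labels)
    return FlipResult(BurialVector(labels, native.cutoff),
                      float(flips.mean()), float(p))


def robustness_curve(
    benchmark: BenchmarkSet,
    p_values,
    n_repeats: int = 20,
    seed: int = 0,
    channel: str = "burial",
    n_bins: int = 20,
    n_boot: int = 1000,
) -> list[dict]:
    """rho versus label-flip probability for the burial channel.

    For each flip probability p and repeat, every target's *native* labels
    are perturbed (decoy labels untouched), phi is recomputed for all
    decoys, and the flattened Spearman against LDDT is taken; the mean and
    standard deviation over repeats are reported together with the mean
    realized flip fraction.
    """
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(list(p_values)))
    lddt_all = benchmark.all_lddt()
    rows = []
    for p_idx, p in enumerate(p_values):
        child = streams[p_idx].generate_state(2 * n_repeats)
        rhos = []
        fflips = []
        for r in range(n_repeats):
            rng = np.random.default_rng(int(child[2 * r] % (2 ** 31)))
            phis = []
            n_flipped = 0
            n_total = 0
            for t in benchmark.targets:
                native = t.native_channels[channel]
                flips = rng.random(len(native)) < p
                perturbed = np.where(flips, 1 - native.labels, native.labels)
                n_flipped += int(flips.sum())
                n_total += len(native)
                for ls in t.decoy_channels[channel]:
                    phis.append(phi_from_labels(perturbed, ls.labels, n_classes=2))
            rhos.append(flattened_spearman(
                np.asarray(phis), lddt_all, n_bins=n_bins, n_boot=n_boot,
                seed=int(child[2 * r + 1] % (2 ** 31))))
            fflips.append(n_flipped / n_total)
        rows.append({
            "p": float(p),
            "f_flip": float(np.mean(fflips)),
            "rho": float(np.mean(rhos)),
            "rho_std": float(np.std(rhos, ddof=1)) if n_repeats > 1 else 0.0,
        })
    return rows


def external_predictor_point(
    benchmark: BenchmarkSet,
    predicted_native: list[LabelSet],
    channel: str = "burial",
    n_bins: int = 20,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """(f_flip, rho) for externally predicted native labels.

    ``predicted_native`` supplies one label set per target, aligned to the
    trimmed targets; f_flip is the pooled mismatch fraction against the
    true native labels and rho the flattened Spearman of phi(predicted
    native, decoy) versus LDDT over all decoys.
    """
    if len(predicted_native) != len(benchmark.targets):
        raise ValueError("need one predicted label set per target")
    phis = []
    n_mismatch = 0
    n_total = 0
    for t, pred in zip(benchmark.targets, predicted_native):
        native = t.native_channels[channel]
        if len(pred) != len(native):
            raise ValueError(
                f"target {t.name}: predicted length {len(pred)} != {len(native)}"
            )
        n_mismatch += int((pred.labels != native.labels).sum())
        n_total += len(native)
        k = native.n_classes
        for ls in t.decoy_channels[channel]:
            phis.append(phi_from_labels(pred.labels, ls.labels, n_classes=k))
    rho = flattened_spearman(np.asarray(phis), benchmark.all_lddt(),
                             n_bins=n_bins, n_boot=n_boot, seed=seed)
    return n_mismatch / n_total, float(rho)


def core_hydrophobicity(burial: BurialVector, types, scale: HydroScale) -> float:
    """H = (1/N) sum_i h_i b_i — mean hydrophobicity of core residues,
    normalized by the full chain length."""
    types = list(types)
    if len(types) != len(burial):
        raise ValueError("types must match the burial vector length")
    h = np.array([scale[t] for t in types])
    return float((h * burial.labels).sum() / len(burial))


def delta_hydrophobicity(h_native: float, h_model: float) -> float:
    """Delta-H = H_native - H_model; negative means the model core is more
    hydrophobic than the native core."""
    return h_native - h_model


def delta_core_hydrophobicity(
    native: BurialVector,
    model: BurialVector,
    types,
    scale: HydroScale,
) -> float:
    """Delta-H computed from two burial vectors over the same chain."""
    if len(native) != len(model):
        raise ValueError("native and model burial vectors must have equal length")
    return delta_hydrophobicity(
        core_hydrophobicity(native, types, scale),
        core_hydrophobicity(model, types, scale),
    )


@dataclass
class TypeRates:
    """Base rates and prediction accuracy for one residue type."""

    res_type: str
    p_core: float
    p_surface: float
    entropy: float       # bits, H = -p_c log2 p_c - p_s log2 p_s
    accuracy: float      # R, fraction of positions with matching labels
    hydrophobicity: float
    n: int


def _entropy_bits(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    q = 1.0 - p
    return float(-p * np.log2(p) - q * np.log2(q))


def type_rates(
    native_labels: np.ndarray,
    predicted_labels: np.ndarray,
    types,
    scale: HydroScale,
) -> list[TypeRates]:
    """Per-residue-type core base rate p_c, label entropy H and accuracy R.

    Inputs are pooled over the corpus: aligned native and predicted binary
    labels plus the residue type of every position.  Types never observed
    are omitted.
    """
    native_labels = np.asarray(native_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    types = np.asarray(list(types))
    if not (len(native_labels) == len(predicted_labels) == len(types)):
        raise ValueError("labels and types must be aligned")
    out = []
    for res_type in STANDARD_AA:
        mask = types == res_type
        n = int(mask.sum())
        if n == 0:
            continue
        p_c = float(native_labels[mask].mean())
        r = float((native_labels[mask] == predicted_labels[mask]).mean())
        out.append(TypeRates(res_type, p_c, 1.0 - p_c, _entropy_bits(p_c),
                             r, scale[res_type], n))
    return out
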