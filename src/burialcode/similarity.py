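"""Agreement scores between native and model encodings.

Two families: the Matthews correlation coefficient phi between categorical
label sets (binary determinant form and its k-class generalization, the
R_K statistic), and the superposition-free C-alpha LDDT model-quality score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .encodings import LabelSet
from .structures import Structure

LDDT_INCLUSION_RADIUS = 15.0
LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)


@dataclass
class ConfusionMatrix:
    """k x k count matrix; rows index the native label, columns the
    predicted label."""

    counts: np.ndarray
    alphabet: tuple

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.alphabet)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for the alphabet")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.alphabet)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))


@dataclass
class PhiScore:
    value: float
    degenerate: bool = False

    def __float__(self) -> float:
        return self.value


def build_confusion(native: LabelSet, predicted: LabelSet) -> ConfusionMatrix:
    """Count co-occurrences of native and predicted labels per position."""
    if native.kind != predicted.kind:
        raise ValueError("label sets must have the same kind")
    if native.alphabet != predicted.alphabet:
        raise ValueError("label sets must share the alphabet")
    if len(native) != len(predicted):
        raise ValueError(
            f"label length mismatch: {len(native)} vs {len(predicted)}"
        )
    k = native.n_classes
    counts = np.bincount(
        native.labels * k + predicted.labels, minlength=k * k
    ).reshape(k, k)
    return ConfusionMatrix(counts, native.alphabet)


def phi_binary(m: ConfusionMatrix) -> PhiScore:
    """Binary Matthews phi: det(M) / sqrt(prod of row and column sums).

    Any zero margin makes the score undefined; following the
    "no correlation" semantics it is reported as 0 with ``degenerate`` set.
    """
    if m.k != 2:
        raise ValueError("phi_binary requires a 2x2 matrix; use phi_multiclass")
    r = m.row_sums.astype(float)
    c = m.col_sums.astype(float)
    denom2 = r.prod() * c.prod()
    if denom2 <= 0:
        return PhiScore(0.0, degenerate=True)
    det = float(m.counts[0, 0]) * m.counts[1, 1] - float(m.counts[0, 1]) * m.counts[1, 0]
    return PhiScore(det / np.sqrt(denom2))


def phi_multiclass(m: ConfusionMatrix) -> PhiScore:
    """k-class Matthews phi (Gorodkin's R_K):
    (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2)),
    with s the total count, c the trace, p_k/t_k the column/row sums.
    """
    if m.k < 2:
        raise ValueError("phi_multiclass requires k >= 2")
    s = float(m.total)
    c = float(m.trace)
    p = m.col_sums.astype(float)
    t = m.row_sums.astype(float)
    cov = c * s - (p * t).sum()
    denom2 = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom2 <= 0:
        return PhiScore(0.0, degenerate=True)
    return PhiScore(cov / np.sqrt(denom2))


def phi(native: LabelSet, predicted: LabelSet) -> PhiScore:
    """phi between two label sets (binary form when the alphabet has 2
    letters, multiclass otherwise)."""
    m = build_confusion(native, predicted)
    return phi_binary(m) if m.k == 2 else phi_multiclass(m)


def phi_from_labels(native: np.ndarray, predicted: np.ndarray,
                    n_classes: int) -> float:
    """Fast phi on raw integer label arrays (used in inner loops)."""
    counts = np.bincount(
        np.asarray(native) * n_classes + np.asarray(predicted),
        minlength=n_classes * n_classes,
    ).reshape(n_classes, n_classes)
    s = float(counts.sum())
    c = float(np.trace(counts))
    p = counts.sum(axis=0).astype(float)
    t = counts.sum(axis=1).astype(float)
    denom2 = (s * s - (p * p).sum()) * (s * s - (t * t).sum())
    if denom2 <= 0:
        return 0.0
    return float((c * s - (p * t).sum()) / np.sqrt(denom2))


@dataclass
class LddtScore:
    global_score: float
    per_residue: np.ndarray
    inclusion_radius: float
    thresholds: tuple


def lddt(
    target: Structure,
    model: Structure,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    thresholds=LDDT_THRESHOLDS,
    min_separation: int = 1,
) -> LddtScore:
    """C-alpha local distance difference test.

    The reference pair set is every C-alpha pair of the *target* with
    |i-j| >= ``min_separation`` and target distance strictly below the
    inclusion radius (default 15 A).  A pair is preserved under threshold t
    when |d_target - d_model| < t; each residue's score is the fraction of
    its reference pairs preserved, averaged over the thresholds
    {0.5, 1, 2, 4} A, and the global score is the mean over residues that
    have at least one reference pair.  The score is not symmetric in its
    arguments: the target defines the reference pairs.
    """
    if target.n_residues != model.n_residues:
        raise ValueError("target and model must be aligned to equal length")
    ct = target.atom_coords("CA")
    cm = model.atom_coords("CA")
    n = len(ct)
    dt = squareform(pdist(ct))
    dm = squareform(pdist(cm))

    ii, jj = np.triu_indices(n, k=max(1, min_separation))
    ref = dt[ii, jj] < inclusion_radius
    ii, jj = ii[ref], jj[ref]
    if len(ii) == 0:
        raise ValueError("no reference pairs under the inclusion radius")

    diff = np.abs(dt[ii, jj] - dm[ii, jj])
    frac = np.mean([(diff < t) for t in thresholds], axis=0)  # per pair

    num = np.zeros(n)
    cnt = np.zeros(n)
    np.add.at(num, ii, frac)
    np.add.at(num, jj, frac)
    np.add.at(cnt, ii, 1)
    np.add.at(cnt, jj, 1)
    has = cnt > 0
    per_residue = np.zeros(n)
    per_residue[has] = num[has] / cnt[has]
    return LddtScore(float(per_residue[has].mean()), per_residue,
                     inclusion_radius, tuple(thresholds))
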