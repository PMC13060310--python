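"""Summary tables: per-channel rho/I/I* summaries and Delta-H by LDDT bin."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .info import CurvePoint, RHO_FOLD_THRESHOLD, i_star


@dataclass
class ChannelSummary:
    channel: str
    rho_full: float                 # rho at full information
    bits_full: float                # I using every label
    i_star: float | None            # bits/residue to reach the threshold
    n_labels: int                   # labels used at full information

    def __post_init__(self) -> None:
        if self.i_star is not None and self.i_star > self.bits_full + 1e-9:
            raise ValueError("I* cannot exceed the full-information I")


def summarize_channels(
    curves: dict[str, list[CurvePoint]],
    threshold: float = RHO_FOLD_THRESHOLD,
    n_labels: dict[str, int] | None = None,
) -> list[ChannelSummary]:
    """One row per channel, sorted by I* ascending with never-crossing
    channels (I* absent) last."""
    if not curves:
        raise ValueError("need at least one channel curve")
    rows = []
    for channel, curve in curves.items():
        pts = sorted(curve, key=lambda p: p.bits_per_residue)
        full = pts[-1]
        rows.append(ChannelSummary(
            channel=channel,
            rho_full=full.rho,
            bits_full=full.bits_per_residue,
            i_star=i_star(curve, threshold),
            n_labels=(n_labels or {}).get(channel, 0),
        ))
    rows.sort(key=lambda r: (r.i_star is None, r.i_star if r.i_star is not None else 0.0))
    return rows


@dataclass
class BinnedDeltaH:
    bin_edges: np.ndarray
    samples: list[np.ndarray]            # Delta-H samples per LDDT bin
    fraction_negative: np.ndarray        # per-bin fraction with Delta-H < 0
    pooled_fraction_low_lddt: float      # fraction Delta-H < 0 among LDDT < 0.8


def binned_delta_h(deltas, bin_edges) -> BinnedDeltaH:
    """Bucket (Delta-H, LDDT) pairs by LDDT and report the per-bin fraction
    with a more-hydrophobic-than-native model core (Delta-H < 0)."""
    deltas = list(deltas)
    if not deltas:
        raise ValueError("empty input")
    edges = np.asarray(bin_edges, dtype=float)
    if edges[0] > 0.0 or edges[-1] < 1.0:
        raise ValueError("bin edges must cover [0, 1]")
    dh = np.array([d for d, _ in deltas])
    ld = np.array([l for _, l in deltas])
    which = np.clip(np.digitize(ld, edges) - 1, 0, len(edges) - 2)
    samples = [dh[which == b] for b in range(len(edges) - 1)]
    frac = np.array([float((s < 0).mean()) if len(s) else 0.0 for s in samples])
    low = ld < 0.8
    pooled = float((dh[low] < 0).mean()) if low.any() else 0.0
    return BinnedDeltaH(edges, samples, frac, pooled)


def write_summary_tsv(rows: list[ChannelSummary], path: str | Path,
                      config: dict | None = None) -> None:
    """TSV table plus a JSON sidecar carrying config/seeds for provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel\trho_full\tI_full_bits\tI_star_bits\tn_labels\n")
        for r in rows:
            istar = f"{r.i_star:.4f}" if r.i_star is not None else "absent"
            fh.write(f"{r.channel}\t{r.rho_full:.4f}\t{r.bits_full:.4f}\t"
                     f"{istar}\t{r.n_labels}\n")
    if config is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(config, fh, indent=1, sort_keys=True)


def write_curve_tsv(points: list[CurvePoint], path: str | Path,
                    config: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("fraction\tI_bits_per_residue\trho\tn_draws\n")
        for p in points:
            fh.write(f"{p.fraction:.6g}\t{p.bits_per_residue:.6f}\t"
                     f"{p.rho:.6f}\t{p.n_draws}\n")
    if config is not None:
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(config, fh, indent=1, sort_keys=True)


def read_curve_tsv(path: str | Path) -> list[CurvePoint]:
    points = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f, i, r, n = line.split()
            points.append(CurvePoint(float(f), float(i), float(r), int(n)))
    return points
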