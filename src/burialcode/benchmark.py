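"""Benchmark containers: native targets plus LDDT-scored decoys with
precomputed label channels, and their on-disk manifest form."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .encodings import (
    LabelSet,
    contact_map,
    flatten_pairs,
    hbond_labels,
    hbond_satisfaction,
    secondary_structure,
)
from .sasa import core_labels, reference_areas, rsasa, shrake_rupley
from .structures import Structure

#: the label channels precomputed for every structure in a benchmark
CHANNELS = ("burial", "contacts", "ss", "hbond")

_CHANNEL_ALPHABET = {
    "burial": (0, 1),
    "contacts": (0, 1),
    "ss": ("C", "H", "E"),
    "hbond": (0, 1),
}
_CHANNEL_KIND = {
    "burial": "residue",
    "contacts": "pair",
    "ss": "residue",
    "hbond": "residue",
}


@dataclass
class ChannelConfig:
    """Shared settings for channel computation across a benchmark."""

    burial_cutoff: float = 0.1
    probe: float = 1.4
    n_points: int = 960
    contact_cutoff: float = 8.0
    contact_atom_mode: str = "CA"
    contact_min_separation: int = 0
    sidechain_mode: str = "pseudo"

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelConfig":
        return cls(**d)


def compute_channels(
    structure: Structure,
    config: ChannelConfig,
    refs=None,
    channels=CHANNELS,
) -> tuple[dict[str, LabelSet], np.ndarray]:
    """All requested label channels plus the rSASA vector for one structure."""
    if refs is None:
        refs = reference_areas(probe=config.probe, n_points=config.n_points,
                               sidechain_mode=config.sidechain_mode)
    out: dict[str, LabelSet] = {}
    sr = shrake_rupley(structure, probe=config.probe, n_points=config.n_points)
    rv = rsasa(structure, sr, refs)
    if "burial" in channels:
        bv = core_labels(rv, config.burial_cutoff)
        out["burial"] = LabelSet(bv.labels, alphabet=(0, 1), kind="residue")
    if "contacts" in channels:
        cmap = contact_map(structure, config.contact_cutoff,
                           config.contact_atom_mode, config.contact_min_separation)
        out["contacts"] = flatten_pairs(cmap)
    if "ss" in channels or "hbond" in channels:
        hb = hbond_satisfaction(structure)
        if "hbond" in channels:
            out["hbond"] = hbond_labels(hb)
        if "ss" in channels:
            out["ss"] = secondary_structure(structure, hb)
    return out, rv.values


@dataclass
class BenchmarkTarget:
    name: str
    native: Structure
    decoys: list[Structure]
    lddt: np.ndarray
    native_channels: dict[str, LabelSet]
    decoy_channels: dict[str, list[LabelSet]]
    native_rsasa: np.ndarray
    decoy_rsasa: list[np.ndarray]

    @property
    def n_residues(self) -> int:
        return self.native.n_residues


@dataclass
class BenchmarkSet:
    """A set of targets, each with LDDT-scored decoys and cached channels."""

    targets: list[BenchmarkTarget]
    config: ChannelConfig = field(default_factory=ChannelConfig)

    @property
    def n_decoys(self) -> int:
        return sum(len(t.decoys) for t in self.targets)

    def all_lddt(self) -> np.ndarray:
        return np.concatenate([t.lddt for t in self.targets])

    def native_label_sets(self, channel: str) -> list[LabelSet]:
        return [t.native_channels[channel] for t in self.targets]

    # ---- manifest serialization -------------------------------------------

    def to_dir(self, path: str | Path) -> Path:
        """Write PDB files, channel/rSASA caches (TSV) and bench.json."""
        from .io import write_structure

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {"config": self.config.to_dict(), "targets": []}
        for t in self.targets:
            tdir = path / t.name
            tdir.mkdir(exist_ok=True)
            write_structure(t.native, tdir / "native.pdb")
            entry = {
                "name": t.name,
                "native": str(Path(t.name) / "native.pdb"),
                "decoys": [],
                "lddt": [float(x) for x in t.lddt],
                "labels": str(Path(t.name) / "labels.tsv"),
                "rsasa": str(Path(t.name) / "rsasa.tsv"),
            }
            rows = []
            for ch, ls in t.native_channels.items():
                rows.append(("native", ch, _labels_to_str(ls)))
            for k, dec in enumerate(t.decoys):
                dname = f"decoy_{k:04d}.pdb"
                write_structure(dec, tdir / dname)
                entry["decoys"].append(str(Path(t.name) / dname))
                for ch in t.decoy_channels:
                    rows.append((f"decoy_{k:04d}", ch,
                                 _labels_to_str(t.decoy_channels[ch][k])))
            with open(tdir / "labels.tsv", "w") as fh:
                fh.write("structure\tchannel\tlabels\n")
                for r in rows:
                    fh.write("\t".join(r) + "\n")
            with open(tdir / "rsasa.tsv", "w") as fh:
                fh.write("structure\trsasa\n")
                fh.write("native\t" + ",".join(f"{x:.4f}" for x in t.native_rsasa) + "\n")
                for k, rv in enumerate(t.decoy_rsasa):
                    fh.write(f"decoy_{k:04d}\t" + ",".join(f"{x:.4f}" for x in rv) + "\n")
            manifest["targets"].append(entry)
        with open(path / "bench.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        return path / "bench.json"

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "BenchmarkSet":
        from .io import read_structure

        manifest_path = Path(manifest_path)
        root = manifest_path.parent
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        config = ChannelConfig.from_dict(manifest["config"])
        targets = []
        for entry in manifest["targets"]:
            native = read_structure(root / entry["native"])
            decoys = [read_structure(root / p) for p in entry["decoys"]]
            label_rows: dict[tuple[str, str], str] = {}
            with open(root / entry["labels"]) as fh:
                next(fh)
                for line in fh:
                    sname, ch, lab = line.rstrip("\n").split("\t")
                    label_rows[(sname, ch)] = lab
            channels = sorted({ch for (_, ch) in label_rows})
            native_channels = {
                ch: _labels_from_str(label_rows[("native", ch)], ch)
                for ch in channels if ("native", ch) in label_rows
            }
            decoy_channels = {
                ch: [
                    _labels_from_str(label_rows[(f"decoy_{k:04d}", ch)], ch)
                    for k in range(len(decoys))
                ]
                for ch in channels if (f"decoy_0000", ch) in label_rows
            }
            rsasa_rows: dict[str, np.ndarray] = {}
            with open(root / entry["rsasa"]) as fh:
                next(fh)
                for line in fh:
                    sname, vals = line.rstrip("\n").split("\t")
                    rsasa_rows[sname] = np.array([float(x) for x in vals.split(",")])
            targets.append(
                BenchmarkTarget(
                    name=entry["name"],
                    native=native,
                    decoys=decoys,
                    lddt=np.array(entry["lddt"], dtype=float),
                    native_channels=native_channels,
                    decoy_channels=decoy_channels,
                    native_rsasa=rsasa_rows["native"],
                    decoy_rsasa=[rsasa_rows[f"decoy_{k:04d}"] for k in range(len(decoys))],
                )
            )
        return cls(targets, config)


def _labels_to_str(ls: LabelSet) -> str:
    return "".join(str(s) for s in ls.symbols())


def _labels_from_str(text: str, channel: str) -> LabelSet:
    alphabet = _CHANNEL_ALPHABET[channel]
    index = {str(a): k for k, a in enumerate(alphabet)}
    labels = np.array([index[ch] for ch in text], dtype=int)
    return LabelSet(labels, alphabet=alphabet, kind=_CHANNEL_KIND[channel])
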