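"""Analysis configuration: one human-editable YAML file.

Atoms may be referred to by 1-based integer index, or by name resolved
through the PDB atom table (or the trajectory's generated labels).  All
thresholds are surfaced here and all have defaults.

Top-level keys::

    trajectory: path.xyz            # required
    bond_orders: bonds.csv          # optional
    charges: charges.csv            # optional
    pdb: model.pdb                  # optional, for atom naming
    xi: xi.csv                      # optional (frame, xi) sidecar
    energies_in_hartree: false      # convert on read (x 627.5095)
    triad: {donor: O3B, p: PG, acceptor: OG}
    distances: [{label: "...", i: ..., j: ...}, ...]
    fragments: [{name: PO3, atoms: [...]}, ...]
    coordination: {metal: MG, ligands: [...], cutoff: 2.6}
    hbonds: {donors: [[D, H], ...], acceptors: [...],
             d_da_max: 3.5, angle_min: 120}
    crossings: [[[i, j], [k, l]], ...]
    thresholds: {prominence_tol: 0.5, smooth_window: 1, min_peak_frac: 0.2,
                 min_net_change: 0.1, charge_sum_tol: 0.01, d1: 1.73,
                 event_window: 0.1}
    seed: 0
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError

DEFAULT_THRESHOLDS = {
    "prominence_tol": 0.5,   # kcal/mol, stationary-point prominence
    "smooth_window": 1,      # frames, odd; 1 = no smoothing
    "min_peak_frac": 0.2,    # fraction of per-pair |dB/dxi| max
    "min_net_change": 0.1,   # bond-order units, forming vs strengthening
    "charge_sum_tol": 0.01,  # a.u., conservation warning threshold
    "d1": 1.73,              # Angstrom, Pauling single-bond P-O distance
    "event_window": 0.1,     # xi units, charge-vs-event correlation window
    "coordination_cutoff": 2.6,  # Angstrom
    "hbond_d_da_max": 3.5,   # Angstrom
    "hbond_angle_min": 120.0,  # degrees
}


@dataclass
class AnalysisConfig:
    trajectory: str
    bond_orders: str | None = None
    charges: str | None = None
    pdb: str | None = None
    xi: str | None = None
    energies_in_hartree: bool = False
    triad: dict = field(default_factory=dict)
    distances: list = field(default_factory=list)
    fragments: list = field(default_factory=list)
    coordination: dict | None = None
    hbonds: dict | None = None
    crossings: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)
    seed: int = 0
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        unknown = set(self.thresholds) - set(merged)
        if unknown:
            raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
        merged.update(self.thresholds)
        self.thresholds = merged

    def resolve_path(self, name: str | None) -> Path | None:
        return None if name is None else (self.base_dir / name)

    def to_dict(self) -> dict:
        return {
            "trajectory": self.trajectory, "bond_orders": self.bond_orders,
            "charges": self.charges, "pdb": self.pdb, "xi": self.xi,
            "energies_in_hartree": self.energies_in_hartree,
            "triad": self.triad, "distances": self.distances,
            "fragments": self.fragments, "coordination": self.coordination,
            "hbonds": self.hbonds, "crossings": self.crossings,
            "thresholds": self.thresholds, "seed": self.seed,
        }

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def load_config(path: str | Path) -> AnalysisConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict) or "trajectory" not in data:
        raise ValidationError(f"{path}: config must define 'trajectory'")
    known = {f for f in AnalysisConfig.__dataclass_fields__} - {"base_dir"}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(base_dir=path.parent, **data)


class AtomResolver:
    """Resolve int-or-name atom references against an atom table."""

    def __init__(self, atoms) -> None:
        self._by_name = {}
        for a in atoms:
            self._by_name.setdefault(a.name, a.index)
        self.n_atoms = len(atoms)

    def __call__(self, ref) -> int:
        if isinstance(ref, bool):
            raise ValidationError(f"bad atom reference {ref!r}")
        if isinstance(ref, int):
            if not (1 <= ref <= self.n_atoms):
                raise ValidationError(
                    f"atom index {ref} out of range 1..{self.n_atoms}")
            return ref
        if isinstance(ref, str) and ref in self._by_name:
            return self._by_name[ref]
        raise ValidationError(f"cannot resolve atom reference {ref!r}")
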