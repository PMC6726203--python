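"""Per-frame geometric measurements: distances, angles, metal coordination,
hydrogen bonds, and stationary-point distance tables.

All atom indices are 1-based; all distances are Angstrom, angles degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IrcmechError, ValidationError
from .model import Frame, ReactionPath


@dataclass(frozen=True)
class DistanceSpec:
    """A labelled atom pair to be tracked, e.g. ("OG(Ser)-PG", 3, 1)."""

    label: str
    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValidationError(f"{self.label}: i and j must differ")


@dataclass(frozen=True)
class CoordinationSpec:
    """Metal centre + candidate ligand atoms + distance cutoff (Angstrom).

    The 2.6 A default keeps every contact the active-site Mg2+ conserves
    along the path (all <= 2.58 A) while excluding the ~3 A contacts of a
    ligand that has left the first shell.
    """

    metal: int
    ligands: tuple[int, ...]
    cutoff: float = 2.6

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValidationError("coordination cutoff must be > 0")
        if not self.ligands:
            raise ValidationError("ligand list must be non-empty")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor-acceptor distance cutoff
    (default 3.5 A) and minimum D-H...A angle (default 120 deg)."""

    d_da_max: float = 3.5
    angle_min: float = 120.0

    def __post_init__(self) -> None:
        if self.d_da_max <= 0:
            raise ValidationError("d_da_max must be > 0")
        if not (0 < self.angle_min <= 180):
            raise ValidationError("angle_min must be in (0, 180]")


def _xyz(frame: Frame, i: int) -> np.ndarray:
    n = frame.coords.shape[0]
    if not (1 <= i <= n):
        raise IndexError(f"atom index {i} out of range 1..{n}")
    return frame.coords[i - 1]


def distance(frame: Frame, i: int, j: int) -> float:
    """Euclidean distance between atoms i and j (1-based), in Angstrom."""
    return float(np.linalg.norm(_xyz(frame, i) - _xyz(frame, j)))


def angle(frame: Frame, i: int, j: int, k: int) -> float:
    """Angle i-j-k with apex j, in degrees in [0, 180]."""
    v1 = _xyz(frame, i) - _xyz(frame, j)
    v2 = _xyz(frame, k) - _xyz(frame, j)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-10 or n2 < 1e-10:
        raise IrcmechError(
            f"angle({i},{j},{k}) undefined: coincident points"
        )
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def coordination_profile(path: ReactionPath, spec: CoordinationSpec
                         ) -> pd.DataFrame:
    """Per-frame metal-ligand distances and first-shell coordination number.

    A ligand counts toward the coordination number iff its distance to the
    metal is <= the cutoff; distances are reported for every candidate
    regardless.
    """
    rows = []
    for f, frame in enumerate(path.frames):
        d = {f"d_{lig}": distance(frame, spec.metal, lig)
             for lig in spec.ligands}
        d["coordination_number"] = int(
            sum(v <= spec.cutoff for v in d.values())
        )
        d["frame"] = f
        rows.append(d)
    cols = ["frame"] + [f"d_{lig}" for lig in spec.ligands] + [
        "coordination_number"]
    return pd.DataFrame(rows)[cols]


def coordination_number(distances, cutoff: float = 2.6) -> int:
    """First-shell count for a bare list of metal-ligand distances."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be > 0")
    return int(sum(d <= cutoff for d in distances))


def hbond_detect(frame: Frame, donors: list[tuple[int, int]],
                 acceptors: list[int],
                 criteria: HBondCriteria = HBondCriteria(),
                 ) -> tuple[list[tuple[int, int, int, float, float]], list[str]]:
    """Detect D-H...A contacts under the geometric criteria.

    ``donors`` are (D, H) pairs; pairs whose D-H distance exceeds 1.3 A are
    not covalently bonded and are skipped with a warning.  A contact is
    reported iff d(D, A) <= d_da_max and the D-H...A angle (apex H) >=
    angle_min.  Returns (contacts sorted by d_DA, warnings); each contact is
    (D, H, A, d_DA, angle).
    """
    contacts = []
    warnings = []
    for d_idx, h_idx in donors:
        if distance(frame, d_idx, h_idx) >= 1.3:
            warnings.append(
                f"donor pair ({d_idx}, {h_idx}) skipped: D-H distance "
                f"{distance(frame, d_idx, h_idx):.2f} A >= 1.3 A"
            )
            continue
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            d_da = distance(frame, d_idx, a_idx)
            if d_da > criteria.d_da_max:
                continue
            ang = angle(frame, d_idx, h_idx, a_idx)
            if ang >= criteria.angle_min:
                contacts.append((d_idx, h_idx, a_idx, d_da, ang))
    contacts.sort(key=lambda c: c[3])
    return contacts, warnings


def key_distance_table(path: ReactionPath, specs: list[DistanceSpec],
                       at_frames: dict[str, int],
                       decimals: int = 2) -> pd.DataFrame:
    """Tabulate labelled distances at named stationary-point frames.

    Rows are the distance labels, columns the stationary-point names (e.g.
    Reac, TS1, Int, TS2, Prod); values rounded to ``decimals`` (default 2,
    the precision such tables are conventionally printed at).
    """
    data = {}
    for point, f in at_frames.items():
        if not (0 <= f < path.n_frames):
            raise IndexError(f"frame {f} out of range for point {point!r}")
        frame = path.frames[f]
        data[point] = [round(distance(frame, s.i, s.j), decimals)
                       for s in specs]
    return pd.DataFrame(data, index=[s.label for s in specs])
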