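"""In-memory data model for reaction-path analysis.

A reaction path is an ordered sequence of molecular geometries ("frames")
along an intrinsic reaction coordinate (IRC), optionally annotated with a
potential energy per frame (kcal/mol) and a scalar reaction-coordinate value
``xi`` per frame.  Wiberg bond orders and natural-population-analysis (NPA)
atomic charges computed along the same path are carried as separate
per-frame series keyed to the path's frame order.

Atom indices are 1-based in every public interface (matching XYZ/PDB
conventions); arrays are indexed 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "Se", "Br", "I",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the QM-region model.

    ``index`` is the 1-based serial used everywhere in the public API;
    ``name`` is a free-text label such as ``"PG"`` or ``"O3B"`` used to
    resolve atoms named in analysis configs.
    """

    index: int
    element: str
    name: str = ""
    residue: str = ""

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"atom index must be >= 1, got {self.index}")
        if self.element not in _ELEMENTS:
            raise ValidationError(f"unknown element symbol {self.element!r}")


def validate_atom_table(atoms: list[AtomRecord]) -> None:
    """Check that indices are unique and contiguous 1..N."""
    indices = sorted(a.index for a in atoms)
    if indices != list(range(1, len(atoms) + 1)):
        raise ValidationError(
            f"atom indices must be contiguous 1..{len(atoms)}, got {indices[:5]}..."
        )


@dataclass
class Frame:
    """A single geometry along the path; coordinates in Angstrom."""

    frame_index: int
    coords: np.ndarray  # (n_atoms, 3)
    energy: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"frame {self.frame_index}: coords must be (n_atoms, 3), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"frame {self.frame_index}: non-finite coordinates")


@dataclass
class ReactionPath:
    """Ordered frames + reaction-coordinate axis.

    ``xi`` is dimensionless (frame index) by default, or IRC arc length in
    Angstrom*amu^1/2 when supplied externally; it must be strictly
    increasing.
    """

    atoms: list[AtomRecord]
    frames: list[Frame]
    xi: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) < 2:
            raise ValidationError("a reaction path needs at least 2 frames")
        n_atoms = len(self.atoms)
        for f in self.frames:
            if f.coords.shape[0] != n_atoms:
                raise ValidationError(
                    f"frame {f.frame_index} has {f.coords.shape[0]} atoms, "
                    f"atom table has {n_atoms}"
                )
        if self.xi is None:
            self.xi = np.arange(len(self.frames), dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if len(self.xi) != len(self.frames):
            raise ValidationError(
                f"xi has {len(self.xi)} values for {len(self.frames)} frames"
            )
        if np.any(np.diff(self.xi) <= 0):
            raise ValidationError("xi must be strictly increasing")
        if self.atoms:
            validate_atom_table(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def energies(self) -> np.ndarray | None:
        """Per-frame energies (kcal/mol), or None if any frame lacks one."""
        vals = [f.energy for f in self.frames]
        if any(v is None for v in vals):
            return None
        return np.asarray(vals, dtype=float)

    def coords_array(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coords for f in self.frames])

    def index_of_name(self, name: str) -> int:
        """Resolve an atom label to its 1-based index."""
        for a in self.atoms:
            if a.name == name:
                return a.index
        raise KeyError(f"no atom named {name!r}")


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Order a bond pair as (min, max); i == j is rejected."""
    if i == j:
        raise ValidationError(f"bond pair requires two distinct atoms, got ({i}, {j})")
    return (i, j) if i < j else (j, i)


@dataclass
class BondOrderSeries:
    """Per-frame Wiberg bond orders for selected atom pairs.

    ``values`` has shape (n_pairs, n_frames); pairs are stored canonically
    with i < j (1-based).
    """

    pairs: list[tuple[int, int]]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = [canonical_pair(i, j) for i, j in self.pairs]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.pairs):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs"
            )
        if np.any(self.values < 0):
            raise ValidationError("bond orders must be >= 0")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValidationError("duplicate bond pairs")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def pair_index(self, i: int, j: int) -> int:
        return self.pairs.index(canonical_pair(i, j))

    def get(self, i: int, j: int) -> np.ndarray:
        """Bond-order trajectory for one pair, shape (n_frames,)."""
        return self.values[self.pair_index(i, j)]


@dataclass
class ChargeSeries:
    """Per-atom, per-frame NPA charges in elementary-charge units.

    ``values`` has shape (n_atoms, n_frames).  The population scheme is
    metadata only; the analysis is agnostic to it.
    """

    values: np.ndarray
    scheme: str = "NPA"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("charge values must be (n_atoms, n_frames)")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frame_totals(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def check_conservation(self, tol: float = 0.01) -> list[str]:
        """Flag frames whose total charge drifts > tol from the first frame."""
        totals = self.frame_totals()
        drift = np.abs(totals - totals[0])
        msgs = [
            f"frame {k}: total charge {totals[k]:.4f} differs from frame 0 "
            f"({totals[0]:.4f}) by {drift[k]:.4f} > {tol}"
            for k in np.nonzero(drift > tol)[0]
        ]
        return msgs
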