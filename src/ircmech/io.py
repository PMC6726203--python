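"""Readers and writers for the external representations of path data.

Canonical formats:

* multi-frame XYZ trajectory; the comment line may carry an
  ``energy=<float>`` token (kcal/mol);
* long-format bond-order CSV with columns ``frame,i,j,order``;
* long-format charge CSV with columns ``frame,atom_index,charge``;
* PDB for atom naming (coordinate records only, via biotite);
* the "Wiberg bond index matrix" text block written by the standard NBO
  program dialect (column-chunked lower layout; see
  ``tests/data/wiberg_block.txt`` for a frozen example);
* JSON for reports.

Energies are kcal/mol throughout; Hartree inputs must be pre-converted
(x 627.5095, exposed as :data:`HARTREE_TO_KCAL`).
"""

from __future__ import annotations

import io as _io
import json
import re
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .errors import PathFormatError, ValidationError
from .model import (
    AtomRecord,
    BondOrderSeries,
    ChargeSeries,
    Frame,
    ReactionPath,
    canonical_pair,
)

HARTREE_TO_KCAL = 627.5095

_ENERGY_RE = re.compile(r"energy\s*=\s*([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def _as_text_stream(stream: IO[str] | str) -> IO[str]:
    if isinstance(stream, str):
        return _io.StringIO(stream)
    return stream


# ---------------------------------------------------------------------------
# XYZ trajectories


def read_xyz_path(stream: IO[str] | str, xi: Iterable[float] | None = None,
                  energies_in_hartree: bool = False) -> ReactionPath:
    """Parse concatenated standard-XYZ frames into a :class:`ReactionPath`.

    The per-frame comment line is scanned for an ``energy=<float>`` token.
    ``xi`` defaults to the frame index 0..n-1; a per-frame sequence may be
    supplied to override it (e.g. IRC arc length from a sidecar CSV).
    """
    stream = _as_text_stream(stream)
    lines = stream.read().splitlines()
    frames: list[Frame] = []
    elements_first: list[str] | None = None
    pos = 0
    lineno = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise PathFormatError(
                f"line {pos + 1}: expected atom count, got {lines[pos]!r}"
            ) from exc
        if pos + 1 + n_atoms >= len(lines) + 1 and pos + 2 + n_atoms > len(lines):
            raise PathFormatError(
                f"frame {len(frames)}: truncated (expected {n_atoms} atom lines)"
            )
        comment = lines[pos + 1]
        m = _ENERGY_RE.search(comment)
        energy = float(m.group(1)) if m else None
        if energy is not None and energies_in_hartree:
            energy *= HARTREE_TO_KCAL
        elements: list[str] = []
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            lineno = pos + 2 + a
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise PathFormatError(
                    f"line {lineno + 1}: expected 'El x y z', got {lines[lineno]!r}"
                )
            elements.append(parts[0])
            try:
                coords[a] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise PathFormatError(
                    f"line {lineno + 1}: non-numeric coordinate in "
                    f"{lines[lineno]!r}"
                ) from exc
        if elements_first is None:
            elements_first = elements
        elif len(elements) != len(elements_first):
            raise PathFormatError(
                f"frame {len(frames)} has {len(elements)} atoms; frame 0 "
                f"has {len(elements_first)}"
            )
        frames.append(Frame(frame_index=len(frames), coords=coords, energy=energy))
        pos = pos + 2 + n_atoms
    if elements_first is None:
        raise PathFormatError("empty XYZ stream")
    atoms = [
        AtomRecord(index=k + 1, element=el, name=f"{el}{k + 1}")
        for k, el in enumerate(elements_first)
    ]
    xi_arr = None if xi is None else np.asarray(list(xi), dtype=float)
    return ReactionPath(atoms=atoms, frames=frames, xi=xi_arr,
                        meta={"source": "xyz"})


def write_xyz_path(path: ReactionPath, stream: IO[str], precision: int = 8) -> None:
    """Write a path as concatenated XYZ frames with energy tokens."""
    fmt = f"{{:.{precision}f}}"
    for frame in path.frames:
        stream.write(f"{path.n_atoms}\n")
        comment = f"frame {frame.frame_index}"
        if frame.energy is not None:
            comment += f" energy={frame.energy:.8f}"
        stream.write(comment + "\n")
        for atom, xyz in zip(path.atoms, frame.coords):
            stream.write(
                f"{atom.element:<2s} "
                + " ".join(fmt.format(v) for v in xyz)
                + "\n"
            )


def read_xi_sidecar(stream: IO[str] | str) -> np.ndarray:
    """Read a (frame, xi) CSV overriding the default frame-index axis."""
    df = pd.read_csv(_as_text_stream(stream))
    if not {"frame", "xi"} <= set(df.columns):
        raise PathFormatError("xi sidecar needs columns 'frame' and 'xi'")
    df = df.sort_values("frame")
    if list(df["frame"]) != list(range(len(df))):
        raise ValidationError("xi sidecar frames must be contiguous 0..n-1")
    return df["xi"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Bond orders


def read_bond_orders(stream: IO[str] | str) -> BondOrderSeries:
    """Read the canonical long-format bond-order table.

    Columns ``frame,i,j,order``; every pair must cover every frame of the
    path's range (no silent interpolation of missing cells).
    """
    df = pd.read_csv(_as_text_stream(stream))
    required = {"frame", "i", "j", "order"}
    if not required <= set(df.columns):
        raise PathFormatError(
            f"bond-order table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if (df["order"] < 0).any():
        bad = df[df["order"] < 0].iloc[0]
        raise ValidationError(
            f"negative bond order {bad['order']} at frame {int(bad['frame'])} "
            f"pair ({int(bad['i'])}, {int(bad['j'])})"
        )
    ij = np.sort(df[["i", "j"]].to_numpy(dtype=int), axis=1)
    df = df.assign(i=ij[:, 0], j=ij[:, 1])
    if df.duplicated(subset=["frame", "i", "j"]).any():
        dup = df[df.duplicated(subset=["frame", "i", "j"])].iloc[0]
        raise ValidationError(
            f"duplicate row for frame {int(dup['frame'])} pair "
            f"({int(dup['i'])}, {int(dup['j'])})"
        )
    frames = sorted(df["frame"].unique())
    if frames != list(range(len(frames))):
        raise ValidationError(
            f"frame indices must be contiguous 0..{len(frames) - 1}"
        )
    wide = df.pivot_table(index=["i", "j"], columns="frame", values="order")
    if wide.isna().any().any():
        row, col = np.argwhere(wide.isna().to_numpy())[0]
        i, j = wide.index[row]
        raise ValidationError(
            f"missing bond order for pair ({i}, {j}) at frame "
            f"{wide.columns[col]}"
        )
    pairs = [(int(i), int(j)) for i, j in wide.index]
    return BondOrderSeries(pairs=pairs, values=wide.to_numpy(dtype=float))


def write_bond_orders(series: BondOrderSeries, stream: IO[str]) -> None:
    """Write the canonical long-format bond-order table."""
    stream.write("frame,i,j,order\n")
    for p, (i, j) in enumerate(series.pairs):
        for f in range(series.n_frames):
            stream.write(f"{f},{i},{j},{series.values[p, f]:.8f}\n")


# ---------------------------------------------------------------------------
# Wiberg bond index text blocks

_WIBERG_HEADER = "Wiberg bond index matrix"
_ROW_RE = re.compile(r"^\s*(\d+)\.\s+(\S+)\s+(.*)$")


def parse_wiberg_matrix(stream: IO[str] | str) -> tuple[list[str], np.ndarray]:
    """Parse the NBO "Wiberg bond index matrix" text block.

    The NBO dialect prints the full symmetric matrix in chunks of at most
    nine columns; each chunk is headed by an ``Atom   c1 c2 ...`` line and a
    dashed rule, followed by one row per atom of the form
    ``  <i>. <El>  v v v ...``.  Chunks are re-assembled here; the diagonal
    is kept as printed but ignored by downstream series extraction.

    Returns (element symbols, symmetric matrix).
    """
    lines = _as_text_stream(stream).read().splitlines()
    start = next(
        (k for k, line in enumerate(lines) if _WIBERG_HEADER in line), None
    )
    if start is None:
        raise PathFormatError(
            "no 'Wiberg bond index matrix' block found in stream"
        )
    k = start + 1
    cols_per_chunk: list[list[int]] = []
    rows_per_chunk: list[dict[int, tuple[str, list[float]]]] = []
    while k < len(lines):
        line = lines[k]
        if "Atom" in line and re.search(r"Atom\s+\d", line):
            col_ids = [int(t) for t in re.findall(r"\d+", line)]
            k += 1
            if k < len(lines) and set(lines[k].strip()) <= set("- "):
                k += 1  # dashed rule
            rows: dict[int, tuple[str, list[float]]] = {}
            while k < len(lines):
                m = _ROW_RE.match(lines[k])
                if not m:
                    break
                idx = int(m.group(1))
                vals = [float(v) for v in m.group(3).split()]
                if len(vals) != len(col_ids):
                    raise PathFormatError(
                        f"Wiberg row for atom {idx}: expected {len(col_ids)} "
                        f"columns, found {len(vals)}"
                    )
                rows[idx] = (m.group(2), vals)
                k += 1
            cols_per_chunk.append(col_ids)
            rows_per_chunk.append(rows)
        elif not line.strip():
            k += 1
        else:
            break
    if not cols_per_chunk:
        raise PathFormatError("Wiberg block has no column chunks")
    n = max(max(r) for r in rows_per_chunk)
    n_cols = max(max(c) for c in cols_per_chunk)
    if n != n_cols:
        raise PathFormatError(
            f"Wiberg block: {n} rows but columns up to {n_cols}"
        )
    row_sets = [set(r) for r in rows_per_chunk]
    if any(rs != set(range(1, n + 1)) for rs in row_sets):
        raise PathFormatError("Wiberg block: chunks list different atom rows")
    mat = np.full((n, n), np.nan)
    elements = [""] * n
    for col_ids, rows in zip(cols_per_chunk, rows_per_chunk):
        for idx, (el, vals) in rows.items():
            elements[idx - 1] = re.sub(r"\d", "", el) or el
            for c, v in zip(col_ids, vals):
                mat[idx - 1, c - 1] = v
    if np.isnan(mat).any():
        miss = np.argwhere(np.isnan(mat))[0] + 1
        raise PathFormatError(
            f"Wiberg block incomplete: entry ({miss[0]}, {miss[1]}) never printed"
        )
    return elements, mat


def parse_wiberg_block(stream: IO[str] | str, frame_index: int = 0
                       ) -> BondOrderSeries:
    """Parse one Wiberg block into a single-frame :class:`BondOrderSeries`.

    All i < j pairs of the matrix are returned; the diagonal is ignored.
    ``frame_index`` is recorded in the series metadata so fragments from
    successive log files can be assembled into a full path series.
    """
    _, mat = parse_wiberg_matrix(stream)
    n = mat.shape[0]
    pairs = [(i + 1, j + 1) for i in range(n) for j in range(i + 1, n)]
    values = np.array([[mat[i - 1, j - 1]] for i, j in pairs])
    return BondOrderSeries(pairs=pairs, values=values,
                           meta={"frame_index": frame_index})


def assemble_wiberg_frames(blocks: list[BondOrderSeries],
                           pairs: list[tuple[int, int]]) -> BondOrderSeries:
    """Stack single-frame Wiberg fragments (in path order) for chosen pairs."""
    sel = [canonical_pair(i, j) for i, j in pairs]
    values = np.empty((len(sel), len(blocks)))
    for f, blk in enumerate(blocks):
        for p, pair in enumerate(sel):
            values[p, f] = blk.get(*pair)[0]
    return BondOrderSeries(pairs=sel, values=values)


# ---------------------------------------------------------------------------
# Charges


def read_charges(stream: IO[str] | str, charge_sum_tol: float = 0.01
                 ) -> ChargeSeries:
    """Read the canonical long-format charge table (frame,atom_index,charge).

    Per-frame totals drifting more than ``charge_sum_tol`` (a.u.) from the
    first frame are recorded as validation warnings on the returned series,
    not raised: population-analysis charges legitimately wobble in the last
    digit.
    """
    df = pd.read_csv(_as_text_stream(stream))
    required = {"frame", "atom_index", "charge"}
    if not required <= set(df.columns):
        raise PathFormatError(
            f"charge table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df.duplicated(subset=["frame", "atom_index"]).any():
        raise ValidationError("duplicate (frame, atom_index) row in charge table")
    wide = df.pivot_table(index="atom_index", columns="frame", values="charge")
    if wide.isna().any().any():
        raise ValidationError("missing (frame, atom) cell in charge table")
    series = ChargeSeries(values=wide.to_numpy(dtype=float))
    series.warnings.extend(series.check_conservation(charge_sum_tol))
    return series


def write_charges(series: ChargeSeries, stream: IO[str]) -> None:
    stream.write("frame,atom_index,charge\n")
    for a in range(series.n_atoms):
        for f in range(series.n_frames):
            stream.write(f"{f},{a + 1},{series.values[a, f]:.8f}\n")


# ---------------------------------------------------------------------------
# PDB atom tables


def read_pdb_atoms(stream: IO[str] | str) -> list[AtomRecord]:
    """Extract (serial, name, resName, resSeq) from PDB coordinate records.

    Uses biotite's PDB reader; only the naming information is kept — the
    trajectory geometry always comes from the XYZ path.
    """
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(_as_text_stream(stream))
    structure = f.get_structure(model=1)
    records = []
    for k in range(structure.array_length()):
        element = str(structure.element[k]).capitalize()
        records.append(
            AtomRecord(
                index=k + 1,
                element=element,
                name=str(structure.atom_name[k]),
                residue=f"{str(structure.res_name[k])}{int(structure.res_id[k])}",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Reports


def write_report(report, stream: IO[str]) -> None:
    """Serialize a report object (anything with ``to_dict``) as JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else report
    json.dump(payload, stream, indent=2, sort_keys=True, default=_json_default)
    stream.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
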