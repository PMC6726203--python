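"""Fragment aggregation and trend analysis of per-atom NPA charges.

A fragment is a named set of atoms (the transferred PO3 group, the metal
ion, a residue side chain...).  Summing atomic charges over a fragment and
tracking the sum along the reaction coordinate exposes charge transfer: a
metaphosphate-like PO3 group approaches -1 a.u., a proton transfer moves
~+0.5 a.u. worth of charge between donor and acceptor fragments, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .model import ChargeSeries
from .synchronicity import BondEvent


@dataclass(frozen=True)
class FragmentDef:
    """A named atom set; indices 1-based.  Overlapping fragments must be
    explicitly flagged or partition-based checks will reject them."""

    name: str
    atom_indices: tuple[int, ...]
    formal_charge: int | None = None
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not self.atom_indices:
            raise ValidationError(f"fragment {self.name!r} has no atoms")
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValidationError(f"fragment {self.name!r} repeats atoms")


def check_fragment_overlap(fragments: list[FragmentDef]) -> None:
    seen: dict[int, str] = {}
    for frag in fragments:
        for a in frag.atom_indices:
            if a in seen and not (frag.allow_overlap):
                raise ValidationError(
                    f"atom {a} appears in both {seen[a]!r} and {frag.name!r} "
                    "without allow_overlap"
                )
            seen.setdefault(a, frag.name)


def fragment_charge(series: ChargeSeries, frag: FragmentDef) -> np.ndarray:
    """Per-frame summed charge of the fragment, shape (n_frames,)."""
    for a in frag.atom_indices:
        if not (1 <= a <= series.n_atoms):
            raise IndexError(
                f"fragment {frag.name!r}: atom {a} out of range "
                f"1..{series.n_atoms}"
            )
    idx = [a - 1 for a in frag.atom_indices]
    return series.values[idx].sum(axis=0)


@dataclass
class FragmentChargeSeries:
    """Fragment charges along the path plus their summary statistics."""

    fragments: list[FragmentDef]
    xi: np.ndarray
    values: dict[str, np.ndarray]  # fragment name -> (n_frames,)
    extrema: dict[str, dict]       # name -> {min: (xi, q), max: (xi, q)}
    at_stationary: pd.DataFrame    # fragment x stationary-point table
    deltas: dict[str, dict]        # name -> {to_extremum, reactant_to_product}
    monotone_segments: dict[str, list[tuple[int, int, int]]]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fragments": [f.name for f in self.fragments],
            "extrema": self.extrema,
            "at_stationary": self.at_stationary.to_dict(),
            "deltas": self.deltas,
            "monotone_segments": self.monotone_segments,
            "warnings": self.warnings,
        }


def _monotone_segments(q: np.ndarray) -> list[tuple[int, int, int]]:
    """(start_frame, end_frame, sign) runs of constant finite-difference sign."""
    signs = np.sign(np.diff(q))
    segments = []
    start = 0
    for k in range(1, len(signs)):
        if signs[k] != signs[start]:
            segments.append((start, k, int(signs[start])))
            start = k
    if len(signs):
        segments.append((start, len(signs), int(signs[start])))
    return segments


def charge_profile_report(series: ChargeSeries,
                          fragments: list[FragmentDef],
                          stationary_points,
                          xi=None) -> FragmentChargeSeries:
    """Tabulate fragment charges at stationary points and summarize trends.

    ``stationary_points`` come from the mechanism stage (anything with
    ``frame_index`` and ``kind``).  Reported per fragment: the value at
    every stationary point, the global extrema with their xi, the
    reactant-to-extremum and reactant-to-product deltas, and the monotone
    segments of the curve.
    """
    xi = np.arange(series.n_frames, dtype=float) if xi is None \
        else np.asarray(xi, dtype=float)
    values = {f.name: fragment_charge(series, f) for f in fragments}
    extrema, deltas, segs = {}, {}, {}
    col_names = _stationary_labels(stationary_points)
    table_rows = {}
    for frag in fragments:
        q = values[frag.name]
        kmin, kmax = int(np.argmin(q)), int(np.argmax(q))
        extrema[frag.name] = {
            "min": {"xi": float(xi[kmin]), "value": float(q[kmin])},
            "max": {"xi": float(xi[kmax]), "value": float(q[kmax])},
        }
        # delta to whichever interior extremum is farther from the start
        k_ext = kmin if abs(q[kmin] - q[0]) >= abs(q[kmax] - q[0]) else kmax
        deltas[frag.name] = {
            "to_extremum": float(q[k_ext] - q[0]),
            "reactant_to_product": float(q[-1] - q[0]),
        }
        segs[frag.name] = _monotone_segments(q)
        table_rows[frag.name] = [
            float(q[p.frame_index]) for p in stationary_points
        ]
    table = pd.DataFrame.from_dict(table_rows, orient="index",
                                   columns=col_names)
    return FragmentChargeSeries(
        fragments=fragments, xi=xi, values=values, extrema=extrema,
        at_stationary=table, deltas=deltas, monotone_segments=segs,
        warnings=list(series.warnings),
    )


def _stationary_labels(points) -> list[str]:
    labels = []
    counts: dict[str, int] = {}
    short = {"reactant": "Reac", "ts": "TS", "intermediate": "Int",
             "product": "Prod"}
    n_kind: dict[str, int] = {}
    for p in points:
        n_kind[p.kind] = n_kind.get(p.kind, 0) + 1
    for p in points:
        base = short.get(p.kind, p.kind)
        if n_kind[p.kind] > 1:
            counts[p.kind] = counts.get(p.kind, 0) + 1
            labels.append(f"{base}{counts[p.kind]}")
        else:
            labels.append(base)
    return labels


def charge_event_correlation(series: ChargeSeries,
                             fragments: list[FragmentDef],
                             events: list[BondEvent],
                             window: float,
                             xi=None) -> tuple[list[dict], list[str]]:
    """Charge change of each fragment across each bond event.

    For every event, the fragment charge difference across
    [xi_peak - window/2, xi_peak + window/2] is reported together with a
    sign-only summary ("gains"/"loses"/"unchanged", threshold 0.01 a.u.).
    Windows reaching past the path ends are clipped with a warning.
    """
    if not events:
        raise InsufficientDataError("no events supplied")
    xi = np.arange(series.n_frames, dtype=float) if xi is None \
        else np.asarray(xi, dtype=float)
    warnings: list[str] = []
    results = []
    frag_values = {f.name: fragment_charge(series, f) for f in fragments}
    for e in events:
        lo_xi, hi_xi = e.xi_peak - window / 2, e.xi_peak + window / 2
        if lo_xi < xi[0] or hi_xi > xi[-1]:
            warnings.append(
                f"event at xi={e.xi_peak:.3g}: window clipped to path range"
            )
        lo = int(np.searchsorted(xi, max(lo_xi, xi[0]), side="left"))
        hi = int(np.searchsorted(xi, min(hi_xi, xi[-1]), side="right")) - 1
        lo, hi = min(lo, series.n_frames - 1), max(hi, 0)
        entry = {"pair": list(e.pair), "xi_peak": e.xi_peak,
                 "direction": e.direction, "fragments": {}}
        for name, q in frag_values.items():
            dq = float(q[hi] - q[lo])
            summary = ("gains" if dq > 0.01
                       else "loses" if dq < -0.01 else "unchanged")
            entry["fragments"][name] = {"delta_q": dq, "summary": summary}
        results.append(entry)
    return results, warnings
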