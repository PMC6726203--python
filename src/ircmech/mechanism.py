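"""Stationary-point analysis of the energy profile and associative vs
dissociative classification of transition states via Pauling's bond
order-distance relation.

Pauling's relation for a fractional bond, D(n) = D(1) - 0.60 * log10(n),
links a P-O distance D(n) to the fractional bond number n, with D(1) the
single-bond P-O distance (1.73 A).  At a phosphoryl-transfer transition
state the mean of the breaking and forming P-O distances gives a single n
that quantifies how "tight" (associative, n -> 1) or "loose" (dissociative,
n -> 0, metaphosphate-like) the TS is: 100*n is the percent associative
character.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InsufficientDataError, IrcmechError
from .geometry import distance
from .model import BondOrderSeries, ReactionPath

#: P-O single-bond distance (Angstrom) used as the Pauling D(1) default.
D1_PO = 1.73

#: Pauling coefficient (Angstrom per decade of bond number).
PAULING_SLOPE = 0.60


def _truncate(x: float, decimals: int) -> float:
    # tiny epsilon so exact decimal values survive float representation
    scale = 10 ** decimals
    return math.floor(x * scale + 1e-9) / scale


@dataclass(frozen=True)
class PaulingResult:
    """Associativity of one transition state from its two P-O distances.

    ``n`` is the fractional bond number reported at 3 decimals (truncated
    toward zero, the convention the percent figures are derived from);
    ``n_exact`` keeps full precision.  ``pct_assoc`` = 100*n, clipped to
    [0, 100], at 1 decimal; ``pct_assoc + pct_dissoc == 100``.
    """

    D1: float
    d_break: float
    d_form: float
    Davg: float
    n: float
    n_exact: float
    pct_assoc: float
    pct_dissoc: float

    def to_dict(self) -> dict:
        return {
            "D1": self.D1, "d_break": self.d_break, "d_form": self.d_form,
            "Davg": self.Davg, "n": self.n, "n_exact": self.n_exact,
            "pct_assoc": self.pct_assoc, "pct_dissoc": self.pct_dissoc,
        }


def pauling_bond_number(d_break: float, d_form: float,
                        D1: float = D1_PO) -> PaulingResult:
    """Fractional bond number n for a TS with the given P-O distances.

    Averages the breaking and forming distances and inverts
    D(n) = D1 - 0.60*log10(n).  The logarithm is base 10: with the 0.60 A
    coefficient this is the only base that reproduces the standard worked
    values for loose phosphoryl-transfer transition states.
    """
    if d_break <= 0 or d_form <= 0 or D1 <= 0:
        raise IrcmechError("Pauling relation requires positive distances")
    davg = (d_break + d_form) / 2.0
    n_exact = 10.0 ** ((D1 - davg) / PAULING_SLOPE)
    n = _truncate(n_exact, 3)
    pct_assoc = float(np.clip(round(100.0 * n, 1), 0.0, 100.0))
    return PaulingResult(
        D1=D1, d_break=d_break, d_form=d_form, Davg=round(davg, 2),
        n=n, n_exact=n_exact,
        pct_assoc=pct_assoc, pct_dissoc=round(100.0 - pct_assoc, 1),
    )


@dataclass(frozen=True)
class StationaryPoint:
    """One stationary point of the energy profile.

    ``kind`` is reactant / ts / intermediate / product; ``rel_energy`` is
    kcal/mol relative to the reactant; ``shoulder`` flags a ts belonging to
    an equal-height adjacent pair (a plateau the potential-energy surface
    cannot resolve into a single maximum).
    """

    frame_index: int
    kind: str
    rel_energy: float
    xi: float = 0.0
    shoulder: bool = False

    def to_dict(self) -> dict:
        return {
            "frame_index": self.frame_index, "kind": self.kind,
            "rel_energy": round(self.rel_energy, 4), "xi": self.xi,
            "shoulder": self.shoulder,
        }


def detect_stationary_points(energies, xi=None,
                             prominence_tol: float = 0.5,
                             smooth_window: int = 1) -> list[StationaryPoint]:
    """Locate reactant, TSs, intermediates and product on an energy profile.

    Interior local maxima with topographic prominence >= ``prominence_tol``
    (kcal/mol) are transition states; the interior minimum between two
    consecutive TSs is an intermediate.  The first and last frames are
    always labelled reactant (rel_energy 0) and product.  An odd
    ``smooth_window`` > 1 applies a moving average before peak detection
    (reported energies always come from the raw profile).

    The 0.5 kcal/mol default prominence keeps sub-kcal features: shallow
    intermediates flanked by a barely higher first TS are mechanistically
    meaningful and must not be smoothed away.
    """
    e = np.asarray(energies, dtype=float)
    if e.ndim != 1 or len(e) < 3:
        raise InsufficientDataError(
            f"stationary-point detection needs >= 3 frames, got {e.shape}"
        )
    if not np.all(np.isfinite(e)):
        raise IrcmechError("energies must be finite")
    xi = np.arange(len(e), dtype=float) if xi is None else np.asarray(xi, float)
    work = e
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise IrcmechError("smooth_window must be odd")
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.concatenate([np.full(pad, e[0]), e, np.full(pad, e[-1])])
        work = np.convolve(padded, kernel, mode="valid")

    peaks, _ = find_peaks(work, prominence=prominence_tol)
    # refine each smoothed peak to the raw-profile local maximum nearby
    if smooth_window > 1 and len(peaks):
        half = smooth_window // 2
        refined = []
        for p in peaks:
            lo, hi = max(1, p - half), min(len(e) - 1, p + half + 1)
            refined.append(lo + int(np.argmax(e[lo:hi])))
        peaks = np.array(sorted(set(refined)))

    e0 = e[0]
    points = [StationaryPoint(0, "reactant", 0.0, xi=float(xi[0]))]
    ts_frames = [int(p) for p in peaks if 0 < p < len(e) - 1]
    for a, b in zip(ts_frames, ts_frames[1:]):
        m = a + 1 + int(np.argmin(e[a + 1:b]))
        points.append(StationaryPoint(m, "intermediate", float(e[m] - e0),
                                      xi=float(xi[m])))
    heights = {f: e[f] for f in ts_frames}
    for k, f in enumerate(ts_frames):
        shoulder = any(
            abs(heights[f] - heights[g]) < 1e-9
            for g in (ts_frames[k - 1:k] + ts_frames[k + 1:k + 2])
        )
        points.append(StationaryPoint(f, "ts", float(e[f] - e0),
                                      xi=float(xi[f]), shoulder=shoulder))
    points.append(StationaryPoint(len(e) - 1, "product", float(e[-1] - e0),
                                  xi=float(xi[-1])))
    points.sort(key=lambda p: p.frame_index)
    return points


@dataclass
class MechanismReport:
    """Full mechanistic characterization of one reaction path."""

    stationary_points: list[StationaryPoint]
    pathway_class: str  # concerted | stepwise | none
    pauling: list[PaulingResult]
    barrier: float | None
    reaction_energy: float
    metaphosphate_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def ts_points(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "ts"]

    @property
    def intermediates(self) -> list[StationaryPoint]:
        return [p for p in self.stationary_points if p.kind == "intermediate"]

    def to_dict(self) -> dict:
        return {
            "stationary_points": [p.to_dict() for p in self.stationary_points],
            "pathway_class": self.pathway_class,
            "pauling": [p.to_dict() for p in self.pauling],
            "barrier": None if self.barrier is None else round(self.barrier, 4),
            "reaction_energy": round(self.reaction_energy, 4),
            "metaphosphate_flags": {
                str(k): v for k, v in self.metaphosphate_flags.items()
            },
        }


def classify_mechanism(path: ReactionPath, donor_o: int, p: int,
                       acceptor_o: int,
                       energies=None,
                       bond_orders: BondOrderSeries | None = None,
                       D1: float = D1_PO,
                       prominence_tol: float = 0.5,
                       smooth_window: int = 1) -> MechanismReport:
    """Classify a phosphoryl-transfer path as concerted or stepwise and
    quantify each TS's associative character.

    ``donor_o``, ``p``, ``acceptor_o`` are the 1-based indices of the
    leaving oxygen, the transferred phosphorus, and the entering oxygen.
    At each detected TS Pauling's relation is applied to the frame's
    d(donor_o, p) and d(p, acceptor_o).  An intermediate is flagged as
    metaphosphate-like iff both its P-O bond orders are < 0.5 when bond
    orders are supplied; without bond orders the geometric surrogate is
    both P-O distances > D1 + 0.60 (one Pauling decade looser than a
    single bond, i.e. n < 0.1 on both sides).
    """
    if energies is None:
        energies = path.energies
    if energies is None:
        raise IrcmechError("no energies on path and none supplied")
    points = detect_stationary_points(energies, xi=path.xi,
                                      prominence_tol=prominence_tol,
                                      smooth_window=smooth_window)
    ts = [pt for pt in points if pt.kind == "ts"]
    ints = [pt for pt in points if pt.kind == "intermediate"]
    if not ts:
        pathway = "none"
    elif len(ts) >= 2 and ints:
        pathway = "stepwise"
    else:
        pathway = "concerted"
    pauling = [
        pauling_bond_number(
            distance(path.frames[pt.frame_index], donor_o, p),
            distance(path.frames[pt.frame_index], p, acceptor_o),
            D1=D1,
        )
        for pt in ts
    ]
    meta_flags: dict[int, bool] = {}
    for pt in ints:
        if bond_orders is not None:
            b1 = bond_orders.get(donor_o, p)[pt.frame_index]
            b2 = bond_orders.get(p, acceptor_o)[pt.frame_index]
            meta_flags[pt.frame_index] = bool(b1 < 0.5 and b2 < 0.5)
        else:
            frame = path.frames[pt.frame_index]
            meta_flags[pt.frame_index] = bool(
                distance(frame, donor_o, p) > D1 + PAULING_SLOPE
                and distance(frame, p, acceptor_o) > D1 + PAULING_SLOPE
            )
    barrier = max((pt.rel_energy for pt in ts), default=None)
    return MechanismReport(
        stationary_points=points,
        pathway_class=pathway,
        pauling=pauling,
        barrier=barrier,
        reaction_energy=points[-1].rel_energy,
        metaphosphate_flags=meta_flags,
    )
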