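"""Synthetic reaction paths with known ground truth.

Quantum-chemistry reaction paths (IRC geometries, energies, Wiberg bond
orders, NPA charges) cannot be regenerated at desk scale, so this module
emulates their structure instead: sigmoidal bond-order transitions for
breaking/forming bonds, an energy profile interpolated through prescribed
stationary points, smoothly drifting charges with a conserved total, and
i.i.d. Gaussian observation noise per channel.  The reactive triad
(donor O, P, acceptor O) is laid out collinearly with P-O distances derived
from the bond orders through the inverted Pauling relation, so geometric
and bond-order descriptors are mutually consistent by construction.

Randomness comes from ``numpy.random.default_rng(seed)`` (PCG64), which is
reproducible across platforms; every generated bundle is bit-identical for
a fixed spec + seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

from .errors import SpecError
from .model import (
    AtomRecord,
    BondOrderSeries,
    ChargeSeries,
    Frame,
    ReactionPath,
    canonical_pair,
)

# canonical atom layout of the synthetic QM region (1-based indices)
_NAMED_ATOMS: list[tuple[int, str, str, str]] = [
    (1, "P", "PG", "ATP"),      # transferred phosphorus
    (2, "O", "O3B", "ATP"),     # leaving (bridging) oxygen
    (3, "O", "OG", "SER"),      # entering serine oxygen
    (4, "O", "O1G", "ATP"),     # non-bridging gamma oxygens
    (5, "O", "O2G", "ATP"),
    (6, "O", "O3G", "ATP"),
    (7, "Mg", "MG", "MG"),      # catalytic magnesium
    (8, "N", "NZ", "LYS129"),
    (9, "H", "HZ1", "LYS129"),
    (10, "H", "HG", "SER"),
    (11, "O", "OD1", "ASP127"),
    (12, "O", "OW", "HOH"),
    (13, "O", "O", "ASN132"),
    (14, "O", "OD2", "ASP145"),
]

TRIAD = (2, 1, 3)  # (donor O, P, acceptor O)


def default_atoms(n_atoms: int = 61) -> list[AtomRecord]:
    """Atom table of the synthetic QM region; filler C/H beyond index 14."""
    if n_atoms < len(_NAMED_ATOMS):
        raise SpecError(f"n_atoms must be >= {len(_NAMED_ATOMS)}")
    atoms = [AtomRecord(index=i, element=el, name=nm, residue=res)
             for i, el, nm, res in _NAMED_ATOMS]
    for k in range(len(_NAMED_ATOMS) + 1, n_atoms + 1):
        el = "C" if k % 2 else "H"
        atoms.append(AtomRecord(index=k, element=el, name=f"{el}{k}",
                                residue="ENV"))
    return atoms


@dataclass(frozen=True)
class LogisticEventSpec:
    """One sigmoidal bond-order transition: B goes from ``B_start`` to
    ``B_end`` with midpoint ``mu`` and steepness ``s`` (xi units)."""

    pair: tuple[int, int]
    B_start: float
    B_end: float
    mu: float
    s: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise SpecError("logistic steepness s must be > 0")

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "B_start": self.B_start,
                "B_end": self.B_end, "mu": self.mu, "s": self.s}


@dataclass(frozen=True)
class StationaryTarget:
    xi: float
    rel_energy: float
    kind: str  # reactant | ts | intermediate | product

    def to_dict(self) -> dict:
        return {"xi": self.xi, "rel_energy": self.rel_energy,
                "kind": self.kind}


@dataclass(frozen=True)
class ProfileSpec:
    """Energy profile through ordered stationary targets, interpolated with
    a cubic Hermite spline having zero slope at every target, so extrema
    fall exactly on the targets and nowhere else."""

    targets: tuple[StationaryTarget, ...]

    def __post_init__(self) -> None:
        kinds = [t.kind for t in self.targets]
        if len(self.targets) < 2 or kinds[0] != "reactant" \
                or kinds[-1] != "product":
            raise SpecError("profile must run reactant ... product")
        for a, b in zip(kinds[1:-1], kinds[2:-1]):
            if {a, b} != {"ts", "intermediate"}:
                raise SpecError("interior stationary kinds must alternate "
                                "ts/intermediate")
        xs = [t.xi for t in self.targets]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise SpecError("profile target xi must be strictly increasing")

    def evaluate(self, xi: np.ndarray) -> np.ndarray:
        xs = np.array([t.xi for t in self.targets])
        ys = np.array([t.rel_energy for t in self.targets])
        spline = CubicHermiteSpline(xs, ys, np.zeros_like(xs))
        return spline(np.clip(xi, xs[0], xs[-1]))

    def to_dict(self) -> dict:
        return {"targets": [t.to_dict() for t in self.targets]}


@dataclass(frozen=True)
class ChargeTrend:
    """Smooth fragment-charge curve: start/end values plus an optional
    interior extremum (value ``q_ext`` at ``xi_ext``), interpolated
    shape-preservingly (PCHIP) so the extremum lands where planted."""

    name: str
    atom_indices: tuple[int, ...]
    q_start: float
    q_end: float
    q_ext: float | None = None
    xi_ext: float | None = None

    def evaluate(self, xi: np.ndarray) -> np.ndarray:
        if self.q_ext is None:
            return np.interp(xi, [xi[0], xi[-1]], [self.q_start, self.q_end])
        interp = PchipInterpolator(
            [xi[0], self.xi_ext, xi[-1]],
            [self.q_start, self.q_ext, self.q_end],
        )
        return interp(xi)

    def to_dict(self) -> dict:
        return {"name": self.name, "atom_indices": list(self.atom_indices),
                "q_start": self.q_start, "q_end": self.q_end,
                "q_ext": self.q_ext, "xi_ext": self.xi_ext}


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian i.i.d. observation noise per data channel."""

    energy: float = 0.0      # kcal/mol
    bond_order: float = 0.0  # dimensionless
    charge: float = 0.0      # a.u.
    coords: float = 0.0      # Angstrom

    def __post_init__(self) -> None:
        if min(self.energy, self.bond_order, self.charge, self.coords) < 0:
            raise SpecError("noise sigmas must be >= 0")

    def to_dict(self) -> dict:
        return {"energy": self.energy, "bond_order": self.bond_order,
                "charge": self.charge, "coords": self.coords}


@dataclass(frozen=True)
class SyntheticPathSpec:
    """Everything needed to generate one reaction-path bundle."""

    n_atoms: int
    n_frames: int
    xi_range: tuple[float, float]
    events: tuple[LogisticEventSpec, ...]
    profile: ProfileSpec
    charge_trends: tuple[ChargeTrend, ...] = ()
    # pair -> (distance at B=1, distance at B=0); drives triad geometry
    distance_couplings: dict[tuple[int, int], tuple[float, float]] = \
        field(default_factory=dict)
    noise: NoiseSpec = NoiseSpec()
    system_charge: float = -2.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise SpecError("n_frames must be >= 3")
        if self.xi_range[1] <= self.xi_range[0]:
            raise SpecError("xi_range must be increasing")

    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms, "n_frames": self.n_frames,
            "xi_range": list(self.xi_range),
            "events": [e.to_dict() for e in self.events],
            "profile": self.profile.to_dict(),
            "charge_trends": [t.to_dict() for t in self.charge_trends],
            "distance_couplings": {
                f"{i}-{j}": list(v)
                for (i, j), v in self.distance_couplings.items()
            },
            "noise": self.noise.to_dict(),
            "system_charge": self.system_charge,
            "seed": self.seed, "name": self.name,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticPathSpec":
        return cls(
            n_atoms=d["n_atoms"], n_frames=d["n_frames"],
            xi_range=tuple(d["xi_range"]),
            events=tuple(LogisticEventSpec(pair=tuple(e["pair"]),
                                           B_start=e["B_start"],
                                           B_end=e["B_end"], mu=e["mu"],
                                           s=e["s"])
                         for e in d["events"]),
            profile=ProfileSpec(tuple(StationaryTarget(**t)
                                      for t in d["profile"]["targets"])),
            charge_trends=tuple(
                ChargeTrend(name=t["name"],
                            atom_indices=tuple(t["atom_indices"]),
                            q_start=t["q_start"], q_end=t["q_end"],
                            q_ext=t["q_ext"], xi_ext=t["xi_ext"])
                for t in d["charge_trends"]),
            distance_couplings={
                tuple(int(x) for x in k.split("-")): tuple(v)
                for k, v in d["distance_couplings"].items()
            },
            noise=NoiseSpec(**d["noise"]),
            system_charge=d["system_charge"],
            seed=d["seed"], name=d.get("name", ""),
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticPathSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class GroundTruth:
    """What was planted, for use as a test oracle."""

    event_midpoints: list[tuple[tuple[int, int], float]]
    stationary: list[dict]          # {frame, xi, kind, rel_energy}
    fragment_extrema: dict[str, tuple[float, float] | None]
    pathway_class: str              # concerted | stepwise | none
    associativity: str | None       # associative | dissociative | None
    implied_n: dict[int, float]     # ts frame -> sqrt(B_break * B_form)
    proton_transfer_span: float | None = None

    def to_dict(self) -> dict:
        return {
            "event_midpoints": [[list(p), m] for p, m in self.event_midpoints],
            "stationary": self.stationary,
            "fragment_extrema": self.fragment_extrema,
            "pathway_class": self.pathway_class,
            "associativity": self.associativity,
            "implied_n": {str(k): v for k, v in self.implied_n.items()},
            "proton_transfer_span": self.proton_transfer_span,
        }


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _bond_curves(spec: SyntheticPathSpec, xi: np.ndarray
                 ) -> tuple[list[tuple[int, int]], np.ndarray]:
    pairs: list[tuple[int, int]] = []
    for e in spec.events:
        p = canonical_pair(*e.pair)
        if p not in pairs:
            pairs.append(p)
    values = np.zeros((len(pairs), len(xi)))
    first_start: dict[tuple[int, int], float] = {}
    for e in sorted(spec.events, key=lambda e: e.mu):
        p = canonical_pair(*e.pair)
        k = pairs.index(p)
        if p not in first_start:
            first_start[p] = e.B_start
            values[k] += e.B_start
        values[k] += (e.B_end - e.B_start) * _logistic((xi - e.mu) / e.s)
    return pairs, values


def _pair_distance(b: np.ndarray, d1: float, d0: float) -> np.ndarray:
    """Invert Pauling's relation, clamped so d stays within [d1, d0]."""
    b_floor = 10.0 ** (-(d0 - d1) / 0.60)
    return d1 - 0.60 * np.log10(np.clip(b, b_floor, None))


def generate_path(spec: SyntheticPathSpec
                  ) -> tuple[ReactionPath, BondOrderSeries, ChargeSeries,
                             GroundTruth]:
    """Generate one (path, bond orders, charges, ground truth) bundle.

    Deterministic for a fixed spec (the RNG seed lives in the spec).  The
    reactive triad is collinear along z with P-O distances derived from the
    bond orders via the inverted Pauling relation; spectator atoms sit on a
    static lattice well away from the reaction axis.
    """
    rng = np.random.default_rng(spec.seed)
    xi = np.linspace(spec.xi_range[0], spec.xi_range[1], spec.n_frames)
    atoms = default_atoms(spec.n_atoms)

    # --- bond orders -------------------------------------------------------
    pairs, b_clean = _bond_curves(spec, xi)
    b_noisy = b_clean
    if spec.noise.bond_order > 0:
        b_noisy = np.clip(
            b_clean + rng.normal(0, spec.noise.bond_order, b_clean.shape),
            0.0, None)
    bond_orders = BondOrderSeries(pairs=list(pairs), values=b_noisy,
                                  meta={"synthetic": spec.name})

    # --- energies ----------------------------------------------------------
    e_clean = spec.profile.evaluate(xi)
    e_noisy = e_clean if spec.noise.energy == 0 else \
        e_clean + rng.normal(0, spec.noise.energy, e_clean.shape)

    # --- geometry ----------------------------------------------------------
    donor, p_atom, acceptor = TRIAD
    break_pair = canonical_pair(donor, p_atom)
    form_pair = canonical_pair(p_atom, acceptor)
    emit_geometry = bool(spec.distance_couplings)
    if emit_geometry:
        for pr in (break_pair, form_pair):
            if pr not in spec.distance_couplings:
                raise SpecError(
                    f"distance_couplings missing triad pair {pr}; cannot "
                    "emit geometry")
        d_break = _pair_distance(b_clean[pairs.index(break_pair)],
                                 *spec.distance_couplings[break_pair])
        d_form = _pair_distance(b_clean[pairs.index(form_pair)],
                                *spec.distance_couplings[form_pair])
    else:
        d_break = np.full(spec.n_frames, 1.73)
        d_form = np.full(spec.n_frames, 1.73)

    base = np.zeros((spec.n_atoms, 3))
    for k in range(spec.n_atoms):
        if k + 1 in TRIAD:
            continue
        base[k] = (8.0 + 2.0 * (k % 8), 12.0 + 2.0 * (k // 8), 0.0)
    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    coords[:, donor - 1] = 0.0
    coords[:, p_atom - 1, 2] = d_break
    coords[:, acceptor - 1, 2] = d_break + d_form
    if spec.noise.coords > 0:
        coords = coords + rng.normal(0, spec.noise.coords, coords.shape)

    frames = [Frame(frame_index=f, coords=coords[f], energy=float(e_noisy[f]))
              for f in range(spec.n_frames)]
    path = ReactionPath(atoms=atoms, frames=frames, xi=xi,
                        meta={"synthetic": spec.name or "unnamed"})

    # --- charges -----------------------------------------------------------
    q = np.zeros((spec.n_atoms, spec.n_frames))
    assigned: set[int] = set()
    for trend in spec.charge_trends:
        curve = trend.evaluate(xi)
        share = curve / len(trend.atom_indices)
        for a in trend.atom_indices:
            q[a - 1] = share
            assigned.add(a)
    background = [a for a in range(1, spec.n_atoms + 1) if a not in assigned]
    if background:
        remainder = spec.system_charge - q.sum(axis=0)
        for a in background:
            q[a - 1] = remainder / len(background)
    if spec.noise.charge > 0:
        q = q + rng.normal(0, spec.noise.charge, q.shape)
    charges = ChargeSeries(values=q)

    # --- ground truth ------------------------------------------------------
    stationary = []
    for t in spec.profile.targets:
        frame = int(np.argmin(np.abs(xi - t.xi)))
        stationary.append({"frame": frame, "xi": float(xi[frame]),
                           "kind": t.kind, "rel_energy": t.rel_energy})
    n_ts = sum(1 for t in spec.profile.targets if t.kind == "ts")
    pathway = "none" if n_ts == 0 else \
        ("concerted" if n_ts == 1 else "stepwise")
    implied_n: dict[int, float] = {}
    associativity = None
    if n_ts and break_pair in pairs and form_pair in pairs:
        for s in stationary:
            if s["kind"] != "ts":
                continue
            bb = b_clean[pairs.index(break_pair), s["frame"]]
            bf = b_clean[pairs.index(form_pair), s["frame"]]
            implied_n[s["frame"]] = float(np.sqrt(max(bb, 1e-12)
                                                  * max(bf, 1e-12)))
        barrier_frame = max(
            (s for s in stationary if s["kind"] == "ts"),
            key=lambda s: s["rel_energy"])["frame"]
        associativity = ("associative" if implied_n[barrier_frame] > 0.5
                         else "dissociative")
    frag_extrema = {
        t.name: (None if t.q_ext is None else (t.xi_ext, t.q_ext))
        for t in spec.charge_trends
    }
    proton_pairs = {canonical_pair(8, 9), canonical_pair(5, 9),
                    canonical_pair(3, 10), canonical_pair(10, 11),
                    canonical_pair(4, 10)}
    proton_mus = [e.mu for e in spec.events
                  if canonical_pair(*e.pair) in proton_pairs]
    span = None
    if len(proton_mus) >= 2:
        span = (max(proton_mus) - min(proton_mus)) / (xi[-1] - xi[0])
    truth = GroundTruth(
        event_midpoints=[(canonical_pair(*e.pair), e.mu)
                         for e in spec.events],
        stationary=stationary,
        fragment_extrema=frag_extrema,
        pathway_class=pathway,
        associativity=associativity,
        implied_n=implied_n,
        proton_transfer_span=span,
    )
    return path, bond_orders, charges, truth


# ---------------------------------------------------------------------------
# Frozen presets


def _base_assisted_like() -> SyntheticPathSpec:
    """Stepwise, dissociative path: two TSs flank a shallow metaphosphate
    intermediate (barrier 14.3, TS1-Int gap 1.1, TS2-Int gap 7.2, reaction
    energy 2.5 kcal/mol); the bridging P-O bond breaks before the new P-O
    bond forms, and two late proton transfers (Lys -> phosphate slightly
    before Ser -> Asp) sit near the second TS with a 0.05 midpoint offset."""
    return SyntheticPathSpec(
        n_atoms=61, n_frames=121, xi_range=(0.0, 1.0),
        events=(
            LogisticEventSpec((2, 1), 0.90, 0.002, mu=0.20, s=0.03),
            LogisticEventSpec((1, 3), 0.00, 0.90, mu=0.447, s=0.055),
            LogisticEventSpec((8, 9), 0.85, 0.05, mu=0.70, s=0.02),
            LogisticEventSpec((5, 9), 0.00, 0.80, mu=0.70, s=0.02),
            LogisticEventSpec((3, 10), 0.80, 0.05, mu=0.75, s=0.02),
            LogisticEventSpec((10, 11), 0.00, 0.75, mu=0.75, s=0.02),
        ),
        profile=ProfileSpec((
            StationaryTarget(0.00, 0.0, "reactant"),
            StationaryTarget(0.30, 8.2, "ts"),
            StationaryTarget(0.45, 7.1, "intermediate"),
            StationaryTarget(0.72, 14.3, "ts"),
            StationaryTarget(1.00, 2.5, "product"),
        )),
        charge_trends=(
            ChargeTrend("PO3", (1, 4, 5, 6), q_start=-0.98, q_end=-0.97,
                        q_ext=-1.03, xi_ext=0.45),
            ChargeTrend("MG", (7,), q_start=1.75, q_end=1.82),
            ChargeTrend("LYS129", (8, 9), q_start=0.62, q_end=0.25),
        ),
        distance_couplings={(1, 2): (1.73, 3.70), (1, 3): (1.73, 4.00)},
        noise=NoiseSpec(energy=0.05, bond_order=0.002, charge=0.0001),
        system_charge=-2.0, seed=20, name="base_assisted_like",
    )


def _substrate_assisted_like() -> SyntheticPathSpec:
    """Concerted, dissociative path with one high TS: the bridging P-O bond
    breaks early (asynchronously), the proton shuttles to a non-bridging
    oxygen right at the TS, and the entering P-O bond forms in a broad
    event trailing toward the product, leaving the TS loose (both P-O
    distances long)."""
    return SyntheticPathSpec(
        n_atoms=61, n_frames=121, xi_range=(0.0, 1.0),
        events=(
            LogisticEventSpec((2, 1), 0.90, 0.002, mu=0.30, s=0.045),
            LogisticEventSpec((1, 3), 0.00, 0.90, mu=0.62, s=0.07),
            LogisticEventSpec((3, 10), 0.85, 0.05, mu=0.55, s=0.04),
            LogisticEventSpec((4, 10), 0.00, 0.85, mu=0.55, s=0.04),
        ),
        profile=ProfileSpec((
            StationaryTarget(0.00, 0.0, "reactant"),
            StationaryTarget(0.55, 50.5, "ts"),
            StationaryTarget(1.00, 2.3, "product"),
        )),
        charge_trends=(
            ChargeTrend("PO3", (1, 4, 5, 6), q_start=-1.04, q_end=-0.98,
                        q_ext=-1.10, xi_ext=0.40),
            ChargeTrend("MG", (7,), q_start=1.78, q_end=1.82),
        ),
        distance_couplings={(1, 2): (1.73, 3.60), (1, 3): (1.73, 4.00)},
        noise=NoiseSpec(energy=0.05, bond_order=0.002, charge=0.0001),
        system_charge=-2.0, seed=21, name="substrate_assisted_like",
    )


def _associative_toy() -> SyntheticPathSpec:
    """Tight (associative) TS: both P-O partial bonds near 0.78 at the
    barrier, with the negative-charge buildup on the phosphoryl group that
    an associative mechanism implies."""
    return SyntheticPathSpec(
        n_atoms=61, n_frames=101, xi_range=(0.0, 1.0),
        events=(
            LogisticEventSpec((2, 1), 0.95, 0.02, mu=0.62, s=0.08),
            LogisticEventSpec((1, 3), 0.02, 0.95, mu=0.38, s=0.08),
        ),
        profile=ProfileSpec((
            StationaryTarget(0.00, 0.0, "reactant"),
            StationaryTarget(0.50, 20.0, "ts"),
            StationaryTarget(1.00, -1.0, "product"),
        )),
        charge_trends=(
            ChargeTrend("PO3", (1, 4, 5, 6), q_start=-1.20, q_end=-1.20,
                        q_ext=-1.45, xi_ext=0.50),
        ),
        distance_couplings={(1, 2): (1.73, 3.50), (1, 3): (1.73, 3.50)},
        noise=NoiseSpec(energy=0.02, bond_order=0.002, charge=0.0001),
        system_charge=-3.0, seed=22, name="associative_toy",
    )


def _barrierless_toy() -> SyntheticPathSpec:
    """Monotone downhill profile: no interior maximum, pathway 'none'."""
    return SyntheticPathSpec(
        n_atoms=61, n_frames=61, xi_range=(0.0, 1.0),
        events=(
            LogisticEventSpec((2, 1), 0.90, 0.10, mu=0.50, s=0.10),
            LogisticEventSpec((1, 3), 0.10, 0.90, mu=0.50, s=0.10),
        ),
        profile=ProfileSpec((
            StationaryTarget(0.00, 0.0, "reactant"),
            StationaryTarget(1.00, -3.0, "product"),
        )),
        charge_trends=(
            ChargeTrend("PO3", (1, 4, 5, 6), q_start=-1.10, q_end=-1.05),
        ),
        distance_couplings={(1, 2): (1.73, 3.50), (1, 3): (1.73, 3.50)},
        noise=NoiseSpec(),
        system_charge=-2.0, seed=23, name="barrierless_toy",
    )


_PRESETS = {
    "base_assisted_like": _base_assisted_like,
    "substrate_assisted_like": _substrate_assisted_like,
    "associative_toy": _associative_toy,
    "barrierless_toy": _barrierless_toy,
}


def preset(name: str) -> SyntheticPathSpec:
    """Return a frozen, documented synthetic-path spec by name."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None


def preset_names() -> list[str]:
    return sorted(_PRESETS)
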