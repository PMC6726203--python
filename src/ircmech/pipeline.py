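"""End-to-end orchestration: read the input bundle, run every requested
stage, and assemble one combined, deterministic report."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import __version__
from .charges import (
    FragmentDef,
    charge_event_correlation,
    charge_profile_report,
)
from .charges import _stationary_labels  # shared column naming
from .config import AnalysisConfig, AtomResolver
from .errors import ConsistencyError, ValidationError
from .geometry import (
    CoordinationSpec,
    DistanceSpec,
    HBondCriteria,
    coordination_profile,
    hbond_detect,
    key_distance_table,
)
from .io import (
    read_bond_orders,
    read_charges,
    read_pdb_atoms,
    read_xi_sidecar,
    read_xyz_path,
)
from .mechanism import classify_mechanism
from .model import canonical_pair
from .synchronicity import analyze_synchronicity

log = logging.getLogger("ircmech")


def run_full_analysis(config: AnalysisConfig,
                      with_curves: bool = False) -> dict:
    """Run mechanism + geometry + synchronicity + charges on one bundle.

    The combined report embeds the config hash and package version; it is
    byte-identical across reruns on identical inputs (no timestamps).
    Raises :class:`ConsistencyError` when channels disagree on frame counts
    or a requested stage lacks its input file.

    ``with_curves`` attaches a ``_curves`` section holding the per-frame
    series behind each stage (energy profile rows, bond-order derivatives,
    fragment charge series) for CSV export.
    """
    th = config.thresholds
    warnings: list[str] = []

    traj_path = config.resolve_path(config.trajectory)
    if traj_path is None or not traj_path.exists():
        raise ConsistencyError(f"trajectory file not found: {traj_path}")
    xi = None
    if config.xi:
        xi = read_xi_sidecar(Path(config.resolve_path(config.xi)).read_text())
    path = read_xyz_path(traj_path.read_text(), xi=xi,
                         energies_in_hartree=config.energies_in_hartree)
    log.info("trajectory: %d frames, %d atoms", path.n_frames, path.n_atoms)

    atoms = path.atoms
    if config.pdb:
        atoms = read_pdb_atoms(Path(config.resolve_path(config.pdb)).read_text())
        if len(atoms) != path.n_atoms:
            raise ConsistencyError(
                f"PDB has {len(atoms)} atoms, trajectory has {path.n_atoms}")
    resolve = AtomResolver(atoms)

    bond_orders = None
    if config.bond_orders:
        bo_path = config.resolve_path(config.bond_orders)
        if not bo_path.exists():
            raise ConsistencyError(f"bond-order file not found: {bo_path}")
        bond_orders = read_bond_orders(bo_path.read_text())
        if bond_orders.n_frames != path.n_frames:
            raise ConsistencyError(
                f"bond-order table has {bond_orders.n_frames} frames, "
                f"trajectory has {path.n_frames}")

    charges = None
    if config.fragments and not config.charges:
        raise ConsistencyError(
            "fragments configured but no charge file supplied")
    if config.charges:
        q_path = config.resolve_path(config.charges)
        if not q_path.exists():
            raise ConsistencyError(f"charge file not found: {q_path}")
        charges = read_charges(q_path.read_text(),
                               charge_sum_tol=th["charge_sum_tol"])
        if charges.n_frames != path.n_frames:
            raise ConsistencyError(
                f"charge table has {charges.n_frames} frames, trajectory "
                f"has {path.n_frames}")
        if charges.n_atoms != path.n_atoms:
            raise ConsistencyError(
                f"charge table has {charges.n_atoms} atoms, trajectory "
                f"has {path.n_atoms}")
        warnings.extend(charges.warnings)

    report: dict = {
        "version": __version__,
        "config_sha256": config.sha256(),
        "n_frames": path.n_frames,
        "n_atoms": path.n_atoms,
    }

    # --- mechanism ---------------------------------------------------------
    if not config.triad:
        raise ValidationError("config must define the reactive triad")
    donor = resolve(config.triad["donor"])
    p_atom = resolve(config.triad["p"])
    acceptor = resolve(config.triad["acceptor"])
    if len({donor, p_atom, acceptor}) != 3:
        raise ValidationError("triad indices must be distinct")
    mech = classify_mechanism(
        path, donor_o=donor, p=p_atom, acceptor_o=acceptor,
        bond_orders=bond_orders, D1=th["d1"],
        prominence_tol=th["prominence_tol"],
        smooth_window=th["smooth_window"])
    report["mechanism"] = mech.to_dict()
    point_names = _stationary_labels(mech.stationary_points)
    at_frames = {name: pt.frame_index
                 for name, pt in zip(point_names, mech.stationary_points)}
    log.info("mechanism: %s, barrier %s", mech.pathway_class, mech.barrier)

    # --- geometry ----------------------------------------------------------
    geometry_report: dict = {}
    if config.distances:
        specs = [DistanceSpec(label=d["label"], i=resolve(d["i"]),
                              j=resolve(d["j"]))
                 for d in config.distances]
        table = key_distance_table(path, specs, at_frames)
        geometry_report["key_distances"] = table.to_dict()
    if config.coordination:
        cspec = CoordinationSpec(
            metal=resolve(config.coordination["metal"]),
            ligands=tuple(resolve(l) for l in config.coordination["ligands"]),
            cutoff=float(config.coordination.get(
                "cutoff", th["coordination_cutoff"])))
        prof = coordination_profile(path, cspec)
        geometry_report["coordination"] = {
            "at_stationary": {
                name: {
                    "coordination_number": int(
                        prof.loc[f, "coordination_number"]),
                    "distances": {
                        str(lig): round(float(prof.loc[f, f"d_{lig}"]), 2)
                        for lig in cspec.ligands},
                }
                for name, f in at_frames.items()
            },
            "cutoff": cspec.cutoff,
        }
    if config.hbonds:
        crit = HBondCriteria(
            d_da_max=float(config.hbonds.get("d_da_max",
                                             th["hbond_d_da_max"])),
            angle_min=float(config.hbonds.get("angle_min",
                                              th["hbond_angle_min"])))
        donors = [(resolve(d), resolve(h)) for d, h in config.hbonds["donors"]]
        acceptors = [resolve(a) for a in config.hbonds["acceptors"]]
        hb = {}
        for name, f in at_frames.items():
            contacts, warns = hbond_detect(path.frames[f], donors, acceptors,
                                           crit)
            warnings.extend(f"{name}: {w}" for w in warns)
            hb[name] = [
                {"donor": d, "h": h, "acceptor": a,
                 "d_da": round(dd, 3), "angle": round(ang, 1)}
                for d, h, a, dd, ang in contacts]
        geometry_report["hbonds"] = hb
    if geometry_report:
        report["geometry"] = geometry_report

    # --- synchronicity -----------------------------------------------------
    if bond_orders is not None:
        crossing_pairs = [
            (canonical_pair(resolve(a[0]), resolve(a[1])),
             canonical_pair(resolve(b[0]), resolve(b[1])))
            for a, b in config.crossings]
        smooth = None
        if th["smooth_window"] > 1:
            smooth = ("moving_poly", int(th["smooth_window"]), 2)
        sync = analyze_synchronicity(
            bond_orders, path.xi,
            min_peak_frac=th["min_peak_frac"],
            min_net_change=th["min_net_change"],
            smooth=smooth, crossing_pairs=crossing_pairs)
        report["synchronicity"] = sync.to_dict()
        log.info("synchronicity: %d events", len(sync.events))
    else:
        sync = None

    # --- charges -----------------------------------------------------------
    if charges is not None and config.fragments:
        frags = [FragmentDef(name=f["name"],
                             atom_indices=tuple(resolve(a)
                                                for a in f["atoms"]),
                             allow_overlap=bool(f.get("allow_overlap",
                                                      False)))
                 for f in config.fragments]
        prof = charge_profile_report(charges, frags, mech.stationary_points,
                                     xi=path.xi)
        charge_report = prof.to_dict()
        if sync is not None and sync.events:
            corr, warns = charge_event_correlation(
                charges, frags, sync.events, window=th["event_window"],
                xi=path.xi)
            warnings.extend(warns)
            charge_report["event_correlation"] = corr
        report["charges"] = charge_report

    report["warnings"] = warnings

    if with_curves:
        curves: dict = {"xi": [float(x) for x in path.xi]}
        curves["profile"] = fig3_style_rows(path, mech)
        if bond_orders is not None:
            smooth = None
            if th["smooth_window"] > 1:
                smooth = ("moving_poly", int(th["smooth_window"]), 2)
            from .synchronicity import bond_order_derivative
            deriv = bond_order_derivative(bond_orders, path.xi,
                                          smooth=smooth)
            curves["derivatives"] = {
                f"{i}-{j}": [float(v) for v in deriv[k]]
                for k, (i, j) in enumerate(bond_orders.pairs)}
        if charges is not None and config.fragments:
            curves["fragment_charges"] = {
                name: [float(v) for v in q]
                for name, q in prof.values.items()}
        report["_curves"] = curves
    return report


def fig3_style_rows(path, mech_report) -> list[dict]:
    """Flat (frame, xi, rel_energy, label) rows for CSV export."""
    energies = path.energies
    e0 = energies[0]
    labels = {p.frame_index: p.kind for p in mech_report.stationary_points}
    return [
        {"frame": f, "xi": float(path.xi[f]),
         "rel_energy": float(energies[f] - e0),
         "label": labels.get(f, "")}
        for f in range(path.n_frames)
    ]
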