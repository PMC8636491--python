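"""Non-bonded interaction detection and per-pair persistence tables.

Three interaction classes are detected per frame and summarized as the
fraction of frames in which they occur (persistence):

* hydrogen bonds — donor-acceptor distance <= 0.30 nm AND the angle between
  the D->H and D->A vectors <= 25 deg (the VMD convention for the cone
  criterion);
* salt bridges — minimum distance between anionic side-chain oxygens
  (Asp/Glu carboxylates, C-terminal OXT) and cationic side-chain nitrogens
  (Lys/Arg, optionally His) <= 0.40 nm;
* hydrophobic contacts — minimum distance between side-chain carbons of two
  apolar residues <= 0.45 nm (for Tyr only the aromatic ring carbons count).

The hydrogen-bond and salt-bridge cutoffs that matter scientifically are
config keys, not constants; the chemistry table (which elements may donate
or accept) ships as editable YAML data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial.distance import cdist

from .trajectory_io import DomainMap, Trajectory

HBOND_DISTANCE_MAX = 0.30   # nm, donor-acceptor
HBOND_ANGLE_MAX = 25.0      # degrees, D->H vs D->A deviation
SALT_BRIDGE_MAX = 0.40      # nm, charged-group heavy atoms
HYDROPHOBIC_MAX = 0.45      # nm, side-chain carbons

ANIONIC_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
CATIONIC_ATOMS = {
    "LYS": {"NZ"},
    "ARG": {"NE", "NH1", "NH2"},
}
HIS_CATIONIC = {"HIS": {"ND1", "NE2"}}

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
TYR_RING = {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class HBond:
    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    frame: int
    distance: float  # nm, D-A
    angle: float     # degrees, D->H vs D->A


@dataclass(frozen=True)
class InteractionRecord:
    kind: str  # hbond | salt | hydrophobic
    residue_i: int  # topology residue index, i < j
    residue_j: int
    persistence: float


def load_hbond_chemistry(path: str | Path | None = None) -> dict:
    """Load the donor/acceptor chemistry rules (package data by default)."""
    if path is None:
        ref = resources.files("abdyn") / "data" / "hbond_chemistry.yaml"
        return yaml.safe_load(ref.read_text())
    with open(path) as fh:
        return yaml.safe_load(fh)


def _find_donor_triples(
    traj: Trajectory, chemistry: dict,
) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) pairs, resolved geometrically in frame 0."""
    top = traj.topology
    donor_elems = {str(e).upper() for e in chemistry["donor_elements"]}
    dh_max = float(chemistry["dh_bond_max"])
    h_idx = [i for i, a in enumerate(top.atoms) if a.element.upper() == "H"]
    d_idx = [i for i, a in enumerate(top.atoms) if a.element.upper() in donor_elems]
    if not h_idx:
        raise ValueError(
            "no hydrogens in topology: hydrogen-bond detection needs explicit "
            "hydrogens (heavy-atom-only mode is not supported)"
        )
    coords = traj.coords[0]
    triples = []
    d_arr = np.array(d_idx)
    dists = cdist(coords[h_idx], coords[d_idx])
    for k, h in enumerate(h_idx):
        j = int(np.argmin(dists[k]))
        if dists[k, j] <= dh_max:
            triples.append((int(d_arr[j]), h))
    return triples


def _acceptor_atoms(traj: Trajectory, chemistry: dict) -> np.ndarray:
    top = traj.topology
    elems = {str(e).upper() for e in chemistry["acceptor_elements"]}
    excl = set(chemistry.get("acceptor_exclude_names") or [])
    return np.array(
        [
            i
            for i, a in enumerate(top.atoms)
            if a.element.upper() in elems and a.atom_name not in excl
        ],
        dtype=int,
    )


def hydrogen_bonds(
    traj: Trajectory,
    d_max: float = HBOND_DISTANCE_MAX,
    angle_max: float = HBOND_ANGLE_MAX,
    chemistry: dict | None = None,
) -> tuple[list[HBond], np.ndarray]:
    """Per-frame hydrogen bonds and the per-frame bond count.

    A bond exists in a frame iff the donor-acceptor distance is <= d_max and
    the angle between the D->H and D->A vectors is <= angle_max.  Donor and
    acceptor must belong to different residues.
    """
    if chemistry is None:
        chemistry = load_hbond_chemistry()
    top = traj.topology
    res_of = top.atom_residue_indices()
    triples = _find_donor_triples(traj, chemistry)
    acceptors = _acceptor_atoms(traj, chemistry)

    records: list[HBond] = []
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        for d, h in triples:
            da = coords[acceptors] - coords[d]
            dist = np.linalg.norm(da, axis=1)
            dh = coords[h] - coords[d]
            dh_norm = np.linalg.norm(dh)
            cand = np.flatnonzero(
                (dist <= d_max) & (res_of[acceptors] != res_of[d]) & (dist > 0)
            )
            for c in cand:
                a = acceptors[c]
                cosang = np.dot(dh, da[c]) / (dh_norm * dist[c])
                ang = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
                if ang <= angle_max:
                    records.append(
                        HBond(d, h, int(a), f, float(dist[c]), ang)
                    )
                    counts[f] += 1
    return records, counts


def _pair_persistence_min_dist(
    traj: Trajectory,
    atoms_i: dict[int, np.ndarray],
    atoms_j: dict[int, np.ndarray],
    d_max: float,
) -> list[InteractionRecord]:
    """Persistence of min-distance contacts between two residue atom groups."""
    out = []
    for ri, ai in atoms_i.items():
        for rj, aj in atoms_j.items():
            if ri == rj:
                continue
            i, j = min(ri, rj), max(ri, rj)
            hits = 0
            for f in range(traj.n_frames):
                d = cdist(traj.coords[f][ai], traj.coords[f][aj]).min()
                if d <= d_max:
                    hits += 1
            if hits:
                out.append((i, j, hits / traj.n_frames))
    # merge duplicate (i, j) coming from both orientations
    merged: dict[tuple[int, int], float] = {}
    for i, j, p in out:
        merged[(i, j)] = max(merged.get((i, j), 0.0), p)
    return [(i, j, p) for (i, j), p in sorted(merged.items())]


def salt_bridges(
    traj: Trajectory,
    d_max: float = SALT_BRIDGE_MAX,
    include_his: bool = True,
) -> list[InteractionRecord]:
    """Salt-bridge records with persistence over the trajectory.

    A bridge exists in a frame iff the minimum distance between an anionic
    side-chain oxygen and a cationic side-chain nitrogen is <= d_max.
    Histidine is included as potentially cationic by default (protonation
    unknown); disable with include_his=False.
    """
    top = traj.topology
    cationic = dict(CATIONIC_ATOMS)
    if include_his:
        cationic.update(HIS_CATIONIC)
    res_of = top.atom_residue_indices()
    anions: dict[int, list[int]] = {}
    cations: dict[int, list[int]] = {}
    for i, a in enumerate(top.atoms):
        names = ANIONIC_ATOMS.get(a.residue_name)
        if (names and a.atom_name in names) or a.atom_name == "OXT":
            anions.setdefault(res_of[i], []).append(i)
        names = cationic.get(a.residue_name)
        if names and a.atom_name in names:
            cations.setdefault(res_of[i], []).append(i)
    pairs = _pair_persistence_min_dist(
        traj,
        {k: np.array(v) for k, v in anions.items()},
        {k: np.array(v) for k, v in cations.items()},
        d_max,
    )
    return [InteractionRecord("salt", i, j, p) for i, j, p in pairs]


def hydrophobic_contacts(
    traj: Trajectory, d_max: float = HYDROPHOBIC_MAX,
) -> list[InteractionRecord]:
    """Apolar side-chain carbon contacts with persistence.

    Only residues in the apolar set participate; for tyrosine only the
    aromatic ring carbons are counted.  Polar residues never appear.
    """
    top = traj.topology
    res_of = top.atom_residue_indices()
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(top.atoms):
        if a.residue_name not in APOLAR_RESIDUES:
            continue
        if a.element.upper() != "C" or a.atom_name in BACKBONE_NAMES:
            continue
        if a.residue_name == "TYR" and a.atom_name not in TYR_RING:
            continue
        groups.setdefault(res_of[i], []).append(i)
    arr = {k: np.array(v) for k, v in groups.items()}
    pairs = _pair_persistence_min_dist(traj, arr, arr, d_max)
    return [InteractionRecord("hydrophobic", i, j, p) for i, j, p in pairs]


def hbond_records_to_interactions(
    records: list[HBond], traj: Trajectory,
) -> list[InteractionRecord]:
    """Collapse per-frame H-bond events into residue-pair persistence."""
    res_of = traj.topology.atom_residue_indices()
    frames_by_pair: dict[tuple[int, int], set[int]] = {}
    for r in records:
        i, j = sorted((int(res_of[r.donor_atom]), int(res_of[r.acceptor_atom])))
        frames_by_pair.setdefault((i, j), set()).add(r.frame)
    return [
        InteractionRecord("hbond", i, j, len(fr) / traj.n_frames)
        for (i, j), fr in sorted(frames_by_pair.items())
    ]


def interdomain_table(
    records: list[InteractionRecord],
    traj: Trajectory,
    dmap: DomainMap,
    persistence_min: float = 0.0,
) -> pd.DataFrame:
    """Inter-domain interaction table sorted by persistence (descending).

    Intra-domain rows and rows below the persistence threshold are dropped;
    residues not covered by the domain map are skipped with a warning column
    in the returned frame's attrs.
    """
    top = traj.topology
    rows = []
    skipped = []
    for rec in records:
        ci, ni, _ = top.residues[rec.residue_i]
        cj, nj, _ = top.residues[rec.residue_j]
        di = dmap.domain_of(ci, ni)
        dj = dmap.domain_of(cj, nj)
        if di is None or dj is None:
            skipped.append((ci, ni) if di is None else (cj, nj))
            continue
        if di == dj:
            continue
        if rec.persistence < persistence_min:
            continue
        # canonical order by (chain, residue)
        if (cj, nj) < (ci, ni):
            ci, ni, di, cj, nj, dj = cj, nj, dj, ci, ni, di
        rows.append(
            {
                "type": rec.kind,
                "chain_i": ci, "res_i": ni, "domain_i": di,
                "chain_j": cj, "res_j": nj, "domain_j": dj,
                "persistence": rec.persistence,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "type", "chain_i", "res_i", "domain_i",
            "chain_j", "res_j", "domain_j", "persistence",
        ],
    )
    df = df.sort_values(
        ["persistence", "chain_i", "res_i"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df.attrs["skipped_residues"] = sorted(set(skipped))
    return df
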