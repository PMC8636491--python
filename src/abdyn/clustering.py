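"""Conformational clustering and per-cluster structural statistics.

Frames are compared by C-alpha RMSD after optimal rigid superposition
(Kabsch), the full pairwise matrix is clustered by average linkage (UPGMA),
and the tree is cut at a distance threshold (1.2 nm for full-length IgG
ensembles).  Cluster indices are conventionally reassigned by increasing
mean radius of gyration so that cluster 0 is the most compact arrangement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation

from .trajectory_io import Topology, Trajectory

# Standard atomic masses (u) for radius-of-gyration weighting.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}

# Average residue masses (u), used when only C-alpha atoms are present and the
# residue mass is collapsed onto it.
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09, "CYS": 103.14,
    "GLN": 128.13, "GLU": 129.12, "GLY": 57.05, "HIS": 137.14, "ILE": 113.16,
    "LEU": 113.16, "LYS": 128.17, "MET": 131.19, "PHE": 147.18, "PRO": 97.12,
    "SER": 87.08, "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}
DEFAULT_RESIDUE_MASS = 110.0


@dataclass
class RMSDMatrix:
    """Symmetric F x F matrix of pairwise superposed RMSD values (nm)."""

    values: np.ndarray
    atom_subset: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("RMSD matrix must be square")
        self.values = v


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    threshold: float
    dendrogram: np.ndarray  # scipy linkage matrix

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass
class ClusterSummary:
    cluster_id: int
    population_fraction: float
    rg_mean: float
    rg_sd: float
    medoid_frame: int
    rmsf: np.ndarray = field(repr=False, default=None)


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray, weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of Q onto P.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) and ``t``
    a translation such that ``Q @ R.T + t`` minimizes the RMSD to ``P`` over
    all rigid transforms.  Mirror images are never matched: only proper
    rotations are considered.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching n x 3 arrays")
    n = P.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    wsum = w.sum()
    pc = (w[:, None] * P).sum(axis=0) / wsum
    qc = (w[:, None] * Q).sum(axis=0) / wsum
    P0, Q0 = P - pc, Q - qc
    with warnings.catch_warnings():
        # Collinear input: the rotation is not unique; best effort is fine.
        warnings.simplefilter("ignore", UserWarning)
        rot, rssd = Rotation.align_vectors(P0, Q0, weights=w)
    R = rot.as_matrix()
    rmsd = rssd / np.sqrt(wsum)
    t = pc - R @ qc
    return R, t, float(rmsd)


def pairwise_rmsd(traj: Trajectory, subset: np.ndarray) -> RMSDMatrix:
    """All-pairs superposed RMSD on an atom subset (batched Kabsch).

    Uses the closed form rmsd^2 = (|P|^2 + |Q|^2 - 2 tr(S*)) / n where S* is
    the proper-rotation-corrected singular-value sum of the 3x3 correlation
    matrix; all pair matrices are SVD-decomposed in one batched call.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("atom subset must be non-empty")
    X = traj.coords[:, subset, :]
    F, n, _ = X.shape
    Xc = X - X.mean(axis=1, keepdims=True)
    sq = np.einsum("fij,fij->f", Xc, Xc)

    iu, ju = np.triu_indices(F, k=1)
    H = np.einsum("pki,pkj->pij", Xc[iu], Xc[ju])  # (n_pairs, 3, 3)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U) * np.linalg.det(Vt)
    # Reflection correction: flip the smallest singular value when det < 0.
    S_corr = S.copy()
    S_corr[:, -1] *= np.sign(det)
    trace = S_corr.sum(axis=1)

    msd = (sq[iu] + sq[ju] - 2.0 * trace) / n
    rmsd = np.sqrt(np.clip(msd, 0.0, None))
    M = np.zeros((F, F))
    M[iu, ju] = rmsd
    M[ju, iu] = rmsd
    return RMSDMatrix(values=M, atom_subset=subset)


def upgma_cut(matrix: RMSDMatrix, threshold: float) -> ClusterAssignment:
    """Average-linkage (UPGMA) clustering with a distance-threshold cut.

    All merges with height strictly greater than the threshold are removed;
    a merge exactly at the threshold stays merged.  Labels are contiguous
    from 0 in order of first frame occurrence.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    D = matrix.values
    F = D.shape[0]
    if F == 1:
        return ClusterAssignment(np.zeros(1, dtype=int), threshold, np.empty((0, 4)))
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=threshold, criterion="distance")
    labels = _relabel_by_first_occurrence(raw)
    return ClusterAssignment(labels, threshold, Z)


def _relabel_by_first_occurrence(raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in mapping:
            mapping[r] = len(mapping)
        out[i] = mapping[r]
    return out


def atom_masses(top: Topology, mass_mode: str = "element") -> np.ndarray:
    """Per-atom masses: by element, unit, or residue mass collapsed onto CA."""
    if mass_mode == "unit":
        return np.ones(top.n_atoms)
    if mass_mode == "element":
        return np.array(
            [ATOMIC_MASSES.get(a.element.upper(), 12.011) for a in top.atoms]
        )
    if mass_mode == "residue_on_ca":
        return np.array(
            [
                RESIDUE_MASSES.get(a.residue_name, DEFAULT_RESIDUE_MASS)
                for a in top.atoms
            ]
        )
    raise ValueError(f"unknown mass mode {mass_mode!r}")


def radius_of_gyration(
    frame: np.ndarray, subset: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> float:
    """Mass-weighted radius of gyration of one frame (nm)."""
    coords = np.asarray(frame, dtype=float)
    if subset is not None:
        coords = coords[np.asarray(subset, dtype=int)]
        if masses is not None:
            masses = np.asarray(masses)[np.asarray(subset, dtype=int)]
    if coords.shape[0] == 0:
        raise ValueError("empty atom subset")
    m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
    if m.sum() <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / m.sum()))


def relabel_by_rg(
    traj: Trajectory, assignment: ClusterAssignment,
    masses: np.ndarray | None = None,
) -> ClusterAssignment:
    """Reassign cluster ids by increasing mean radius of gyration.

    Ties (identical mean Rg) are broken by decreasing population.
    """
    labels = assignment.labels
    ids = np.unique(labels)
    rg = np.array([radius_of_gyration(f, masses=masses) for f in traj.coords])
    order = sorted(
        ids,
        key=lambda c: (round(float(rg[labels == c].mean()), 12), -(labels == c).sum()),
    )
    mapping = {old: new for new, old in enumerate(order)}
    new_labels = np.array([mapping[l] for l in labels], dtype=int)
    return ClusterAssignment(new_labels, assignment.threshold, assignment.dendrogram)


def medoid_frame(rmsd: RMSDMatrix, members: np.ndarray) -> int:
    """Member frame minimizing summed RMSD to the other members."""
    sub = rmsd.values[np.ix_(members, members)]
    return int(members[np.argmin(sub.sum(axis=1))])


def cluster_summary(
    traj: Trajectory,
    assignment: ClusterAssignment,
    rmsd: RMSDMatrix | None = None,
    mass_mode: str = "element",
) -> list[ClusterSummary]:
    """Population, Rg statistics, medoid and per-residue RMSF per cluster."""
    top = traj.topology
    masses = atom_masses(top, mass_mode)
    if rmsd is None:
        ca = top.ca_indices()
        rmsd = pairwise_rmsd(traj, ca if ca.size else np.arange(top.n_atoms))
    rg = np.array(
        [radius_of_gyration(f, masses=masses) for f in traj.coords]
    )
    out = []
    F = traj.n_frames
    for cid in range(assignment.n_clusters):
        members = assignment.members(cid)
        med = medoid_frame(rmsd, members)
        prof = rmsf_to_reference(traj, members, med, subset=rmsd.atom_subset)
        out.append(
            ClusterSummary(
                cluster_id=cid,
                population_fraction=len(members) / F,
                rg_mean=float(rg[members].mean()),
                rg_sd=float(rg[members].std()),
                medoid_frame=med,
                rmsf=prof,
            )
        )
    return out


def align_frames(
    traj_coords: np.ndarray, reference: np.ndarray, subset: np.ndarray,
) -> np.ndarray:
    """Superpose every frame onto a reference using the subset atoms."""
    out = np.empty_like(traj_coords)
    for f in range(traj_coords.shape[0]):
        R, t, _ = kabsch_superpose(reference[subset], traj_coords[f][subset])
        out[f] = traj_coords[f] @ R.T + t
    return out


def rmsf_to_reference(
    traj: Trajectory, members: np.ndarray, reference_frame: int,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-subset-atom RMSF of the member frames after alignment."""
    if subset is None:
        subset = traj.topology.ca_indices()
    subset = np.asarray(subset, dtype=int)
    coords = align_frames(
        traj.coords[members], traj.coords[reference_frame], subset
    )[:, subset, :]
    mean = coords.mean(axis=0)
    return np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))


def essential_dynamics(
    traj: Trajectory, subset: np.ndarray, n_components: int = 3,
    align: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict[int, tuple[int, int]]]:
    """Covariance eigen-analysis of aligned positions (essential dynamics).

    Frames are superposed onto their mean structure, the 3n x 3n positional
    covariance is diagonalized, and for each of the leading components the
    frames with extreme projections are reported.

    Returns (eigenvalues descending, eigenvectors as columns,
    {component: (min_frame, max_frame)}).
    """
    if traj.n_frames <= 1:
        raise ValueError("essential dynamics requires more than one frame")
    subset = np.asarray(subset, dtype=int)
    coords = traj.coords
    if align:
        # Two alignment passes: to frame 0, then to the running mean.
        aligned = align_frames(coords, coords[0], subset)
        mean = aligned.mean(axis=0)
        aligned = align_frames(aligned, mean, subset)
    else:
        aligned = coords

    X = aligned[:, subset, :].reshape(traj.n_frames, -1)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (traj.n_frames - 1)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]

    projections = Xc @ V[:, :n_components]
    extremes = {
        k: (int(np.argmin(projections[:, k])), int(np.argmax(projections[:, k])))
        for k in range(min(n_components, V.shape[1]))
    }
    return w, V, extremes
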