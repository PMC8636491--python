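"""Synthetic ensembles with known ground truth.

Every analysis stage in this package has a generator here that emulates the
statistical structure the stage assumes, with the planted quantity recorded:

* rigid multi-state mixtures with Gaussian positional noise (clustering),
* stationary Gaussian fluctuations with a prescribed inter-residue
  correlation (mutual information / generalized correlation),
* backbone chains built from prescribed phi/psi series (dihedral and
  angular-dispersion analyses),
* residue pairs with prescribed contact persistence and planted
  hydrogen-bond geometry (network and interaction analyses).

The noise model is isotropic i.i.d. Gaussian per coordinate — the minimal
stand-in for MD fluctuations that gives every estimator an analytic target.
All generators are deterministic functions of their arguments and a seed;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory_io import AtomRecord, Topology, Trajectory

# Ideal backbone geometry (Angstrom-free: everything in nm, angles in deg).
BOND_C_N = 0.1329
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_O = 0.1231
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.8
OMEGA_TRANS = 180.0  # peptide bond held trans


@dataclass
class SyntheticSpec:
    """Parameters of a multi-state synthetic ensemble."""

    n_domains: int = 4
    residues_per_domain: int = 10
    k_states: int = 3
    state_weights: np.ndarray | None = None
    noise_sigma: float = 0.05  # nm
    n_frames: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_states < 1:
            raise ValueError("k_states must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.state_weights is None:
            self.state_weights = np.full(self.k_states, 1.0 / self.k_states)
        self.state_weights = np.asarray(self.state_weights, dtype=float)
        if len(self.state_weights) != self.k_states:
            raise ValueError("state_weights length must equal k_states")
        if not np.isclose(self.state_weights.sum(), 1.0):
            raise ValueError("state_weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted quantities recorded alongside a synthetic trajectory."""

    frame_state_labels: np.ndarray | None = None
    planted_corr: dict[tuple[int, int], float] = field(default_factory=dict)
    planted_contacts: dict[tuple[int, int], float] = field(default_factory=dict)
    dihedral_params: dict[int, tuple[float, float]] = field(default_factory=dict)


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(axis, axis)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: position d given bond c-d, angle b-c-d, torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            -bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ca_topology(
    n_residues: int,
    chain_id: str = "A",
    residue_name: str = "ALA",
    start_index: int = 1,
) -> Topology:
    """C-alpha-only chain topology for coarse synthetic ensembles."""
    atoms = [
        AtomRecord("CA", "C", start_index + i, residue_name, chain_id)
        for i in range(n_residues)
    ]
    return Topology(atoms)


def make_backbone_topology(
    n_residues: int, chain_id: str = "A", residue_name: str = "ALA",
) -> Topology:
    atoms = []
    for i in range(n_residues):
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(AtomRecord(name, elem, i + 1, residue_name, chain_id))
    return Topology(atoms)


def build_backbone_from_dihedrals(
    phi: np.ndarray, psi: np.ndarray, chain_id: str = "A",
) -> Trajectory:
    """Build a single-frame backbone (N, CA, C, O per residue) from phi/psi.

    Bond lengths/angles are ideal and the peptide bond is trans.  ``phi[0]``
    and ``psi[-1]`` do not affect the geometry of interior dihedrals (they
    are undefined for a chain of n residues); ``psi[-1]`` only orients the
    final carbonyl oxygen.  Recomputing phi/psi from the built coordinates
    returns the inputs to numerical precision.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape:
        raise ValueError("phi and psi must have equal length")
    n = len(phi)
    if n < 2:
        raise ValueError("need at least 2 residues to build a backbone")

    coords = np.zeros((4 * n, 3))
    # First residue: N at origin, CA along +x, C placed in the xy plane.
    N0 = np.array([0.0, 0.0, 0.0])
    CA0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    C0 = CA0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords[0], coords[1], coords[2] = N0, CA0, C0

    prev_N, prev_CA, prev_C = N0, CA0, C0
    for i in range(1, n):
        Ni = _place_atom(prev_N, prev_CA, prev_C, BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CAi = _place_atom(prev_CA, prev_C, Ni, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
        Ci = _place_atom(prev_C, Ni, CAi, BOND_CA_C, ANGLE_N_CA_C, phi[i])
        # Carbonyl O of the *previous* residue sits opposite the next N:
        # dihedral N-CA-C-O equals psi + 180.
        coords[4 * (i - 1) + 3] = _place_atom(
            prev_N, prev_CA, prev_C, BOND_C_O, ANGLE_CA_C_O,
            _wrap_degrees(psi[i - 1] + 180.0),
        )
        coords[4 * i + 0], coords[4 * i + 1], coords[4 * i + 2] = Ni, CAi, Ci
        prev_N, prev_CA, prev_C = Ni, CAi, Ci
    # Last O: use psi[-1] + 180 about N-CA-C to keep it trans to a virtual N.
    coords[4 * (n - 1) + 3] = _place_atom(
        prev_N, prev_CA, prev_C, BOND_C_O, ANGLE_CA_C_O,
        _wrap_degrees(psi[-1] + 180.0),
    )

    top = make_backbone_topology(n, chain_id=chain_id)
    return Trajectory(top, coords[None, :, :])


def _wrap_degrees(a):
    """Wrap angles into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def make_reference_states(
    spec: SyntheticSpec, separation: float = 2.0,
) -> tuple[Topology, np.ndarray]:
    """Build k rigid CA-only conformations of a multi-domain chain.

    Domains are compact helical-pitch coils; the states differ by rigid-body
    rotations of alternate domains about the inter-domain axis, so the
    inter-state RMSD is large and tunable via ``separation`` (nm scale of
    domain displacement), emulating open/closed antibody arrangements.
    """
    n_res = spec.n_domains * spec.residues_per_domain
    top = make_ca_topology(n_res)
    base = np.zeros((n_res, 3))
    for d in range(spec.n_domains):
        for r in range(spec.residues_per_domain):
            i = d * spec.residues_per_domain + r
            theta = 2.0 * np.pi * r / 3.6
            base[i] = (
                d * 2.5 + 0.23 * np.cos(theta),
                0.23 * np.sin(theta),
                0.15 * r,
            )
    states = np.zeros((spec.k_states, n_res, 3))
    for k in range(spec.k_states):
        conf = base.copy()
        for d in range(1, spec.n_domains, 2):
            sl = slice(d * spec.residues_per_domain, (d + 1) * spec.residues_per_domain)
            pivot = conf[sl].mean(axis=0)
            R = _rotation_matrix([0, 0, 1], k * 2.0 * np.pi / max(spec.k_states, 2))
            conf[sl] = (conf[sl] - pivot) @ R.T + pivot + k * np.array(
                [0.0, separation, 0.0]
            )
        states[k] = conf
    return top, states


def sample_multistate_trajectory(
    spec: SyntheticSpec,
    reference_states: np.ndarray | None = None,
    topology: Topology | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Mixture of k rigid conformations plus i.i.d. Gaussian noise.

    Each frame is one reference conformation (chosen i.i.d. with the state
    weights) plus isotropic Gaussian noise of sd ``noise_sigma`` per
    coordinate.  Frame labels are recorded in the ground truth.
    """
    if reference_states is None:
        topology, reference_states = make_reference_states(spec)
    if topology is None:
        topology = make_ca_topology(reference_states.shape[1])
    reference_states = np.asarray(reference_states, dtype=float)
    if reference_states.shape[0] != spec.k_states:
        raise ValueError(
            f"{reference_states.shape[0]} reference states but k_states="
            f"{spec.k_states}"
        )
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.k_states, size=spec.n_frames, p=spec.state_weights)
    noise = rng.normal(0.0, spec.noise_sigma, size=(spec.n_frames,) + reference_states.shape[1:])
    coords = reference_states[labels] + noise
    return Trajectory(topology, coords), GroundTruth(frame_state_labels=labels)


def sample_correlated_displacements(
    base: np.ndarray,
    corr: np.ndarray,
    n_frames: int,
    sigma: float = 0.1,
    seed: int = 0,
    topology: Topology | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Gaussian CA fluctuations with a prescribed residue correlation matrix.

    The same correlation is applied to x, y and z independently, so the
    per-coordinate correlation between two residues equals the planted
    entry.  ``corr`` must be a valid (positive semi-definite) correlation
    matrix over residues.
    """
    base = np.asarray(base, dtype=float)
    corr = np.asarray(corr, dtype=float)
    n_res = base.shape[0]
    if corr.shape != (n_res, n_res):
        raise ValueError("corr must be R x R for R residues")
    if not np.allclose(corr, corr.T):
        raise ValueError("corr must be symmetric")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError("corr is not positive semi-definite")
    # Eigen square root tolerates semi-definite matrices (Cholesky does not).
    w, V = np.linalg.eigh(corr)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    rng = np.random.default_rng(seed)
    disp = np.empty((n_frames, n_res, 3))
    for axis in range(3):
        z = rng.standard_normal((n_frames, n_res))
        disp[:, :, axis] = sigma * (z @ L.T)
    coords = base[None] + disp
    if topology is None:
        topology = make_ca_topology(n_res)
    planted = {
        (i, j): float(corr[i, j])
        for i in range(n_res)
        for j in range(i + 1, n_res)
        if corr[i, j] != 0.0
    }
    return Trajectory(topology, coords), GroundTruth(planted_corr=planted)


def sample_discrete_joint_series(
    joint_pmf: np.ndarray, n: int, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw i.i.d. integer pairs from a joint pmf; return analytic MI (nats).

    The analytic value is direct summation of p(x,y) log[p(x,y)/(p(x)p(y))].
    """
    pmf = np.asarray(joint_pmf, dtype=float)
    if pmf.ndim != 2 or np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
        raise ValueError("joint_pmf must be a 2-D pmf with entries summing to 1")
    rng = np.random.default_rng(seed)
    flat = pmf.ravel()
    draws = rng.choice(len(flat), size=n, p=flat)
    x, y = np.unravel_index(draws, pmf.shape)

    px = pmf.sum(axis=1)
    py = pmf.sum(axis=0)
    mask = pmf > 0
    mi = float(
        np.sum(pmf[mask] * np.log(pmf[mask] / np.outer(px, py)[mask]))
    )
    return x.astype(int), y.astype(int), mi


def sample_vonmises_series(
    mu: float, kappa: float, n: int, seed: int = 0,
) -> np.ndarray:
    """I.i.d. von Mises angles in degrees, wrapped to (-180, 180].

    kappa = 0 degenerates to the uniform distribution on the circle.
    """
    if kappa < 0 or not np.isfinite(kappa):
        raise ValueError("kappa must be finite and >= 0")
    rng = np.random.default_rng(seed)
    if kappa == 0:
        theta = rng.uniform(-np.pi, np.pi, size=n)
    else:
        theta = rng.vonmises(np.deg2rad(mu), kappa, size=n)
    return _wrap_degrees(np.rad2deg(theta))


def sample_contact_trajectory(
    n_residues: int,
    planted_contacts: dict[tuple[int, int], float],
    n_frames: int,
    contact_distance: float = 0.40,
    apart_distance: float = 2.0,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth]:
    """CA-only ensemble in which chosen residue pairs touch a chosen fraction
    of frames.

    Residues sit on a sparse grid (spacing ``apart_distance`` nm, far beyond
    any contact cutoff); for each planted pair (i, j) with persistence p, the
    j-th residue is moved to ``contact_distance`` nm from i in a random
    subset of round(p * F) frames.  Each residue may appear in at most one
    planted pair so plants cannot interfere.
    """
    seen: set[int] = set()
    for (i, j), p in planted_contacts.items():
        if not (0 <= i < n_residues and 0 <= j < n_residues) or i == j:
            raise ValueError(f"invalid pair {(i, j)}")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"persistence {p} outside [0, 1]")
        if i in seen or j in seen:
            raise ValueError("each residue may appear in at most one planted pair")
        seen.update((i, j))

    rng = np.random.default_rng(seed)
    side = int(np.ceil(n_residues ** (1 / 3)))
    grid = np.array(
        [
            (a * apart_distance, b * apart_distance, c * apart_distance)
            for a in range(side)
            for b in range(side)
            for c in range(side)
        ][:n_residues]
    )
    coords = np.tile(grid, (n_frames, 1, 1))
    for (i, j), p in planted_contacts.items():
        n_contact = int(round(p * n_frames))
        frames = rng.permutation(n_frames)[:n_contact]
        coords[frames, j] = grid[i] + np.array([contact_distance, 0.0, 0.0])
    top = make_ca_topology(n_residues)
    return Trajectory(top, coords), GroundTruth(planted_contacts=dict(planted_contacts))


def sample_hbond_trajectory(
    n_pairs: int,
    bond_fractions: list[float],
    n_frames: int,
    seed: int = 0,
) -> tuple[Trajectory, GroundTruth, np.ndarray]:
    """Planted donor-H...acceptor geometry with known per-frame bond counts.

    Pair k consists of a serine-like donor (OG with hydrogen HG) and an
    acceptor carbonyl O in another residue.  In "bonded" frames the acceptor
    sits collinear with the O-H vector at 0.28 nm from the donor; otherwise
    it is displaced to 0.5 nm.  Returns the planted per-frame count vector.
    """
    if len(bond_fractions) != n_pairs:
        raise ValueError("one bond fraction per pair required")
    rng = np.random.default_rng(seed)
    atoms = []
    for k in range(n_pairs):
        atoms.append(AtomRecord("OG", "O", 2 * k + 1, "SER", "A"))
        atoms.append(AtomRecord("HG", "H", 2 * k + 1, "SER", "A"))
        atoms.append(AtomRecord("O", "O", 2 * k + 2, "GLY", "A"))
    top = Topology(atoms)

    coords = np.zeros((n_frames, len(atoms), 3))
    bonded = np.zeros((n_frames, n_pairs), dtype=bool)
    for k, frac in enumerate(bond_fractions):
        n_on = int(round(frac * n_frames))
        on = np.zeros(n_frames, dtype=bool)
        on[rng.permutation(n_frames)[:n_on]] = True
        bonded[:, k] = on
        origin = np.array([0.0, 3.0 * k, 0.0])
        d = origin
        h = origin + np.array([0.096, 0.0, 0.0])
        coords[:, 3 * k + 0] = d
        coords[:, 3 * k + 1] = h
        a_on = origin + np.array([0.28, 0.0, 0.0])
        a_off = origin + np.array([0.50, 0.0, 0.0])
        coords[:, 3 * k + 2] = np.where(on[:, None], a_on, a_off)
    counts = bonded.sum(axis=1)
    return Trajectory(top, coords), GroundTruth(), counts
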