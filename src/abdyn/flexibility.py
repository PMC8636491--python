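"""Backbone dihedrals, angular-dispersion (PAD) profiles, and RMSF.

The per-residue backbone plasticity measure PAD_omega works on the angle
omega = phi + psi (wrapped), NOT the peptide-bond dihedral: summing the two
torsions gives one circular variable per residue whose dispersion tracks
backbone flexibility.  With Rbar the mean resultant length of the omega
samples on the unit circle,

    PAD_omega = (180 / pi) * arccos(2 Rbar - 1)   [degrees]

which is 0 when every frame has the same omega (Rbar = 1) and 180 when the
samples are maximally dispersed (Rbar = 0).  The map is config-pluggable so
an alternative dispersion-to-angle convention can be swapped in.

Angles are degrees in (-180, 180] at all interfaces; radians internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .clustering import align_frames
from .trajectory_io import Trajectory


@dataclass
class DihedralSeries:
    """Per-frame, per-residue phi/psi and their wrapped sum omega (degrees)."""

    phi: np.ndarray     # F x R, NaN where undefined
    psi: np.ndarray     # F x R
    omega_sum: np.ndarray  # F x R, wrap(phi + psi)
    defined: np.ndarray    # R bool, False at termini / missing atoms
    residue_keys: list


@dataclass
class PADProfile:
    values: np.ndarray     # R, degrees in [0, 180]; NaN where undefined
    defined: np.ndarray
    residue_keys: list


@dataclass
class RMSFProfile:
    values: np.ndarray     # R, nm
    residue_keys: list
    reference: int


def wrap_degrees(a):
    """Wrap angle(s) into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return float(out) if out.ndim == 0 else out


def dihedral_angle(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral (degrees) for points of shape (..., 3), IUPAC sign."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return np.degrees(np.arctan2(y, x))


def backbone_dihedrals(traj: Trajectory) -> DihedralSeries:
    """phi (C' - N - CA - C) and psi (N - CA - C - N') series per residue.

    The first residue of each chain has no phi and the last no psi; residues
    with missing backbone atoms are masked with a warning.  omega_sum is the
    wrapped sum phi + psi, defined only where both torsions exist.
    """
    top = traj.topology
    F = traj.n_frames
    R = top.n_residues
    # locate backbone atoms per residue
    atom_idx: list[dict[str, int]] = [{} for _ in range(R)]
    res_of_atom = top.atom_residue_indices()
    for i, a in enumerate(top.atoms):
        if a.atom_name in ("N", "CA", "C"):
            atom_idx[res_of_atom[i]].setdefault(a.atom_name, i)

    phi = np.full((F, R), np.nan)
    psi = np.full((F, R), np.nan)
    defined = np.zeros(R, dtype=bool)
    chains = [k[0] for k in top.residues]

    for r in range(R):
        names = atom_idx[r]
        if not all(n in names for n in ("N", "CA", "C")):
            warnings.warn(
                f"residue {top.residues[r]} missing backbone atoms; masked",
                stacklevel=2,
            )
            continue
        has_prev = r > 0 and chains[r - 1] == chains[r] and "C" in atom_idx[r - 1]
        has_next = (
            r < R - 1 and chains[r + 1] == chains[r] and "N" in atom_idx[r + 1]
        )
        if has_prev:
            phi[:, r] = dihedral_angle(
                traj.coords[:, atom_idx[r - 1]["C"]],
                traj.coords[:, names["N"]],
                traj.coords[:, names["CA"]],
                traj.coords[:, names["C"]],
            )
        if has_next:
            psi[:, r] = dihedral_angle(
                traj.coords[:, names["N"]],
                traj.coords[:, names["CA"]],
                traj.coords[:, names["C"]],
                traj.coords[:, atom_idx[r + 1]["N"]],
            )
        defined[r] = has_prev and has_next

    omega = np.where(
        np.isnan(phi) | np.isnan(psi), np.nan, wrap_degrees(phi + psi)
    )
    return DihedralSeries(
        phi=phi, psi=psi, omega_sum=omega, defined=defined,
        residue_keys=list(top.residues),
    )


def pad_from_resultant(rbar: float) -> float:
    """Default dispersion-to-angle map: (180/pi) * arccos(2 Rbar - 1)."""
    return float(np.degrees(np.arccos(np.clip(2.0 * rbar - 1.0, -1.0, 1.0))))


def pad_omega(
    omega_series: np.ndarray,
    pad_map: Callable[[float], float] = pad_from_resultant,
) -> float:
    """Angular dispersion (degrees in [0, 180]) of one omega sample series.

    Rbar is the mean resultant length of the samples on the unit circle;
    NaN entries (undefined frames) are ignored.  Requires >= 2 samples.
    """
    omega = np.asarray(omega_series, dtype=float)
    omega = omega[np.isfinite(omega)]
    if omega.size < 2:
        raise ValueError("need at least 2 defined samples")
    theta = np.deg2rad(omega)
    rbar = float(np.abs(np.exp(1j * theta).mean()))
    return pad_map(rbar)


def pad_profile(
    dihedrals: DihedralSeries,
    pad_map: Callable[[float], float] = pad_from_resultant,
) -> PADProfile:
    """Per-residue PAD_omega profile; undefined residues carry NaN, not 0."""
    R = dihedrals.omega_sum.shape[1]
    values = np.full(R, np.nan)
    for r in range(R):
        if dihedrals.defined[r]:
            values[r] = pad_omega(dihedrals.omega_sum[:, r], pad_map=pad_map)
    return PADProfile(
        values=values, defined=dihedrals.defined.copy(),
        residue_keys=dihedrals.residue_keys,
    )


def rmsf(
    traj: Trajectory,
    frames: np.ndarray | None = None,
    reference: int = 0,
    align: bool = True,
) -> RMSFProfile:
    """Per-residue C-alpha RMSF (nm) after superposition onto a reference."""
    ca = traj.topology.ca_indices()
    if ca.size == 0:
        raise ValueError("no C-alpha atoms in topology")
    if frames is None:
        frames = np.arange(traj.n_frames)
    frames = np.asarray(frames, dtype=int)
    if frames.size < 2:
        raise ValueError("need at least 2 frames")
    coords = traj.coords[frames]
    if align:
        coords = align_frames(coords, traj.coords[reference], ca)
    pos = coords[:, ca, :]
    mean = pos.mean(axis=0)
    values = np.sqrt(((pos - mean) ** 2).sum(axis=2).mean(axis=0))
    keys = [traj.topology.atoms[i].residue_key for i in ca]
    return RMSFProfile(values=values, residue_keys=keys, reference=reference)
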