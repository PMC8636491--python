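"""Mutual information, generalized correlation, and domain correlation scores.

Inter-residue communication is quantified from the scalar displacements of
each residue's C-alpha from its mean position (after rigid superposition of
the frames).  Mutual information between two displacement series is the
plug-in histogram estimator with 100 equal-width bins spanning [0, max] per
series, in nats:

    MI_ij = sum p(x_i, x_j) ln [ p(x_i, x_j) / (p(x_i) p(x_j)) ]

The generalized correlation coefficient maps MI to [0, 1] with the
3-dimensional Gaussian reference normalization,

    GCC_ij = sqrt(1 - exp(-2 MI_ij / 3)),

so that for jointly Gaussian 3-D displacement vectors with per-coordinate
correlation r, GCC equals |r| exactly.  The per-residue correlation score is
CS_i = sum_{j != i} GCC_ij, split into intra-domain and inter-domain parts.

No bias correction or pseudo-counts are applied: the estimator is the plain
100-bin plug-in recipe, and its positive bias on independent series
(~ (bins-1)^2 / 2n nats) is documented rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import align_frames
from .trajectory_io import DomainMap, Trajectory

DEFAULT_N_BINS = 100


@dataclass
class DisplacementSeries:
    """F x R scalar displacement magnitudes (nm) of each residue's C-alpha."""

    values: np.ndarray
    residue_keys: list[tuple[str, int, str]]
    reference: int | str = "mean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("displacements must be finite and non-negative")
        self.values = v


@dataclass
class MIMatrix:
    values: np.ndarray  # R x R, nats
    n_bins: int


@dataclass
class GCCMatrix:
    values: np.ndarray  # R x R in [0, 1]


@dataclass
class CorrelationScores:
    intra_cs: np.ndarray
    inter_cs: np.ndarray
    residue_keys: list[tuple[str, int, str]]
    domains: list[str]

    @property
    def total_cs(self) -> np.ndarray:
        return self.intra_cs + self.inter_cs

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.residue_keys],
                "residue": [k[1] for k in self.residue_keys],
                "domain": self.domains,
                "intra_cs": self.intra_cs,
                "inter_cs": self.inter_cs,
                "total_cs": self.total_cs,
            }
        )


def displacement_series(
    traj: Trajectory,
    frames: np.ndarray | None = None,
    reference: int = 0,
    align: bool = True,
) -> DisplacementSeries:
    """Scalar C-alpha displacement of each residue from its mean position.

    Frames are superposed (C-alpha Kabsch) onto the reference frame, the
    mean position of every C-alpha over the frame subset is computed, and
    the series value is the Euclidean distance of each frame's C-alpha from
    that mean.
    """
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
    values = np.linalg.norm(pos - mean, axis=2)
    keys = [traj.topology.atoms[i].residue_key for i in ca]
    return DisplacementSeries(values=values, residue_keys=keys, reference=reference)


def _bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width bins over [0, max(x)]; a constant series occupies bin 0."""
    xmax = x.max()
    if xmax <= 0:
        return np.zeros(len(x), dtype=int)
    idx = np.floor(x / xmax * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def mutual_information(
    x: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Plug-in MI estimate (nats) on per-series [0, max] equal-width bins.

    0 * log 0 terms are dropped; a constant series yields exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series length mismatch")
    n = len(x)
    ix = _bin_indices(x, n_bins)
    iy = _bin_indices(y, n_bins)
    joint = np.bincount(ix * n_bins + iy, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins
    ).astype(float) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mask = joint > 0
    return float(
        np.sum(joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask]))
    )


def mi_matrix(ds: DisplacementSeries, n_bins: int = DEFAULT_N_BINS) -> MIMatrix:
    """Symmetric residue x residue MI matrix.

    The diagonal holds each residue's self-information (its marginal bin
    entropy); downstream sums and network weights exclude it.
    """
    X = ds.values
    F, R = X.shape
    if R < 2:
        raise ValueError("need at least 2 residues")
    idx = np.empty((R, F), dtype=int)
    for r in range(R):
        idx[r] = _bin_indices(X[:, r], n_bins)
    M = np.zeros((R, R))
    for i in range(R):
        for j in range(i, R):
            joint = np.bincount(
                idx[i] * n_bins + idx[j], minlength=n_bins * n_bins
            ).reshape(n_bins, n_bins).astype(float) / F
            px = joint.sum(axis=1)
            py = joint.sum(axis=0)
            mask = joint > 0
            mi = float(
                np.sum(joint[mask] * np.log(joint[mask] / np.outer(px, py)[mask]))
            )
            M[i, j] = M[j, i] = mi
    return MIMatrix(values=M, n_bins=n_bins)


def gcc_from_mi(mi):
    """Generalized correlation coefficient: sqrt(1 - exp(-2 MI / 3)).

    Small negative MI values (estimator noise) are clamped to 0 so the
    coefficient stays in [0, 1].
    """
    mi = np.clip(np.asarray(mi, dtype=float), 0.0, None)
    out = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
    return float(out) if out.ndim == 0 else out


def gcc_matrix(mi: MIMatrix) -> GCCMatrix:
    return GCCMatrix(values=gcc_from_mi(mi.values))


def correlation_scores(
    gcc: GCCMatrix,
    residue_keys: list[tuple[str, int, str]],
    dmap: DomainMap,
) -> CorrelationScores:
    """Per-residue sums of GCC split into intra- and inter-domain parts.

    The diagonal (j = i) is excluded.  Every residue must be covered by the
    domain map; uncovered residues are reported in the error.
    """
    G = gcc.values
    R = G.shape[0]
    if len(residue_keys) != R:
        raise ValueError("residue key list does not match matrix size")
    domains = []
    missing = []
    for chain, idx, _ in residue_keys:
        d = dmap.domain_of(chain, idx)
        if d is None:
            missing.append((chain, idx))
        domains.append(d)
    if missing:
        raise ValueError(f"residues not covered by domain map: {missing}")

    dom_arr = np.array(domains)
    same = dom_arr[:, None] == dom_arr[None, :]
    off = ~np.eye(R, dtype=bool)
    intra = (G * (same & off)).sum(axis=1)
    inter = (G * (~same & off)).sum(axis=1)
    return CorrelationScores(
        intra_cs=intra, inter_cs=inter, residue_keys=residue_keys, domains=domains
    )
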