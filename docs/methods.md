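# Methods

`abdyn` analyses conformational ensembles of multi-domain proteins —
designed around full-length IgG antibodies — along five axes: conformational
clustering, information-theoretic residue correlation, communication
networks, backbone angular dispersion, and non-bonded interaction
persistence. This note records the models, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices.

## Conformational clustering

Frames are compared by Cα RMSD after optimal rigid superposition. The
rotation is the Kabsch solution restricted to proper rotations (mirror
images are never matched); the full F×F matrix uses a batched SVD closed
form, `rmsd² = (|P|² + |Q|² − 2·tr S*)/n`, with the smallest singular value
sign-flipped when the correlation matrix has negative determinant.

The matrix is clustered by average linkage (UPGMA) and cut at a distance
threshold: merges with height strictly above the threshold are removed, a
merge exactly at the threshold stays merged. The default threshold is
**1.2 nm**, the scale that separates global Fab/Fc rearrangements of a
full-length antibody; on the synthetic toy systems (inter-state RMSD
≈ 0.9 nm) an intermediate cut such as 0.5 nm is appropriate and is what the
examples use. Cluster ids are reassigned by increasing mean radius of
gyration (ties broken by population), so cluster 0 is always the most
compact state. Per-cluster statistics: population fraction, mass-weighted
Rg mean/sd, the medoid (member minimizing summed RMSD to the others), and
per-residue RMSF after aligning members to the medoid.

Essential dynamics diagonalizes the 3n×3n positional covariance after two
alignment passes (to frame 0, then to the mean) and reports the frames with
extreme projections on the leading components. Superposition itself mixes a
strictly one-axis motion into small rotational modes (relative eigenvalue
leakage ~1e-4); `align=False` is available when exact mode counting
matters.

## Mutual information and generalized correlation

The displacement series of residue *i* is the scalar distance of its Cα
from its mean position, after Cα superposition of all frames of the
analysed subset onto a reference (per-cluster: the medoid). Scalar
magnitudes — not 3-D vectors — are used because the binning is defined on
`[0, max]` per residue.

MI between two series is the plug-in histogram estimator on **100**
equal-width bins per series spanning `[0, max(series)]`, in nats, with
`0·log 0 ≡ 0`. No bias correction and no pseudo-counts are applied; the
estimator's positive bias on independent data (≈ (bins−1)²/2n nats) is a
documented property, and the test suite checks it decays with n. The
matrix diagonal holds each residue's marginal bin entropy and is excluded
from every downstream sum.

The generalized correlation coefficient is

    GCC = sqrt(1 − exp(−2·MI/3)),

the 3-dimensional Gaussian-reference normalization: for jointly Gaussian
3-D displacement vectors with per-coordinate correlation r, MI =
−(3/2)·ln(1−r²) and GCC inverts it to |r| exactly (checked to 1e-12).
Natural log is forced by this identity; base 2 would break it. Small
negative MI (estimator noise) is clamped to 0.

The correlation score of residue *i* is `CS_i = Σ_{j≠i} GCC_ij`, split by a
domain map into intra-domain (j in the same structural domain) and
inter-domain (all other domains) parts; the two parts sum to the total by
construction.

## Communication networks

Nodes are residues (Cα-centered). An edge requires heavy-atom contact —
minimum heavy-atom distance ≤ **0.45 nm** — in at least **75%** of the
analysed frames (inclusive threshold). Sequence neighbours (|i−j| ≤ 1
within one chain) are excluded: the peptide bond is always in contact and
carries no communication signal. Retained edges are weighted by the
information distance `w = −log(GCC)`; a GCC of exactly 0 would give
infinite distance, so such edges are dropped and recorded.

Edge betweenness: all-pairs shortest path lengths come from the
Floyd–Warshall recursion; the number of equal-cost shortest paths is then
counted exactly per source by dynamic programming over nodes in increasing
distance order (correct for positive weights; zero-weight edges, which
would need GCC = 1 exactly, are not counted). Each unordered connected pair
contributes one unit split equally among its equal-cost shortest paths.
Ties in path cost are detected with relative tolerance 1e-9.

Communities: Girvan–Newman — repeatedly remove the edge of maximum
betweenness, ties broken by the lexicographically smallest node pair (for
determinism), and keep the partition along the removal sequence maximizing
weighted modularity. Modularity uses GCC as the affinity weight, not
−log GCC, because modularity expects similarity weights.

Partition comparisons use the Rand distance (fraction of unordered node
pairs whose co-membership status disagrees), here called the community
repartition difference. This is a declared substitute for a
supplementary-material metric whose exact published formula was not
available; it is a true metric on the pair-indicator representation, with
value 0 for identical partitions and 1 when every pair disagrees.

## Backbone angular dispersion (PAD)

φ (C′−N−CA−C) and ψ (N−CA−C−N′) are computed per frame and residue; the
first φ and last ψ of each chain are undefined and masked, as are residues
with missing backbone atoms. The circular variable is ω = φ + ψ wrapped to
(−180°, 180°] — the *sum of torsions*, not the peptide-bond dihedral. With
R̄ the mean resultant length of the ω samples,

    PAD_ω = (180/π) · arccos(2·R̄ − 1),

which is exactly 0° for a constant series and 180° at maximal dispersion.
This is the simplest map satisfying the published range and monotonicity
constraints; the dispersion-to-angle map is a pluggable argument so an
alternative convention can be substituted without touching callers.
Degrees at all interfaces; radians internally. Undefined residues carry
NaN, never a fake 0.

## Interactions

* Hydrogen bonds: donor–acceptor distance ≤ **0.30 nm** and the angle
  between the D→H and D→A vectors ≤ **25°** (the deviation-from-linearity
  convention of the common visualization tools). Donor hydrogens are
  resolved geometrically (nearest N/O within 0.125 nm in frame 0); the
  element rules ship as editable YAML data. Explicit hydrogens are
  required; there is no heavy-atom-only mode.
* Salt bridges: minimum distance between anionic side-chain O (Asp/Glu,
  C-terminal OXT) and cationic side-chain N (Lys/Arg; His optionally, since
  protonation is unknown) ≤ **0.40 nm**. The criterion is standard practice
  — no published criterion existed to copy — and is a config key.
* Hydrophobic contacts: minimum distance between side-chain carbons of two
  apolar residues (Ala, Val, Leu, Ile, Met, Phe, Trp, Pro; for Tyr only the
  ring carbons) ≤ **0.45 nm**; same caveat.

Per-pair persistence is the fraction of frames with the interaction
present. The inter-domain table drops intra-domain rows, filters by a
persistence threshold (default 0.5), canonicalizes pair order by
(chain, residue), and sorts by persistence descending.

## Synthetic generators — what a green test establishes

Each analysis stage has a generator that plants its target quantity:

* **Multi-state mixtures** (clustering): k rigid reference conformations of
  a multi-domain Cα chain, differing by rigid-body motions of alternate
  domains (inter-state Cα RMSD ≈ 0.9 nm with the defaults), plus isotropic
  i.i.d. Gaussian noise (σ = 0.05 nm). Frame labels are recorded.
* **Correlated displacements** (MI/GCC): zero-mean Gaussian Cα fluctuations
  with a prescribed residue correlation matrix applied identically and
  independently to x, y, z, so the per-coordinate correlation equals the
  planted scalar.
* **Discrete joint series** (MI oracle): i.i.d. draws from an explicit
  joint pmf with the analytic MI from direct summation.
* **Backbone chains** (dihedrals/PAD): NeRF construction with ideal bond
  geometry and trans peptide bonds from prescribed φ/ψ; von Mises angle
  series of known concentration for dispersion targets.
* **Contact / H-bond plants** (network/interactions): residue pairs moved
  into contact in exactly round(p·F) frames; donor–H–acceptor triples with
  planted per-frame bond counts.

All generators are deterministic functions of their parameters and a seed;
no global random state. The Gaussian noise model gives every estimator an
analytic target but does **not** emulate real MD: no anharmonicity, no
correlated solvent-driven kinetics, no sidechain packing, no physical
energetics. A green recovery test establishes estimator and algorithm
correctness on the assumed statistical structure — not agreement with any
simulated or experimental antibody ensemble.

## Numerical choices and limitations

* Internal unit is nm everywhere; PDB Å converted at I/O. Multi-model PDB
  is the required on-disk dialect (coordinates round-trip to the format's
  1e-3 Å precision); binary trajectory formats are out of scope.
* First altloc kept; insertion codes carried as a residue-key suffix;
  author (EU) numbering never renumbered.
* UPGMA and threshold-cut semantics delegate to scipy
  (`linkage(method="average")`, `fcluster(criterion="distance")`); merge
  heights are verified against a from-definition recursion in the tests.
* Betweenness tie detection and Girvan–Newman tie-breaking are exact up to
  the 1e-9 relative tolerance; graphs whose distinct path costs differ by
  less than that are resolved arbitrarily but deterministically.
* The Floyd–Warshall betweenness is O(n³ + n·m) time and O(n²) memory;
  adequate for per-domain residue graphs (hundreds of nodes), not for
  atom-level graphs.
* `contact_persistence` computes a full heavy-atom distance matrix per
  frame — O(A²) memory per frame; use atom subsets for very large systems.
* The pipeline writes every stage's outputs before the next stage starts;
  identical config and inputs give byte-identical CSVs, and the manifest
  records config, input hash, seed and library versions.
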