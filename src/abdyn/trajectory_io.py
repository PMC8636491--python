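"""Structures, ensembles and domain maps.

The in-memory model is deliberately small: a :class:`Topology` (atoms grouped
into residues, residues grouped into chains) plus an ``F x A x 3`` coordinate
array in nanometres.  Multi-model PDB is the on-disk dialect: each MODEL block
becomes one frame, and atom order must be identical across models.

All coordinates are held in nm internally; PDB files use Angstrom and are
converted on read/write.  Residue numbering is carried verbatim from the
input file (antibody work conventionally cites EU numbers), never renumbered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

NM_PER_ANGSTROM = 0.1

#: Atom names treated as protein backbone.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class TrajectoryError(ValueError):
    """Malformed structure file or inconsistent ensemble."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the fixed topology.

    ``residue_index`` is the author-assigned number from the source file;
    insertion codes are kept as a separate suffix key so that authors'
    numbering (e.g. EU numbering for antibodies) survives a round trip.
    """

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise TrajectoryError(f"atom {self.atom_name!r} has empty element")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_backbone(self) -> bool:
        return self.atom_name in BACKBONE_NAMES

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.insertion_code)


class Topology:
    """Ordered atom list plus the residue grouping derived from it."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self.residues: list[tuple[str, int, str]] = []
        self.residue_names: list[str] = []
        self._atom_residue = np.empty(len(self.atoms), dtype=int)
        seen: dict[tuple[str, int, str], int] = {}
        for i, atom in enumerate(self.atoms):
            key = atom.residue_key
            if key not in seen:
                seen[key] = len(self.residues)
                self.residues.append(key)
                self.residue_names.append(atom.residue_name)
            self._atom_residue[i] = seen[key]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def atom_residue_indices(self) -> np.ndarray:
        """Residue index (0-based, in topology order) of every atom."""
        return self._atom_residue.copy()

    def atoms_of_residue(self, res_idx: int) -> np.ndarray:
        return np.flatnonzero(self._atom_residue == res_idx)

    def ca_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.atom_name == "CA"], dtype=int
        )

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Topology):
            return NotImplemented
        return self.atoms == other.atoms

    def __repr__(self) -> str:
        return f"<Topology {self.n_atoms} atoms, {self.n_residues} residues>"


@dataclass
class Trajectory:
    """Fixed topology plus ``F x A x 3`` coordinates in nm."""

    topology: Topology
    coords: np.ndarray
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must be F x A x 3, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coords have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class DomainEntry:
    label: str
    chain_id: str
    residue_start: int
    residue_end: int

    def __contains__(self, item: tuple[str, int]) -> bool:
        chain, idx = item
        return chain == self.chain_id and self.residue_start <= idx <= self.residue_end


@dataclass
class DomainMap:
    """Assignment of residue ranges to structural domains (VH, CL, hinge...)."""

    entries: list[DomainEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[DomainEntry]] = {}
        for e in self.entries:
            if e.residue_start > e.residue_end:
                raise ValueError(f"domain {e.label}: start > end")
            by_chain.setdefault(e.chain_id, []).append(e)
        for chain, ents in by_chain.items():
            ents = sorted(ents, key=lambda e: e.residue_start)
            for a, b in zip(ents, ents[1:]):
                if b.residue_start <= a.residue_end:
                    raise ValueError(
                        f"overlapping domain ranges on chain {chain}: "
                        f"{a.label} and {b.label}"
                    )

    def domain_of(self, chain_id: str, residue_index: int) -> str | None:
        for e in self.entries:
            if (chain_id, residue_index) in e:
                return e.label
        return None

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def load_domain_map(source: str | Path | dict) -> DomainMap:
    """Load a domain map from YAML (path or already-parsed mapping).

    Expected layout::

        domains:
          - {label: VH, chain: A, start: 1, end: 117}
          - {label: hinge1, chain: B, start: 216, end: 230}
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = source
    if not isinstance(data, dict) or "domains" not in data:
        raise ValueError("domain map must be a mapping with a 'domains' list")
    entries = []
    for item in data["domains"]:
        try:
            entries.append(
                DomainEntry(
                    label=str(item["label"]),
                    chain_id=str(item["chain"]),
                    residue_start=int(item["start"]),
                    residue_end=int(item["end"]),
                )
            )
        except KeyError as exc:
            raise ValueError(f"domain entry {item!r} missing key {exc}") from exc
    return DomainMap(entries)


def _scan_model_atom_counts(path: Path) -> list[int]:
    """Count ATOM/HETATM records per MODEL block for the consistency check."""
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec.startswith("MODEL"):
                saw_model = True
                if current is not None:
                    counts.append(current)
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec.startswith("ENDMDL"):
                if current is not None:
                    counts.append(current)
                    current = None
    if current is not None and (current > 0 or not saw_model):
        counts.append(current)
    return counts


def read_structure(path: str | Path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    MODEL blocks become frames; atom order must be identical across models —
    a model with a deviating atom count is a hard error naming that model.
    First alternate location is kept.  Coordinates are converted to nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    counts = _scan_model_atom_counts(path)
    if len(counts) > 1 and len(set(counts)) != 1:
        ref = counts[0]
        for i, c in enumerate(counts[1:], start=2):
            if c != ref:
                raise TrajectoryError(
                    f"inconsistent atom count in MODEL {i}: "
                    f"expected {ref}, found {c}"
                )

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # biotite raises several error types
        raise TrajectoryError(f"cannot parse {path}: {exc}") from exc

    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])

    atoms = []
    n = stack.array_length()
    ins = (
        stack.ins_code
        if "ins_code" in stack.get_annotation_categories()
        else np.full(n, "", dtype="U1")
    )
    for i in range(n):
        atoms.append(
            AtomRecord(
                atom_name=str(stack.atom_name[i]),
                element=str(stack.element[i]),
                residue_index=int(stack.res_id[i]),
                residue_name=str(stack.res_name[i]),
                chain_id=str(stack.chain_id[i]),
                insertion_code=str(ins[i]).strip(),
            )
        )
    coords = stack.coord * NM_PER_ANGSTROM
    return Trajectory(Topology(atoms), coords)


def write_structure(traj: Trajectory, path: str | Path) -> Path:
    """Write a Trajectory as multi-model PDB (one MODEL block per frame)."""
    path = Path(path)
    top = traj.topology
    n = top.n_atoms
    template = struc.AtomArray(n)
    template.coord = np.zeros((n, 3))
    template.chain_id = np.array([a.chain_id for a in top.atoms])
    template.res_id = np.array([a.residue_index for a in top.atoms])
    template.ins_code = np.array([a.insertion_code for a in top.atoms])
    template.res_name = np.array([a.residue_name for a in top.atoms])
    template.atom_name = np.array([a.atom_name for a in top.atoms])
    template.element = np.array([a.element for a in top.atoms])
    template.hetero = np.zeros(n, dtype=bool)

    frames = []
    for f in range(traj.n_frames):
        arr = template.copy()
        arr.coord = traj.coords[f] / NM_PER_ANGSTROM
        frames.append(arr)
    stack = struc.stack(frames)

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    # biotite omits MODEL records for a depth-1 stack; the multi-model
    # dialect requires one MODEL/ENDMDL pair per frame even for F = 1.
    text = path.read_text()
    if "MODEL" not in text:
        lines = text.splitlines(keepends=True)
        first = next(
            i for i, l in enumerate(lines) if l.startswith(("ATOM", "HETATM"))
        )
        last = max(
            i for i, l in enumerate(lines) if l.startswith(("ATOM", "HETATM"))
        )
        lines.insert(last + 1, "ENDMDL\n")
        lines.insert(first, "MODEL        1\n")
        path.write_text("".join(lines))
    return path


def select_atoms(
    top: Topology,
    atom_names: Iterable[str] | None = None,
    chain_id: str | None = None,
    residue_range: tuple[int, int] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Select atom indices by name / chain / residue range / heavy-atom flag.

    A pure function of (topology, selector); indices are strictly increasing.
    An empty selection is legal but emits a warning.
    """
    names = set(atom_names) if atom_names is not None else None
    out = []
    for i, a in enumerate(top.atoms):
        if names is not None and a.atom_name not in names:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_index <= residue_range[1]
        ):
            continue
        if heavy_only and not a.is_heavy:
            continue
        out.append(i)
    if not out:
        warnings.warn("atom selection is empty", stacklevel=2)
    return np.array(out, dtype=int)
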