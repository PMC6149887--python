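"""Text formats: ligand PDBQT (torsion-tree subset), AutoDock-style ``.map``
grids, result JSON and tab-separated trace tables.

The PDBQT subset covers ligand files as produced by standard AutoDock ligand
preparation: ``ATOM``/``HETATM`` records carrying partial charge and atom
type, ``ROOT``/``ENDROOT``, nested ``BRANCH``/``ENDBRANCH`` pairs and
``TORSDOF``.  Parsers reject malformed records with the offending line number
rather than skipping them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .engine import RunResult
from .genome import Atom, Branch, LigandTopology, PoseGenome, decode_pose
from .scoring import GridMapSet

__all__ = [
    "PdbqtParseError",
    "MapParseError",
    "read_pdbqt",
    "write_pdbqt",
    "read_map",
    "write_map",
    "MapGrid",
    "write_result_json",
    "write_trace_tsv",
]


class PdbqtParseError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"PDBQT line {line_no}: {message}")
        self.line_no = line_no


class MapParseError(ValueError):
    pass


def _parse_atom(line: str, line_no: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        charge = float(line[66:76])
        ad_type = line[77:].strip() or name[:1]
    except (ValueError, IndexError) as exc:
        raise PdbqtParseError(line_no, f"malformed ATOM/HETATM record: {exc}")
    element = "".join(c for c in ad_type if c.isalpha())[:1].upper() or "C"
    if name[:1].upper() == "H" or ad_type.upper() in ("H", "HD", "HS"):
        element = "H"
    return Atom(serial, name, element, ad_type, charge, (x, y, z))


def read_pdbqt(text: str) -> LigandTopology:
    """Parse a ligand PDBQT into a :class:`LigandTopology`.

    The branch nesting in the file defines the torsion tree; atoms inside a
    ``BRANCH``/``ENDBRANCH`` pair (including nested branches) form that
    branch's moving set.  A ``TORSDOF`` disagreeing with the branch count
    triggers a warning and the branch count wins.
    """
    atoms: list[Atom] = []
    root_serials: set[int] = set()
    branches: list[dict] = []  # {"bond", "moving", "parent"}
    stack: list[int | str] = []  # "root" or branch index
    in_root_seen = False
    torsdof_value: int | None = None

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.startswith(("REMARK", "MODEL", "ENDMDL", "USER")):
            continue
        tag = line.split()[0]
        if tag == "ROOT":
            if in_root_seen:
                raise PdbqtParseError(line_no, "duplicate ROOT")
            in_root_seen = True
            stack.append("root")
        elif tag == "ENDROOT":
            if not stack or stack[-1] != "root":
                raise PdbqtParseError(line_no, "ENDROOT without open ROOT")
            stack.pop()
        elif tag == "BRANCH":
            parts = line.split()
            if len(parts) != 3:
                raise PdbqtParseError(line_no, "BRANCH needs two atom serials")
            try:
                a, b = int(parts[1]), int(parts[2])
            except ValueError:
                raise PdbqtParseError(line_no, "non-numeric BRANCH serials")
            parent = None
            for frame in reversed(stack):
                if isinstance(frame, int):
                    parent = frame
                    break
            branches.append({"bond": (a, b), "moving": set(), "parent": parent})
            stack.append(len(branches) - 1)
        elif tag == "ENDBRANCH":
            if not stack or not isinstance(stack[-1], int):
                raise PdbqtParseError(line_no, "unbalanced ENDBRANCH")
            stack.pop()
        elif tag == "TORSDOF":
            try:
                torsdof_value = int(line.split()[1])
            except (IndexError, ValueError):
                raise PdbqtParseError(line_no, "malformed TORSDOF")
        elif tag in ("ATOM", "HETATM"):
            atom = _parse_atom(line, line_no)
            atoms.append(atom)
            placed = False
            for frame in stack:
                if frame == "root":
                    if not any(isinstance(f, int) for f in stack):
                        root_serials.add(atom.serial)
                        placed = True
                        break
            for frame in stack:
                if isinstance(frame, int):
                    branches[frame]["moving"].add(atom.serial)
                    placed = True
            if not placed:
                raise PdbqtParseError(
                    line_no, "atom outside ROOT/BRANCH structure")
        elif tag == "END":
            break
        else:
            raise PdbqtParseError(line_no, f"unrecognized record {tag!r}")

    if not in_root_seen:
        raise PdbqtParseError(0, "missing ROOT record")
    if any(isinstance(f, int) for f in stack) or "root" in stack:
        raise PdbqtParseError(0, "unbalanced ROOT/BRANCH nesting at EOF")
    if not atoms:
        raise PdbqtParseError(0, "no atoms")

    n_branches = len(branches)
    if torsdof_value is not None and torsdof_value != n_branches:
        warnings.warn(
            f"TORSDOF {torsdof_value} disagrees with {n_branches} BRANCH "
            "records; using the branch count", stacklevel=2)
    branch_objs = [
        Branch(bond=b["bond"], moving=frozenset(b["moving"]), parent=b["parent"])
        for b in branches
    ]
    bonds = [b["bond"] for b in branches]
    return LigandTopology(atoms=atoms, bonds=bonds,
                          root=frozenset(root_serials),
                          branches=branch_objs, torsdof=n_branches)


def _format_atom(atom: Atom, xyz: np.ndarray) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {atom.serial:>5d} {name:<4s} LIG A   1    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"    {atom.charge:6.3f} {atom.ad_type:<2s}"
    )


def write_pdbqt(topo: LigandTopology, genome: PoseGenome | np.ndarray | None = None
                ) -> str:
    """Serialize a topology (optionally posed by ``genome``) as ligand PDBQT.

    Coordinates are :func:`decode_pose` output at 3 decimals (the PDB column
    quantum); the torsion-tree nesting is reconstructed from branch parents.
    """
    if genome is None:
        genome = PoseGenome.identity(topo.torsdof)
    coords = decode_pose(genome, topo)
    row = topo.row_of
    owned: list[list[Atom]] = [[] for _ in topo.branches]
    children: list[list[int]] = [[] for _ in topo.branches]
    top_level: list[int] = []
    for i, br in enumerate(topo.branches):
        descendant = set()
        for j, other in enumerate(topo.branches):
            if other.parent == i:
                children[i].append(j)
                descendant |= other.moving
        owned[i] = [a for a in topo.atoms
                    if a.serial in br.moving - descendant]
        if br.parent is None:
            top_level.append(i)

    lines = [f"REMARK  {topo.torsdof} active torsions", "ROOT"]
    for a in topo.atoms:
        if a.serial in topo.root:
            lines.append(_format_atom(a, coords[row(a.serial)]))
    lines.append("ENDROOT")

    def emit(i: int) -> None:
        a, b = topo.branches[i].bond
        lines.append(f"BRANCH {a:>3d} {b:>3d}")
        for atom in owned[i]:
            lines.append(_format_atom(atom, coords[row(atom.serial)]))
        for j in children[i]:
            emit(j)
        lines.append(f"ENDBRANCH {a:>3d} {b:>3d}")

    for i in top_level:
        emit(i)
    lines.append(f"TORSDOF {topo.torsdof}")
    return "\n".join(lines) + "\n"


@dataclass
class MapGrid:
    """One parsed affinity lattice with its box geometry."""

    values: np.ndarray  # (nx, ny, nz), x fastest on disk
    spacing: float
    center: np.ndarray


def read_map(text: str) -> MapGrid:
    """Parse an AutoDock-style ``.map``: header keywords then one value per
    line in x-fastest / z-slowest order; ``NELEMENTS`` are intervals per axis
    (points per axis = NELEMENTS + 1)."""
    spacing = None
    nelements = None
    center = None
    values: list[float] = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        key = line.split()[0].upper()
        if key in ("GRID_PARAMETER_FILE", "GRID_DATA_FILE", "MACROMOLECULE"):
            continue
        if key == "SPACING":
            spacing = float(line.split()[1])
        elif key == "NELEMENTS":
            nelements = tuple(int(v) for v in line.split()[1:4])
        elif key == "CENTER":
            center = np.array([float(v) for v in line.split()[1:4]])
        else:
            try:
                values.append(float(line))
            except ValueError:
                raise MapParseError(f"line {line_no}: unexpected token {line!r}")
    if spacing is None or nelements is None or center is None:
        raise MapParseError("incomplete header (SPACING/NELEMENTS/CENTER)")
    npts = tuple(n + 1 for n in nelements)
    expected = npts[0] * npts[1] * npts[2]
    if len(values) != expected:
        raise MapParseError(
            f"expected {expected} grid values for NELEMENTS {nelements}, "
            f"found {len(values)}")
    # file order: x fastest, then y, then z -> reshape (z, y, x), transpose
    lattice = np.array(values).reshape(npts[2], npts[1], npts[0]).T
    return MapGrid(values=np.ascontiguousarray(lattice), spacing=spacing,
                   center=center)


def write_map(values: np.ndarray, spacing: float, center: np.ndarray,
              label: str = "none") -> str:
    """Serialize a lattice in the ``.map`` dialect read by :func:`read_map`."""
    values = np.asarray(values)
    nx, ny, nz = values.shape
    head = [
        f"GRID_PARAMETER_FILE {label}",
        f"GRID_DATA_FILE {label}",
        f"MACROMOLECULE {label}",
        f"SPACING {spacing:g}",
        f"NELEMENTS {nx - 1} {ny - 1} {nz - 1}",
        "CENTER {:.3f} {:.3f} {:.3f}".format(*np.asarray(center, dtype=float)),
    ]
    body = [f"{v:.6f}" for v in values.T.ravel()]  # x fastest
    return "\n".join(head + body) + "\n"


def write_result_json(result: RunResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(result.to_json())
        fh.write("\n")


def write_trace_tsv(result: RunResult, path: str) -> None:
    """One row per generation: generation index and best-so-far energy."""
    with open(path, "w") as fh:
        fh.write("generation\tbest_energy\n")
        for g, e in enumerate(result.trace):
            fh.write(f"{g}\t{e:.10g}\n")
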