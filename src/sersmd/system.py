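"""Molecular system container and structure/topology IO.

A :class:`MolecularSystem` holds atoms (element, mass, force-field class,
position, velocity), the bonded topology (bonds, angles, torsions), named
atom groups (``graphene`` / ``nucleotide`` / ``nanoparticle``) and a
fixed-atom mask.  Atom indices are 0-based internally; all file formats and
user-facing bond labels such as ``C(2)-C(3)`` are 1-based in file order, so
labels match the conventional internal numbering of the bundled nucleosides.

Structure input is XYZ (plain, Å; an optional fifth column carries a group
tag) or PDB (coordinates and elements only, read through MDAnalysis).  The
topology sidecar is plain text, one record per line::

    bond i j
    angle i j k
    torsion i j k l
    ring i j k l m n        # aromatic ring membership (optional)
    class i NAME            # force-field class override (optional)

with 1-based indices.  Angles and torsions are derived from bonds when the
sidecar does not list them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .units import ATOMIC_MASSES, COVALENT_RADII

GROUP_NAMES = ("graphene", "nucleotide", "nanoparticle")


class TopologyError(ValueError):
    """Malformed structure or topology input."""


@dataclass
class MolecularSystem:
    elements: list[str]
    positions: np.ndarray          # (n, 3) Å
    velocities: np.ndarray         # (n, 3) Å/fs
    masses: np.ndarray             # (n,) amu
    classes: list[str]             # force-field class ids
    bonds: np.ndarray              # (nb, 2) int
    angles: np.ndarray             # (na, 3) int
    torsions: np.ndarray           # (nt, 4) int
    groups: dict[str, np.ndarray]  # label -> atom indices
    fixed_mask: np.ndarray         # (n,) bool
    ring: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            elements=list(self.elements),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            classes=list(self.classes),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            torsions=self.torsions.copy(),
            groups={k: v.copy() for k, v in self.groups.items()},
            fixed_mask=self.fixed_mask.copy(),
            ring=self.ring.copy(),
        )

    def group_indices(self, label: str) -> np.ndarray:
        if label not in self.groups:
            raise KeyError(f"no group {label!r}; have {sorted(self.groups)}")
        return self.groups[label]

    def validate(self) -> None:
        n = self.n_atoms
        if not np.all(np.isfinite(self.positions)):
            raise TopologyError("non-finite positions")
        if np.any(self.masses <= 0):
            raise TopologyError("all masses must be positive")
        for name, arr in (("bonds", self.bonds), ("angles", self.angles),
                          ("torsions", self.torsions)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise TopologyError(f"{name} reference atom indices outside 0..{n - 1}")
        if self.bonds.size:
            key = {tuple(sorted(b)) for b in self.bonds.tolist()}
            if len(key) != len(self.bonds):
                raise TopologyError("duplicate bonds")
        covered = np.concatenate([v for v in self.groups.values()]) if self.groups else \
            np.empty(0, dtype=int)
        if len(covered) != n or len(np.unique(covered)) != n:
            raise TopologyError("groups must partition the atom set")
        if np.any(np.abs(self.velocities[self.fixed_mask]) > 0):
            raise TopologyError("fixed atoms must have zero velocity")

    def neighbor_lists(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs


def _empty(n: int):
    return (np.zeros((n, 3)), np.zeros((n, 3)))


def new_system(elements, positions, group: str, classes=None,
               bonds=None, angles=None, torsions=None) -> MolecularSystem:
    """Assemble a single-group system, deriving missing pieces."""
    elements = list(elements)
    n = len(elements)
    positions = np.asarray(positions, dtype=float).reshape(n, 3)
    try:
        masses = np.array([ATOMIC_MASSES[e] for e in elements])
    except KeyError as exc:
        raise TopologyError(f"unknown element {exc.args[0]!r}") from None
    bonds = np.asarray(bonds if bonds is not None else [], dtype=int).reshape(-1, 2)
    sys = MolecularSystem(
        elements=elements,
        positions=positions,
        velocities=np.zeros((n, 3)),
        masses=masses,
        classes=list(classes) if classes is not None else ["?"] * n,
        bonds=bonds,
        angles=np.asarray(angles if angles is not None else [], dtype=int).reshape(-1, 3),
        torsions=np.asarray(torsions if torsions is not None else [], dtype=int).reshape(-1, 4),
        groups={group: np.arange(n)},
        fixed_mask=np.zeros(n, dtype=bool),
    )
    if classes is None:
        sys.classes = infer_classes(sys)
    return sys


def angles_from_bonds(bonds: np.ndarray, n_atoms: int) -> np.ndarray:
    """All i-j-k triples with j bonded to both i and k (i < k)."""
    nbrs: list[list[int]] = [[] for _ in range(n_atoms)]
    for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
        nbrs[i].append(j)
        nbrs[j].append(i)
    out = []
    for j in range(n_atoms):
        for i, k in itertools.combinations(sorted(nbrs[j]), 2):
            out.append((i, j, k))
    return np.asarray(out, dtype=int).reshape(-1, 3)


def torsions_from_bonds(bonds: np.ndarray, n_atoms: int) -> np.ndarray:
    """All i-j-k-l quadruples around every central bond j-k."""
    nbrs: list[list[int]] = [[] for _ in range(n_atoms)]
    blist = np.asarray(bonds, dtype=int).reshape(-1, 2)
    for i, j in blist:
        nbrs[i].append(j)
        nbrs[j].append(i)
    out = []
    for j, k in blist:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                out.append((i, j, k, l))
    return np.asarray(out, dtype=int).reshape(-1, 4)


def infer_classes(sys: MolecularSystem) -> list[str]:
    """Assign force-field class ids from element and connectivity.

    C3/C2 for sp3/sp2 carbon (by neighbour count), N2 for (planar amide or
    amino) nitrogen, O2 carbonyl vs O3 sp3 oxygen, HC/HN/HO for hydrogen by
    the heavy atom it rides on, CG for graphene carbon, AU for gold.
    """
    nbrs = sys.neighbor_lists()
    graphene = set(sys.groups.get("graphene", np.empty(0, dtype=int)).tolist())
    classes = []
    for i, el in enumerate(sys.elements):
        if el == "Au":
            classes.append("AU")
        elif i in graphene:
            classes.append("CG")
        elif el == "C":
            classes.append("C3" if len(nbrs[i]) >= 4 else "C2")
        elif el == "N":
            classes.append("N2")
        elif el == "O":
            classes.append("O2" if len(nbrs[i]) <= 1 else "O3")
        elif el == "H":
            host = sys.elements[nbrs[i][0]] if nbrs[i] else "C"
            classes.append({"N": "HN", "O": "HO"}.get(host, "HC"))
        elif el == "P":
            classes.append("P")
        else:
            classes.append(el.upper())
    return classes


def infer_bonds(elements, positions, slack: float = 1.15) -> np.ndarray:
    """Bond pairs whose distance is below ``slack`` x covalent-radius sum."""
    positions = np.asarray(positions, dtype=float)
    radii = np.array([COVALENT_RADII.get(e, 0.8) for e in elements])
    out = []
    for i in range(len(elements)):
        d = np.linalg.norm(positions[i + 1:] - positions[i], axis=1)
        cut = slack * (radii[i] + radii[i + 1:])
        for off in np.nonzero(d < cut)[0]:
            out.append((i, i + 1 + off))
    return np.asarray(out, dtype=int).reshape(-1, 2)


# ---------------------------------------------------------------------------
# file IO

def read_xyz(path) -> tuple[list[str], np.ndarray, list[str | None]]:
    """Read XYZ; returns (elements, positions, per-atom group tags or None)."""
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines:
        raise TopologyError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise TopologyError(f"{path}: line 1: expected atom count") from None
    if len(lines) < n + 2:
        raise TopologyError(f"{path}: truncated, expected {n} atom lines")
    elements, pos, tags = [], [], []
    for ln, line in enumerate(lines[2:2 + n], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise TopologyError(f"{path}: line {ln}: expected 'El x y z [group]'")
        el = parts[0].capitalize() if len(parts[0]) > 1 else parts[0].upper()
        if el not in ATOMIC_MASSES:
            raise TopologyError(f"{path}: line {ln}: unknown element {parts[0]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise TopologyError(f"{path}: line {ln}: malformed coordinates") from None
        elements.append(el)
        pos.append(xyz)
        tags.append(parts[4] if len(parts) > 4 else None)
    return elements, np.asarray(pos), tags


def write_xyz(path, sys: MolecularSystem, comment: str = "") -> None:
    """Write XYZ with a per-atom group tag in the fifth column."""
    label = np.empty(sys.n_atoms, dtype=object)
    for name, idx in sys.groups.items():
        label[idx] = name
    with open(path, "w") as f:
        f.write(f"{sys.n_atoms}\n")
        f.write(f"{comment} | columns: element x y z group\n".lstrip())
        for i in range(sys.n_atoms):
            x, y, z = sys.positions[i]
            f.write(f"{sys.elements[i]:2s} {x:14.8f} {y:14.8f} {z:14.8f} {label[i]}\n")


def read_pdb(path) -> tuple[list[str], np.ndarray]:
    """Read coordinates + elements from a PDB file via MDAnalysis."""
    import warnings

    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        elements = [e.capitalize() for e in u.atoms.elements] \
            if hasattr(u.atoms, "elements") else \
            [mda.topology.guessers.guess_atom_element(n).capitalize() for n in u.atoms.names]
        return elements, u.atoms.positions.astype(float)


def read_topology_sidecar(path, n_atoms: int):
    """Parse the sidecar; returns (bonds, angles, torsions, ring, class_over, fixed)."""
    bonds, angles, torsions, ring, fixed = [], [], [], [], []
    class_over: dict[int, str] = {}
    with open(path) as f:
        for ln, raw in enumerate(f, start=1):
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            kind, args = parts[0].lower(), parts[1:]
            if kind == "class":
                class_over[int(args[0]) - 1] = args[1]
                continue
            try:
                idx = [int(a) - 1 for a in args]
            except ValueError:
                raise TopologyError(f"{path}: line {ln}: non-integer index") from None
            if any(i < 0 or i >= n_atoms for i in idx):
                raise TopologyError(
                    f"{path}: line {ln}: atom index out of range 1..{n_atoms}")
            if kind == "bond" and len(idx) == 2:
                bonds.append(idx)
            elif kind == "angle" and len(idx) == 3:
                angles.append(idx)
            elif kind == "torsion" and len(idx) == 4:
                torsions.append(idx)
            elif kind == "ring":
                ring = idx
            elif kind == "fixed":
                fixed += idx
            else:
                raise TopologyError(f"{path}: line {ln}: unknown record {kind!r}")
    return (np.asarray(bonds, dtype=int).reshape(-1, 2),
            np.asarray(angles, dtype=int).reshape(-1, 3),
            np.asarray(torsions, dtype=int).reshape(-1, 4),
            np.asarray(ring, dtype=int), class_over,
            np.asarray(fixed, dtype=int))


def load_structure(path, topology_path=None, group: str = "nucleotide") -> MolecularSystem:
    """Load a structure file plus its topology sidecar.

    Atom numbering is preserved from file order (1-based in labels), so bond
    labels like ``C(2)-C(3)`` refer to the same atoms as in the source file.
    With an empty or missing sidecar, bonds are inferred from covalent radii;
    angles and torsions are always derived from bonds when not listed.
    """
    path = str(path)
    if path.lower().endswith(".pdb"):
        elements, positions = read_pdb(path)
    else:
        elements, positions, _ = read_xyz(path)
    n = len(elements)
    bonds = angles = torsions = None
    ring = np.empty(0, dtype=int)
    class_over: dict[int, str] = {}
    fixed = np.empty(0, dtype=int)
    if topology_path is not None:
        bonds, angles, torsions, ring, class_over, fixed = \
            read_topology_sidecar(topology_path, n)
    if bonds is None or len(bonds) == 0:
        bonds = infer_bonds(elements, positions)
    if angles is None or len(angles) == 0:
        angles = angles_from_bonds(bonds, n)
    if torsions is None or len(torsions) == 0:
        torsions = torsions_from_bonds(bonds, n)
    sys = new_system(elements, positions, group, bonds=bonds,
                     angles=angles, torsions=torsions)
    for i, cls in class_over.items():
        sys.classes[i] = cls
    sys.ring = ring
    if fixed.size:
        sys.fixed_mask[fixed] = True
    sys.validate()
    return sys


def write_topology_sidecar(path, sys: MolecularSystem) -> None:
    """Write the full topology (bonds/angles/torsions/ring/fixed), 1-based."""
    with open(path, "w") as f:
        f.write("# sersmd topology sidecar (1-based indices)\n")
        for i, j in sys.bonds:
            f.write(f"bond {i + 1} {j + 1}\n")
        for i, j, k in sys.angles:
            f.write(f"angle {i + 1} {j + 1} {k + 1}\n")
        for i, j, k, l in sys.torsions:
            f.write(f"torsion {i + 1} {j + 1} {k + 1} {l + 1}\n")
        if sys.ring.size:
            f.write("ring " + " ".join(str(i + 1) for i in sys.ring) + "\n")
        fixed = np.nonzero(sys.fixed_mask)[0]
        if fixed.size:
            f.write("fixed " + " ".join(str(i + 1) for i in fixed) + "\n")
        for i, cls in enumerate(sys.classes):
            f.write(f"class {i + 1} {cls}\n")


def save_system(xyz_path, top_path, sys: MolecularSystem, comment: str = "") -> None:
    """Write a (possibly multi-group) system as tagged XYZ + topology sidecar."""
    write_xyz(xyz_path, sys, comment)
    write_topology_sidecar(top_path, sys)


def load_system(xyz_path, top_path=None) -> MolecularSystem:
    """Load a tagged XYZ + sidecar, reconstructing groups from column 5."""
    elements, positions, tags = read_xyz(xyz_path)
    n = len(elements)
    groups: dict[str, list[int]] = {}
    for i, t in enumerate(tags):
        groups.setdefault(t if t is not None else "nucleotide", []).append(i)
    bonds = angles = torsions = None
    ring = np.empty(0, dtype=int)
    fixed = np.empty(0, dtype=int)
    class_over: dict[int, str] = {}
    if top_path is not None:
        bonds, angles, torsions, ring, class_over, fixed = \
            read_topology_sidecar(top_path, n)
    if bonds is None or len(bonds) == 0:
        bonds = infer_bonds(elements, positions)
        if "nanoparticle" in groups and len(bonds):   # metallic: no topology
            npset = set(groups["nanoparticle"])
            bonds = np.asarray([b for b in bonds.tolist()
                                if not (b[0] in npset or b[1] in npset)],
                               dtype=int).reshape(-1, 2)
    if angles is None or len(angles) == 0:
        angles = angles_from_bonds(bonds, n)
    if torsions is None or len(torsions) == 0:
        torsions = torsions_from_bonds(bonds, n)
    try:
        masses = np.array([ATOMIC_MASSES[e] for e in elements])
    except KeyError as exc:
        raise TopologyError(f"unknown element {exc.args[0]!r}") from None
    sys = MolecularSystem(
        elements=elements, positions=positions, velocities=np.zeros((n, 3)),
        masses=masses, classes=["?"] * n,
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        angles=np.asarray(angles, dtype=int).reshape(-1, 3),
        torsions=np.asarray(torsions, dtype=int).reshape(-1, 4),
        groups={k: np.asarray(v, dtype=int) for k, v in groups.items()},
        fixed_mask=np.zeros(n, dtype=bool), ring=ring,
    )
    sys.classes = infer_classes(sys)
    for i, cls in class_over.items():
        sys.classes[i] = cls
    if fixed.size:
        sys.fixed_mask[fixed] = True
    sys.validate()
    return sys


def merge_systems(*systems: MolecularSystem) -> MolecularSystem:
    """Concatenate systems, offsetting topology indices and keeping groups."""
    offset = 0
    elements, classes = [], []
    pos, vel, mass, fix = [], [], [], []
    bonds, angles, torsions = [], [], []
    groups: dict[str, np.ndarray] = {}
    ring = np.empty(0, dtype=int)
    for s in systems:
        elements += s.elements
        classes += s.classes
        pos.append(s.positions)
        vel.append(s.velocities)
        mass.append(s.masses)
        fix.append(s.fixed_mask)
        if s.bonds.size:
            bonds.append(s.bonds + offset)
        if s.angles.size:
            angles.append(s.angles + offset)
        if s.torsions.size:
            torsions.append(s.torsions + offset)
        for k, v in s.groups.items():
            if k in groups:
                groups[k] = np.concatenate([groups[k], v + offset])
            else:
                groups[k] = v + offset
        if s.ring.size:
            ring = s.ring + offset
        offset += s.n_atoms
    out = MolecularSystem(
        elements=elements,
        positions=np.concatenate(pos),
        velocities=np.concatenate(vel),
        masses=np.concatenate(mass),
        classes=classes,
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), dtype=int),
        angles=np.concatenate(angles) if angles else np.empty((0, 3), dtype=int),
        torsions=np.concatenate(torsions) if torsions else np.empty((0, 4), dtype=int),
        groups=groups,
        fixed_mask=np.concatenate(fix),
        ring=ring,
    )
    out.validate()
    return out
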