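"""Builders for the three system components and their assembly.

* a rectangular graphene sheet in the x-y plane with a circular nanopore cut
  at its center (edges running along y are held fixed, edges along x are
  free),
* a 20-atom tetrahedral gold cluster (Au20) on ideal FCC sites, layers of
  1/3/6/10 atoms, intended for subsequent EAM relaxation,
* placement of a nucleotide over the pore at a prescribed base-plane tilt
  with the nanoparticle tip at a prescribed van der Waals gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import (MolecularSystem, TopologyError, angles_from_bonds,
                     merge_systems, new_system)

DEFAULT_CC_BOND = 1.42        # graphene C-C, Å
DEFAULT_AU_NN = 2.885         # FCC Au nearest-neighbour distance, Å


class PlacementError(ValueError):
    """Component placement failed (steric clash or impossible geometry)."""


@dataclass
class PlacementSpec:
    """Relative geometry of the assembled sensor system.

    tilt_deg
        tilt of the nucleobase plane relative to the z-x plane (rotation
        about the z axis), degrees in [0, 90].
    com_offset
        nucleotide center-of-mass position relative to the pore center, Å.
    np_gap
        minimum distance between the nanoparticle and the nearest
        nucleotide atom, Å (> 0).
    np_rotation
        (axis, angle_deg) rigid rotation applied to the nanoparticle about
        its own center of mass before placement.
    np_direction
        unit direction from the nucleotide c.o.m. along which the
        nanoparticle is backed off until the gap is met.
    """

    tilt_deg: float = 30.0
    com_offset: tuple = (0.0, 0.0, 12.0)
    np_gap: float = 4.0
    np_rotation: tuple | None = None
    np_direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.0 <= self.tilt_deg <= 90.0:
            raise ValueError("tilt_deg must be in [0, 90]")
        if self.np_gap <= 0:
            raise ValueError("np_gap must be positive")


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg``."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("rotation axis must be a nonzero vector")
    ux, uy, uz = axis / norm
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + s * k + (1 - c) * (k @ k)


# ---------------------------------------------------------------------------
# graphene

def honeycomb_sites(width: float, height: float, cc_bond: float) -> np.ndarray:
    """Enumerate honeycomb lattice sites inside a centred width x height box.

    The lattice is laid out with zigzag rows along x: a rectangular 4-atom
    cell of period (3*a, sqrt(3)*a).
    """
    a = cc_bond
    px, py = 3.0 * a, np.sqrt(3.0) * a
    basis = np.array([
        [0.0, 0.0],
        [a, 0.0],
        [1.5 * a, 0.5 * py],
        [2.5 * a, 0.5 * py],
    ])
    nx = int(np.ceil(width / px)) + 2
    ny = int(np.ceil(height / py)) + 2
    pts = []
    for i in range(-nx, nx + 1):
        for j in range(-ny, ny + 1):
            for b in basis:
                pts.append((i * px + b[0], j * py + b[1]))
    pts = np.asarray(pts)
    # centre the sheet on the centroid of retained atoms of the infinite
    # lattice patch: keep sites within the half-box about the origin
    keep = (np.abs(pts[:, 0]) <= width / 2 + 1e-9) & (np.abs(pts[:, 1]) <= height / 2 + 1e-9)
    pts = pts[keep]
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


def build_graphene_sheet(width: float, height: float, pore_diameter: float = 15.0,
                         cc_bond: float = DEFAULT_CC_BOND) -> MolecularSystem:
    """Build a graphene sheet with a circular pore cut at its center.

    Atoms closer to the sheet center (in-plane) than ``pore_diameter / 2``
    are removed, then rim atoms left with a single bond are pruned.  Atoms
    on the two edges running along the y axis are flagged fixed.
    """
    if cc_bond <= 0:
        raise ValueError("cc_bond must be positive")
    if pore_diameter > 0 and (width < 2 * pore_diameter or height < 2 * pore_diameter):
        raise ValueError(
            f"sheet {width} x {height} Å too small to contain a "
            f"{pore_diameter} Å pore: need at least twice the pore diameter")
    pts = honeycomb_sites(width, height, cc_bond)
    if pore_diameter > 0:
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) >= pore_diameter / 2]
    if len(pts) == 0:
        raise ValueError("no atoms remain after cutting the pore")

    def bond_pairs(p):
        out = []
        cut = 1.2 * cc_bond
        for i in range(len(p)):
            d = np.linalg.norm(p[i + 1:] - p[i], axis=1)
            for off in np.nonzero(d < cut)[0]:
                out.append((i, i + 1 + off))
        return np.asarray(out, dtype=int).reshape(-1, 2)

    # prune dangling rim atoms (single bond) until stable
    while True:
        bonds = bond_pairs(pts)
        deg = np.bincount(bonds.ravel(), minlength=len(pts)) if bonds.size else \
            np.zeros(len(pts), dtype=int)
        dangling = deg <= 1
        if not dangling.any():
            break
        pts = pts[~dangling]
        if len(pts) == 0:
            raise ValueError("pruning removed the whole sheet")

    positions = np.column_stack([pts, np.zeros(len(pts))])
    sys = new_system(["C"] * len(pts), positions, "graphene",
                     classes=["CG"] * len(pts), bonds=bonds)
    sys.angles = angles_from_bonds(bonds, sys.n_atoms)
    sys.torsions = np.empty((0, 4), dtype=int)
    # fix the edges along the y axis (extreme x); x edges remain free
    xmax = pts[:, 0].max()
    xmin = pts[:, 0].min()
    sys.fixed_mask = (pts[:, 0] > xmax - 1.01 * cc_bond) | (pts[:, 0] < xmin + 1.01 * cc_bond)
    sys.validate()
    return sys


# ---------------------------------------------------------------------------
# Au20

def build_au20(nn_distance: float = DEFAULT_AU_NN) -> MolecularSystem:
    """Ideal FCC tetrahedron of 20 Au atoms (layers 1, 3, 6, 10).

    Sites are ``i*a1 + j*a2 + k*a3`` with FCC primitive vectors of length
    ``nn_distance`` and ``i + j + k <= 3``; the cluster is then oriented so
    the 10-atom base face is normal to z with the apex above it at +z, and
    centred on its centroid.  No internal topology is generated: metallic
    cohesion is handled by the EAM potential.
    """
    if nn_distance <= 0:
        raise ValueError("nn_distance must be positive")
    a1 = np.array([1.0, 0.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3) / 2, 0.0])
    a3 = np.array([0.5, np.sqrt(3) / 6, np.sqrt(2.0 / 3.0)])
    sites, layer = [], []
    for s in range(4):
        for i in range(s + 1):
            for j in range(s - i + 1):
                k = s - i - j
                sites.append(i * a1 + j * a2 + k * a3)
                layer.append(s)
    pts = np.asarray(sites) * nn_distance
    layer = np.asarray(layer)
    # orient: base (layer 3) normal -> -z, apex (layer 0) on top
    apex = pts[layer == 0][0]
    base = pts[layer == 3]
    centroid = base.mean(axis=0)
    axis = apex - centroid
    axis /= np.linalg.norm(axis)
    target = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, target)
    if np.linalg.norm(v) > 1e-12:
        ang = np.rad2deg(np.arctan2(np.linalg.norm(v), axis @ target))
        pts = (rotation_matrix(v, ang) @ pts.T).T
    elif axis @ target < 0:
        pts = (rotation_matrix([1.0, 0.0, 0.0], 180.0) @ pts.T).T
    pts -= pts.mean(axis=0)
    order = np.lexsort((pts[:, 0], pts[:, 1], -pts[:, 2]))  # apex first
    sys = new_system(["Au"] * 20, pts[order], "nanoparticle", classes=["AU"] * 20)
    sys.validate()
    return sys


def au20_vertex_indices(sys: MolecularSystem) -> np.ndarray:
    """Indices of the four vertex (apex-region) atoms of the tetrahedron.

    The vertices are the atoms farthest from the cluster center of mass;
    robust to EAM relaxation and rigid rotation.
    """
    idx = sys.group_indices("nanoparticle")
    pos = sys.positions[idx]
    d = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
    return idx[np.argsort(d)[-4:]]


# ---------------------------------------------------------------------------
# assembly

def base_plane_normal(nucleotide: MolecularSystem) -> np.ndarray:
    """Best-fit normal of the nucleobase ring plane (SVD of ring atoms)."""
    idx = nucleotide.ring if nucleotide.ring.size else np.arange(nucleotide.n_atoms)
    pts = nucleotide.positions[idx]
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts, full_matrices=False)
    n = vt[-1]
    return n / np.linalg.norm(n)


def orient_nucleotide(nucleotide: MolecularSystem, tilt_deg: float) -> MolecularSystem:
    """Rotate so the base plane is the z-x plane, then tilt about z.

    At ``tilt_deg = 0`` the ring normal is parallel to the y axis.
    """
    out = nucleotide.copy()
    com = np.average(out.positions, axis=0, weights=out.masses)
    pos = out.positions - com
    normal = base_plane_normal(out)
    target = np.array([0.0, 1.0, 0.0])
    v = np.cross(normal, target)
    if np.linalg.norm(v) > 1e-12:
        ang = np.rad2deg(np.arctan2(np.linalg.norm(v), normal @ target))
        pos = (rotation_matrix(v, ang) @ pos.T).T
    elif normal @ target < 0:
        pos = (rotation_matrix([1.0, 0.0, 0.0], 180.0) @ pos.T).T
    if tilt_deg:
        pos = (rotation_matrix([0.0, 0.0, 1.0], tilt_deg) @ pos.T).T
    out.positions = pos + com
    return out


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.distance import cdist
    return float(cdist(a, b).min())


def place_components(graphene: MolecularSystem | None,
                     nucleotide: MolecularSystem,
                     nanoparticle: MolecularSystem | None,
                     spec: PlacementSpec | None = None) -> MolecularSystem:
    """Assemble the sensor system per the placement spec.

    The graphene sheet stays in the x-y plane at z = 0; the nucleotide is
    tilted to ``tilt_deg`` and its center of mass put at ``com_offset``
    from the pore center; the nanoparticle is moved in from
    ``np_direction`` until its closest approach to the nucleotide equals
    ``np_gap``.  Deterministic: identical inputs give identical coordinates.
    """
    spec = spec or PlacementSpec()
    parts = []
    if graphene is not None:
        parts.append(graphene.copy())
    nuc = orient_nucleotide(nucleotide, spec.tilt_deg)
    com = np.average(nuc.positions, axis=0, weights=nuc.masses)
    nuc.positions += np.asarray(spec.com_offset, dtype=float) - com
    parts.append(nuc)
    if nanoparticle is not None:
        np_sys = nanoparticle.copy()
        if spec.np_rotation is not None:
            rotations = spec.np_rotation
            if np.isscalar(rotations[1]):       # single (axis, angle) pair
                rotations = [rotations]
            c = np_sys.positions.mean(axis=0)
            for axis, angle in rotations:
                np_sys.positions = (rotation_matrix(axis, angle)
                                    @ (np_sys.positions - c).T).T + c
        direction = np.asarray(spec.np_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)
        # start far out along `direction`, bisect the approach distance so
        # the minimum NP-nucleotide distance equals np_gap
        np_com = np_sys.positions.mean(axis=0)
        nuc_com = np.asarray(spec.com_offset, dtype=float)
        span = (np.linalg.norm(nuc.positions - nuc_com, axis=1).max()
                + np.linalg.norm(np_sys.positions - np_com, axis=1).max())
        lo, hi = 0.0, span + spec.np_gap + 5.0

        def gap_at(t):
            shift = nuc_com + direction * t - np_com
            return _min_dist(np_sys.positions + shift, nuc.positions)

        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if gap_at(mid) < spec.np_gap:
                lo = mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        np_sys.positions += nuc_com + direction * t - np_com
        parts.append(np_sys)
    merged = merge_systems(*parts)
    # steric check across all groups
    labels = list(merged.groups)
    for gi in range(len(labels)):
        for gj in range(gi + 1, len(labels)):
            pa = merged.positions[merged.groups[labels[gi]]]
            pb = merged.positions[merged.groups[labels[gj]]]
            from scipy.spatial.distance import cdist
            d = cdist(pa, pb)
            bad = np.argwhere(d < 1.0)
            if len(bad):
                pairs = [(int(merged.groups[labels[gi]][i]),
                          int(merged.groups[labels[gj]][j])) for i, j in bad[:10]]
                raise PlacementError(
                    f"steric clash between {labels[gi]} and {labels[gj]}: "
                    f"atom pairs {pairs} closer than 1.0 Å")
    merged.validate()
    return merged


def rotate_nanoparticle(system: MolecularSystem, axis, angle_deg: float) -> MolecularSystem:
    """Rigid rotation of the nanoparticle group about its center of mass."""
    idx = system.group_indices("nanoparticle")
    if len(idx) == 0:
        raise ValueError("nanoparticle group is empty")
    rot = rotation_matrix(axis, angle_deg)
    out = system.copy()
    c = out.positions[idx].mean(axis=0)
    out.positions[idx] = (rot @ (out.positions[idx] - c).T).T + c
    out.velocities[idx] = (rot @ out.velocities[idx].T).T
    return out
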