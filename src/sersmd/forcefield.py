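"""Class-I intramolecular terms, harmonic graphene terms, and LJ cross terms.

Functional forms (see the bundled ``data/mm3_params.txt`` for parameters):

* bond stretch ``E = k (r - r0)^2 [1 + c3 (r - r0)]`` — harmonic with an
  optional cubic (anharmonic) correction, exposed as a switch,
* angle bend ``E = ka (theta - theta0)^2``,
* torsion ``E = sum_n (V_n / 2) (1 + cos(n phi - phase_n))``,
* Lennard-Jones 12-6 ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` energy-shifted
  to zero at the cutoff, with Lorentz–Berthelot mixing across classes and
  1-2 / 1-3 intramolecular exclusions.

Electrostatics are deliberately absent: the model treats all cross
interactions as van der Waals only.  All forces are exact analytic
gradients of the energies; Newton's third law holds term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .system import MolecularSystem


class MissingParameterError(KeyError):
    """A bond/angle/torsion class tuple has no parameter entry."""


@dataclass
class ForceFieldParams:
    """Parameter tables keyed by force-field class tuples.

    ``cubic_default`` is the cubic stretch coefficient (1/Å) applied to
    bonds whose table entry does not set one; 0 gives purely harmonic
    stretches, the MM3-style value is about -2.55/Å.
    """

    bonds: dict = field(default_factory=dict)      # (a,b) -> (k, r0, c3 or None)
    angles: dict = field(default_factory=dict)     # (a,b,c) -> (ka, theta0_deg)
    torsions: dict = field(default_factory=dict)   # (a,b,c,d) -> [(V, n, phase_deg)]
    lj: dict = field(default_factory=dict)         # class -> (eps, sigma)
    cubic_default: float = 0.0

    def bond(self, a: str, b: str):
        for key in ((a, b), (b, a)):
            if key in self.bonds:
                k, r0, c3 = self.bonds[key]
                return k, r0, (c3 if c3 is not None else self.cubic_default)
        raise MissingParameterError(f"no bond parameters for class pair ({a}, {b})")

    def angle(self, a: str, b: str, c: str):
        for key in ((a, b, c), (c, b, a), ("*", b, "*")):
            if key in self.angles:
                return self.angles[key]
        raise MissingParameterError(f"no angle parameters for class triple ({a}, {b}, {c})")

    def torsion(self, a: str, b: str, c: str, d: str):
        for key in ((a, b, c, d), (d, c, b, a), ("*", b, c, "*"), ("*", c, b, "*")):
            if key in self.torsions:
                return self.torsions[key]
        raise MissingParameterError(
            f"no torsion parameters for class quadruple ({a}, {b}, {c}, {d})")

    def lj_params(self, cls: str):
        if cls not in self.lj:
            raise MissingParameterError(f"no LJ parameters for class {cls}")
        return self.lj[cls]

    @classmethod
    def from_file(cls, path) -> "ForceFieldParams":
        out = cls()
        section = None
        with open(path) as f:
            for raw in f:
                line = raw.split("#")[0].strip()
                if not line:
                    continue
                if line.startswith("["):
                    section = line.strip("[]").lower()
                    continue
                p = line.split()
                if section == "bonds":
                    c3 = float(p[4]) if len(p) > 4 else None
                    out.bonds[(p[0], p[1])] = (float(p[2]), float(p[3]), c3)
                elif section == "angles":
                    out.angles[(p[0], p[1], p[2])] = (float(p[3]), float(p[4]))
                elif section == "torsions":
                    key = (p[0], p[1], p[2], p[3])
                    out.torsions.setdefault(key, []).append(
                        (float(p[4]), int(p[5]), float(p[6])))
                elif section == "lj":
                    out.lj[p[0]] = (float(p[1]), float(p[2]))
                else:
                    raise ValueError(f"parameter line outside a section: {line!r}")
        return out

    @classmethod
    def default(cls) -> "ForceFieldParams":
        with resources.as_file(resources.files("sersmd.data") / "mm3_params.txt") as p:
            return cls.from_file(p)


def mix_lj(eps_i: float, sigma_i: float, eps_j: float, sigma_j: float):
    """Lorentz–Berthelot mixing: geometric-mean eps, arithmetic-mean sigma."""
    return float(np.sqrt(eps_i * eps_j)), 0.5 * (sigma_i + sigma_j)


@dataclass
class PairExclusions:
    """Per-atom 1-2 and 1-3 bonded neighbour sets excluded from LJ."""

    excluded: set  # frozenset of sorted (i, j) pairs

    @classmethod
    def from_topology(cls, bonds: np.ndarray, n_atoms: int) -> "PairExclusions":
        nbrs: list[set] = [set() for _ in range(n_atoms)]
        for i, j in np.asarray(bonds, dtype=int).reshape(-1, 2):
            nbrs[i].add(j)
            nbrs[j].add(i)
        excl = set()
        for i in range(n_atoms):
            for j in nbrs[i]:
                excl.add(tuple(sorted((i, int(j)))))
                for k in nbrs[j]:
                    if k != i:
                        excl.add(tuple(sorted((i, int(k)))))
        return cls(excluded=excl)

    def __contains__(self, pair) -> bool:
        return tuple(sorted(pair)) in self.excluded


# ---------------------------------------------------------------------------
# vectorized kernels (shared by the nucleotide and graphene terms)

def _bond_kernel(pos, bonds, k, r0, c3):
    i, j = bonds[:, 0], bonds[:, 1]
    d = pos[j] - pos[i]
    r = np.linalg.norm(d, axis=1)
    dr = r - r0
    # a diverging run can push dr to inf; the integrator's divergence/
    # finiteness checks handle it, so suppress the transient warnings
    with np.errstate(over="ignore", invalid="ignore"):
        energy = np.sum(k * dr**2 * (1.0 + c3 * dr))
        dEdr = k * (2.0 * dr + 3.0 * c3 * dr**2)
    fpair = (dEdr / r)[:, None] * d          # dE/dp_j
    forces = np.zeros_like(pos)
    np.add.at(forces, j, -fpair)
    np.add.at(forces, i, fpair)
    return energy, forces


def _angle_kernel(pos, angles, ka, theta0_rad):
    i, j, k = angles[:, 0], angles[:, 1], angles[:, 2]
    u = pos[i] - pos[j]
    v = pos[k] - pos[j]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cost = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cost)
    sint = np.sqrt(np.maximum(1.0 - cost**2, 1e-12))
    dth = theta - theta0_rad
    energy = np.sum(ka * dth**2)
    dEdth = 2.0 * ka * dth
    uhat = u / nu[:, None]
    vhat = v / nv[:, None]
    dth_di = (cost[:, None] * uhat - vhat) / (nu * sint)[:, None]
    dth_dk = (cost[:, None] * vhat - uhat) / (nv * sint)[:, None]
    forces = np.zeros_like(pos)
    np.add.at(forces, i, -dEdth[:, None] * dth_di)
    np.add.at(forces, k, -dEdth[:, None] * dth_dk)
    np.add.at(forces, j, dEdth[:, None] * (dth_di + dth_dk))
    return energy, forces


def _torsion_kernel(pos, torsions, terms):
    """terms: list per torsion of [(V, n, phase_rad), ...]."""
    i, j, k, l = torsions[:, 0], torsions[:, 1], torsions[:, 2], torsions[:, 3]
    b1 = pos[j] - pos[i]
    b2 = pos[k] - pos[j]
    b3 = pos[l] - pos[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    phi = np.arctan2(np.einsum("ij,ij->i", np.cross(n1, n2), b2) / nb2,
                     np.einsum("ij,ij->i", n1, n2))
    energy = 0.0
    dEdphi = np.zeros(len(torsions))
    for t, tl in enumerate(terms):
        for V, n, phase in tl:
            energy += 0.5 * V * (1.0 + np.cos(n * phi[t] - phase))
            dEdphi[t] += -0.5 * V * n * np.sin(n * phi[t] - phase)
    sn1 = np.einsum("ij,ij->i", n1, n1)
    sn2 = np.einsum("ij,ij->i", n2, n2)
    dphi_di = -(nb2 / np.maximum(sn1, 1e-12))[:, None] * n1
    dphi_dl = (nb2 / np.maximum(sn2, 1e-12))[:, None] * n2
    p = (np.einsum("ij,ij->i", b1, b2) / nb2**2)[:, None]
    q = (np.einsum("ij,ij->i", b3, b2) / nb2**2)[:, None]
    dphi_dj = -(1.0 + p) * dphi_di + q * dphi_dl
    dphi_dk = -(1.0 + q) * dphi_dl + p * dphi_di
    forces = np.zeros_like(pos)
    np.add.at(forces, i, -dEdphi[:, None] * dphi_di)
    np.add.at(forces, j, -dEdphi[:, None] * dphi_dj)
    np.add.at(forces, k, -dEdphi[:, None] * dphi_dk)
    np.add.at(forces, l, -dEdphi[:, None] * dphi_dl)
    return energy, forces


def _topology_outside(system: MolecularSystem, arr: np.ndarray, group: str):
    """Rows of a topology array with at least one atom outside ``group``."""
    if arr.size == 0 or group not in system.groups:
        return arr
    members = np.zeros(system.n_atoms, dtype=bool)
    members[system.groups[group]] = True
    return arr[~members[arr].all(axis=1)]


def bonded_energy_forces(system: MolecularSystem, params: ForceFieldParams,
                         positions: np.ndarray | None = None):
    """Class-I bond + angle + torsion energy and forces for the molecule.

    Applies to all bonds/angles/torsions except those fully inside the
    graphene group (graphene has its own harmonic term).  Every topology
    entry must have a parameter; a missing entry raises
    :class:`MissingParameterError` naming the class tuple.
    """
    pos = system.positions if positions is None else positions
    forces = np.zeros_like(pos)
    energy = 0.0
    cls = system.classes

    bonds = _topology_outside(system, system.bonds, "graphene")
    if bonds.size:
        par = np.array([params.bond(cls[i], cls[j]) for i, j in bonds])
        e, f = _bond_kernel(pos, bonds, par[:, 0], par[:, 1], par[:, 2])
        energy += e
        forces += f
    angles = _topology_outside(system, system.angles, "graphene")
    if angles.size:
        par = np.array([params.angle(cls[i], cls[j], cls[k]) for i, j, k in angles])
        e, f = _angle_kernel(pos, angles, par[:, 0], np.deg2rad(par[:, 1]))
        energy += e
        forces += f
    torsions = _topology_outside(system, system.torsions, "graphene")
    if torsions.size:
        terms = [[(V, n, np.deg2rad(ph))
                  for V, n, ph in params.torsion(cls[i], cls[j], cls[k], cls[l])]
                 for i, j, k, l in torsions]
        e, f = _torsion_kernel(pos, torsions, terms)
        energy += e
        forces += f
    return energy, forces


def graphene_internal_forces(system: MolecularSystem,
                             kb: float = 469.0, ka: float = 63.0,
                             r0: float = 1.42, theta0_deg: float = 120.0,
                             positions: np.ndarray | None = None):
    """Harmonic bond/angle energy and forces over the graphene topology.

    A deliberate fidelity reduction from reactive bond-order chemistry: the
    sheet serves as a thermal and steric background, so harmonic terms about
    the ideal lattice (r0, 120 deg) suffice.  Fixed atoms still contribute
    forces to their neighbours; the integrator is what keeps them in place.
    """
    pos = system.positions if positions is None else positions
    forces = np.zeros_like(pos)
    energy = 0.0
    if "graphene" not in system.groups:
        return energy, forces
    members = np.zeros(system.n_atoms, dtype=bool)
    members[system.groups["graphene"]] = True
    bonds = system.bonds[members[system.bonds].all(axis=1)] if system.bonds.size else \
        system.bonds
    angles = system.angles[members[system.angles].all(axis=1)] if system.angles.size else \
        system.angles
    if bonds.size:
        e, f = _bond_kernel(pos, bonds, kb, r0, 0.0)
        energy += e
        forces += f
    if angles.size:
        e, f = _angle_kernel(pos, angles, ka, np.deg2rad(theta0_deg))
        energy += e
        forces += f
    return energy, forces


# ---------------------------------------------------------------------------
# Lennard-Jones cross interactions

class LJTerm:
    """Precomputed LJ pair interactions for a system.

    Pairs are (a) every inter-group pair (nucleotide-graphene,
    nucleotide-nanoparticle, nanoparticle-graphene) and (b) intra-nucleotide
    pairs beyond the 1-2/1-3 exclusions.  Energy-shifted to zero at the
    cutoff.
    """

    def __init__(self, system: MolecularSystem, params: ForceFieldParams,
                 exclusions: PairExclusions | None = None, cutoff: float = 10.0):
        self.cutoff = float(cutoff)
        if exclusions is None:
            exclusions = PairExclusions.from_topology(system.bonds, system.n_atoms)
        pairs = []
        labels = [g for g in system.groups if len(system.groups[g])]
        for gi in range(len(labels)):
            for gj in range(gi + 1, len(labels)):
                for i in system.groups[labels[gi]]:
                    for j in system.groups[labels[gj]]:
                        pairs.append((int(i), int(j)))
        if "nucleotide" in system.groups:
            idx = system.groups["nucleotide"]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    i, j = int(idx[a]), int(idx[b])
                    if (i, j) not in exclusions:
                        pairs.append((i, j))
        self.pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        eps_sig = [mix_lj(*params.lj_params(system.classes[i]),
                          *params.lj_params(system.classes[j]))
                   for i, j in self.pairs]
        es = np.asarray(eps_sig, dtype=float).reshape(-1, 2)
        self.eps = es[:, 0]
        self.sigma = es[:, 1]
        if self.sigma.size and self.cutoff <= self.sigma.max():
            raise ValueError(f"cutoff {cutoff} Å must exceed the largest sigma "
                             f"({self.sigma.max():.3f} Å)")
        sr6 = (self.sigma / self.cutoff) ** 6
        self.shift = 4.0 * self.eps * (sr6**2 - sr6)

    def energy_forces(self, positions: np.ndarray):
        forces = np.zeros_like(positions)
        if len(self.pairs) == 0:
            return 0.0, forces
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = positions[j] - positions[i]
        r2 = np.einsum("ij,ij->i", d, d)
        tiny = r2 < 0.01  # 0.1 Å overlap guard
        if tiny.any():
            a, b = self.pairs[np.argmax(tiny)]
            raise FloatingPointError(
                f"atom overlap: pair ({a}, {b}) closer than 0.1 Å")
        within = r2 < self.cutoff**2
        if not within.any():
            return 0.0, forces
        r2w = r2[within]
        sig2 = self.sigma[within] ** 2
        sr6 = (sig2 / r2w) ** 3
        epsw = self.eps[within]
        energy = float(np.sum(4.0 * epsw * (sr6**2 - sr6) - self.shift[within]))
        # dE/dr * (1/r) = -24 eps (2 sr12 - sr6) / r^2
        coef = (-24.0 * epsw * (2.0 * sr6**2 - sr6) / r2w)[:, None] * d[within]
        np.add.at(forces, j[within], -coef)
        np.add.at(forces, i[within], coef)
        return energy, forces


def lj_energy_forces(system: MolecularSystem, params: ForceFieldParams,
                     exclusions: PairExclusions | None = None,
                     cutoff: float = 10.0, positions: np.ndarray | None = None):
    """One-shot LJ evaluation (see :class:`LJTerm` for the pair rules)."""
    term = LJTerm(system, params, exclusions, cutoff)
    return term.energy_forces(system.positions if positions is None else positions)


class TotalForceField:
    """All interaction terms applicable to a system, callable on positions.

    Composes class-I intramolecular terms for the molecule, harmonic terms
    for graphene, LJ cross interactions, and EAM for the nanoparticle group
    (when an EAM potential is supplied).  ``total(positions)`` returns
    ``(energy, forces)`` and is the ``forces_fn`` consumed by the
    integrator.
    """

    def __init__(self, system: MolecularSystem, params: ForceFieldParams | None = None,
                 eam_potential=None, lj_cutoff: float = 10.0,
                 graphene_kb: float = 469.0, graphene_ka: float = 63.0,
                 graphene_r0: float = 1.42):
        from . import eam as _eam
        self.system = system
        self.params = params or ForceFieldParams.default()
        self.lj_cutoff = lj_cutoff
        self.graphene = (graphene_kb, graphene_ka, graphene_r0)
        if eam_potential is None and len(system.groups.get("nanoparticle", ())) > 0:
            eam_potential = _eam.default_au_potential()
        self.eam_potential = eam_potential
        self._lj = LJTerm(system, self.params, cutoff=lj_cutoff)
        self._has_molecule = bool(
            _topology_outside(system, system.bonds, "graphene").size)
        self._has_graphene = len(system.groups.get("graphene", ())) > 0

    def __call__(self, positions: np.ndarray):
        from . import eam as _eam
        energy = 0.0
        forces = np.zeros_like(positions)
        if self._has_molecule:
            e, f = bonded_energy_forces(self.system, self.params, positions=positions)
            energy += e
            forces += f
        if self._has_graphene:
            kb, ka, r0 = self.graphene
            e, f = graphene_internal_forces(self.system, kb=kb, ka=ka, r0=r0,
                                            positions=positions)
            energy += e
            forces += f
        e, f = self._lj.energy_forces(positions)
        energy += e
        forces += f
        if self.eam_potential is not None:
            e, f = _eam.eam_energy_forces(self.system, self.eam_potential,
                                          positions=positions)
            energy += e
            forces += f
        return energy, forces
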