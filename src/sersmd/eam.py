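"""Embedded-atom-method (EAM) potential for the gold nanoparticle.

``E = sum_i F(rho_i) + 1/2 sum_{i != j} V(r_ij)`` with host electron density
``rho_i = sum_{j != i} phi(r_ij)``.  The potential is table-driven: F, V and
phi are read from a plain-text funcfl-style single-element table and
cubic-spline interpolated, so forces are exact analytic gradients of the
interpolated tables.

The bundled table (``data/au_suttonchen.eam.txt``) is generated from the
published Sutton–Chen analytic EAM parameterisation for Au (n = 10, m = 8,
eps = 1.2793e-2 eV, c = 34.408, a = 4.08 Å) with a smooth switching taper
so that V and phi vanish at and beyond the cutoff.  Tables are stored in eV
and Å and converted to kcal/mol on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import CubicSpline

from .system import MolecularSystem
from .units import EV_TO_KCALMOL


@dataclass
class EAMPotential:
    """Cubic-interpolated single-element EAM tables (internal units kcal/mol, Å)."""

    r: np.ndarray          # pair-distance grid, Å (strictly increasing)
    rho: np.ndarray        # density grid (strictly increasing, from 0)
    F_tab: np.ndarray      # embedding energy F(rho), kcal/mol
    V_tab: np.ndarray      # pair potential V(r), kcal/mol
    phi_tab: np.ndarray    # electron density phi(r), dimensionless
    cutoff: float          # Å
    comment: str = ""

    def __post_init__(self):
        if np.any(np.diff(self.r) <= 0) or np.any(np.diff(self.rho) <= 0):
            raise ValueError("EAM table abscissae must be strictly increasing")
        self._F = CubicSpline(self.rho, self.F_tab)
        self._V = CubicSpline(self.r, self.V_tab)
        self._phi = CubicSpline(self.r, self.phi_tab)
        self._dF = self._F.derivative()
        self._dV = self._V.derivative()
        self._dphi = self._phi.derivative()

    def _check_range(self, r: np.ndarray):
        if np.any(r < self.r[0]):
            raise ValueError(
                f"atom pair at {float(np.min(r)):.3f} Å below EAM table minimum "
                f"{self.r[0]:.3f} Å")

    def V(self, r):
        r = np.asarray(r, dtype=float)
        self._check_range(r)
        return np.where(r < self.cutoff, self._V(np.minimum(r, self.cutoff)), 0.0)

    def phi(self, r):
        r = np.asarray(r, dtype=float)
        self._check_range(r)
        return np.where(r < self.cutoff, self._phi(np.minimum(r, self.cutoff)), 0.0)

    def F(self, rho):
        return self._F(np.asarray(rho, dtype=float))

    def dV(self, r):
        r = np.asarray(r, dtype=float)
        return np.where(r < self.cutoff, self._dV(np.minimum(r, self.cutoff)), 0.0)

    def dphi(self, r):
        r = np.asarray(r, dtype=float)
        return np.where(r < self.cutoff, self._dphi(np.minimum(r, self.cutoff)), 0.0)

    def dF(self, rho):
        return self._dF(np.asarray(rho, dtype=float))


def _switch(r, r_on, r_off):
    """CHARMM-style C1 switching function, 1 below r_on, 0 beyond r_off."""
    r = np.asarray(r, dtype=float)
    r2, on2, off2 = r**2, r_on**2, r_off**2
    s = ((off2 - r2) ** 2 * (off2 + 2 * r2 - 3 * on2)) / (off2 - on2) ** 3
    return np.where(r <= r_on, 1.0, np.where(r >= r_off, 0.0, s))


def make_sutton_chen_au(n_r: int = 800, n_rho: int = 800,
                        r_min: float = 1.5, cutoff: float = 10.0,
                        r_on: float = 8.5, rho_max: float = 400.0) -> EAMPotential:
    """Tabulate the Sutton–Chen analytic EAM for Au.

    V(r) = eps (a/r)^10 (tapered), phi(r) = (a/r)^8 (tapered),
    F(rho) = -c eps sqrt(rho), with the published Au constants.
    """
    eps_ev = 1.2793e-2
    c = 34.408
    a = 4.08
    r = np.linspace(r_min, cutoff, n_r)
    sw = _switch(r, r_on, cutoff)
    V = eps_ev * (a / r) ** 10 * sw * EV_TO_KCALMOL
    phi = (a / r) ** 8 * sw
    rho = np.linspace(0.0, rho_max, n_rho)
    F = -c * eps_ev * np.sqrt(rho) * EV_TO_KCALMOL
    return EAMPotential(r=r, rho=rho, F_tab=F, V_tab=V, phi_tab=phi, cutoff=cutoff,
                        comment="Sutton-Chen analytic EAM for Au (n=10 m=8 "
                                "eps=1.2793e-2eV c=34.408 a=4.08A), switch-tapered")


# ---------------------------------------------------------------------------
# funcfl-style text table IO (single element; V stored directly in eV)

def write_funcfl(path, pot: EAMPotential) -> None:
    nr, nrho = len(pot.r), len(pot.rho)
    dr = pot.r[1] - pot.r[0]
    drho = pot.rho[1] - pot.rho[0]
    with open(path, "w") as f:
        f.write(f"# {pot.comment} | columns: F(rho)[eV], V(r)[eV], phi(r); eV/Angstrom\n")
        f.write("79 196.96657 4.08 fcc\n")
        f.write(f"{nrho} {drho:.10g} {nr} {dr:.10g} {pot.cutoff:.10g} {pot.r[0]:.10g}\n")
        for tab, scale in ((pot.F_tab, 1 / EV_TO_KCALMOL),
                           (pot.V_tab, 1 / EV_TO_KCALMOL),
                           (pot.phi_tab, 1.0)):
            vals = tab * scale
            for k in range(0, len(vals), 5):
                f.write(" ".join(f"{v: .10e}" for v in vals[k:k + 5]) + "\n")


def read_funcfl(path) -> EAMPotential:
    with open(path) as f:
        comment = f.readline().lstrip("#").strip()
        f.readline()  # element line (single-element table)
        hdr = f.readline().split()
        nrho, drho, nr, dr, cutoff, rmin = (int(hdr[0]), float(hdr[1]), int(hdr[2]),
                                            float(hdr[3]), float(hdr[4]), float(hdr[5]))
        vals = np.array(f.read().split(), dtype=float)
    if len(vals) != nrho + 2 * nr:
        raise ValueError(f"{path}: expected {nrho + 2 * nr} table values, got {len(vals)}")
    F = vals[:nrho] * EV_TO_KCALMOL
    V = vals[nrho:nrho + nr] * EV_TO_KCALMOL
    phi = vals[nrho + nr:]
    return EAMPotential(
        r=rmin + dr * np.arange(nr), rho=drho * np.arange(nrho),
        F_tab=F, V_tab=V, phi_tab=phi, cutoff=cutoff, comment=comment)


def default_au_potential() -> EAMPotential:
    """The bundled Au table."""
    with resources.as_file(resources.files("sersmd.data") / "au_suttonchen.eam.txt") as p:
        return read_funcfl(p)


# ---------------------------------------------------------------------------
# energy/forces and relaxation

def eam_energy_forces(system: MolecularSystem, pot: EAMPotential,
                      positions: np.ndarray | None = None):
    """EAM energy and forces over the nanoparticle group.

    Forces on all other atoms are zero; metallic cohesion does not couple
    to the molecular force field except through LJ cross terms.
    """
    pos_all = system.positions if positions is None else positions
    idx = system.groups.get("nanoparticle", np.empty(0, dtype=int))
    forces = np.zeros_like(pos_all)
    if len(idx) == 0:
        return 0.0, forces
    pos = pos_all[idx]
    n = len(pos)
    if n == 1:
        return float(pot.F(0.0)), forces
    d = pos[:, None, :] - pos[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    np.fill_diagonal(r, np.inf)
    pot._check_range(r[np.isfinite(r)])
    within = r < pot.cutoff
    rc = np.where(within, r, pot.cutoff)  # clamped for spline safety
    phi = np.where(within, pot._phi(rc), 0.0)
    V = np.where(within, pot._V(rc), 0.0)
    rho_i = phi.sum(axis=1)
    energy = float(np.sum(pot.F(rho_i)) + 0.5 * V.sum())
    dF = pot.dF(rho_i)
    dphi = np.where(within, pot._dphi(rc), 0.0)
    dV = np.where(within, pot._dV(rc), 0.0)
    # pair force magnitude: dE/dr_ij = dF_i dphi + dF_j dphi + dV
    coef = (dF[:, None] + dF[None, :]) * dphi + dV
    with np.errstate(invalid="ignore"):
        fvec = np.where(within[..., None], (coef / r)[..., None] * d, 0.0)
    forces[idx] = -np.nansum(fvec, axis=1)
    return energy, forces


def normal_mode_frequencies(system: MolecularSystem, pot: EAMPotential,
                            h: float = 1e-4) -> np.ndarray:
    """Harmonic normal-mode frequencies (cm^-1) of the nanoparticle group.

    Mass-weighted Hessian by central differences of the analytic EAM
    forces; the six near-zero rigid-body modes come out as ~0.  Serves as
    the harmonic reference for the vibrational band of the cluster: VACF
    spectral peaks of a (quasi)harmonic cluster lie within this band.
    """
    from .units import FORCE_TO_ACC, THZ_TO_CM1
    idx = system.group_indices("nanoparticle")
    n = len(idx)
    hess = np.zeros((3 * n, 3 * n))
    for a in range(n):
        for k in range(3):
            p = system.positions.copy()
            p[idx[a], k] += h
            _, fp = eam_energy_forces(system, pot, positions=p)
            p[idx[a], k] -= 2 * h
            _, fm = eam_energy_forces(system, pot, positions=p)
            hess[3 * a + k] = (-(fp - fm)[idx] / (2 * h)).ravel()
    hess = 0.5 * (hess + hess.T)
    m = np.repeat(system.masses[idx], 3)
    w2 = np.linalg.eigvalsh(hess / np.sqrt(np.outer(m, m)))
    freq_inv_fs = np.sqrt(np.clip(w2, 0.0, None) * FORCE_TO_ACC) / (2.0 * np.pi)
    return freq_inv_fs * 1e3 * THZ_TO_CM1


def relax_nanoparticle(system: MolecularSystem, pot: EAMPotential,
                       tol: float = 1e-8, maxiter: int = 2000) -> MolecularSystem:
    """Minimise the EAM energy of the nanoparticle group (L-BFGS)."""
    from scipy.optimize import minimize
    out = system.copy()
    idx = out.group_indices("nanoparticle")
    shape = out.positions[idx].shape

    def fun(x):
        p = out.positions.copy()
        p[idx] = x.reshape(shape)
        e, f = eam_energy_forces(out, pot, positions=p)
        return e, -f[idx].ravel()

    res = minimize(fun, out.positions[idx].ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": tol * 1e-6,
                            "gtol": tol * 1e2})
    out.positions[idx] = res.x.reshape(shape)
    return out
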