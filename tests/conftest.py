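import numpy as np
import pytest

from sersmd.eam import default_au_potential, relax_nanoparticle
from sersmd.forcefield import ForceFieldParams, bonded_energy_forces
from sersmd.geometry import build_au20, build_graphene_sheet
from sersmd.md import SimulationConfig, run_simulation
from sersmd.presets import load_nucleoside
from sersmd.system import new_system


@pytest.fixture(scope="session")
def params():
    return ForceFieldParams.default()


@pytest.fixture(scope="session")
def au_potential():
    return default_au_potential()


@pytest.fixture(scope="session")
def cytidine():
    return load_nucleoside("cytidine")


@pytest.fixture(scope="session")
def hmc():
    return load_nucleoside("hmc")


@pytest.fixture(scope="session")
def au20_relaxed(au_potential):
    return relax_nanoparticle(build_au20(), au_potential)


@pytest.fixture(scope="session")
def graphene_small():
    return build_graphene_sheet(34.0, 34.0, 15.0)


@pytest.fixture()
def diatomic_factory():
    """Harmonic diatomic with tunable stiffness and masses."""

    def make(k=310.0, elements=("C", "C"), r0=1.50, r_start=1.54, cubic=None):
        sys = new_system(list(elements), [[0, 0, 0], [0, 0, r_start]],
                         "nucleotide", bonds=[[0, 1]])
        par = ForceFieldParams(
            bonds={(sys.classes[0], sys.classes[1]): (k, r0, cubic)})
        return sys, par, (lambda p, s=sys, pr=par:
                          bonded_energy_forces(s, pr, positions=p))

    return make


def simulate_nve(system, forces_fn, n_steps, dt=0.05, record_stride=1, seed=0,
                 temperatures=None, equilibration_steps=0, com_velocity=None):
    cfg = SimulationConfig(dt=dt, n_steps=n_steps, record_stride=record_stride,
                           temperatures=temperatures or {}, seed=seed,
                           equilibration_steps=equilibration_steps,
                           com_velocity=com_velocity)
    return run_simulation(system, cfg, forces_fn)


def numerical_forces(positions, efun, h=1e-6):
    """Central-difference gradient oracle for any energy function."""
    num = np.zeros_like(positions)
    for i in range(len(positions)):
        for k in range(3):
            p = positions.copy()
            p[i, k] += h
            ep, _ = efun(p)
            p[i, k] -= 2 * h
            em, _ = efun(p)
            num[i, k] = -(ep - em) / (2 * h)
    return num
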