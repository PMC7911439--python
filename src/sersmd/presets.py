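"""Experiment presets: the interaction scenarios the simulator reproduces.

Each preset bundles the placement geometry and run parameters of one
scenario — the isolated relaxed Au20 cluster, the free nucleoside, the
static nucleoside–nanoparticle pair at a 4 Å van der Waals gap, the same
pair with the nanoparticle flipped so an edge of its base face points at
the molecule, and driven translocation through the graphene nanopore.
Every field is individually overridable; every preset runs end-to-end
offline from the bundled fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .eam import default_au_potential, relax_nanoparticle
from .forcefield import ForceFieldParams, TotalForceField
from .geometry import PlacementSpec, build_au20, build_graphene_sheet, place_components
from .md import SimulationConfig
from .system import MolecularSystem, load_structure

T_GRAPHENE = 300.0        # K
T_NUCLEOTIDE = 303.15     # K (30 °C)
T_NANOPARTICLE = 300.0    # K
VZ_DEFAULT = 25.0         # Å/ps, driven translocation velocity

# Fig-panel bond set of the cytosine base (1-based labels in fixture order)
CYTOSINE_PANEL_BONDS = ("C(2)-C(3)", "C(2)-N(5)", "C(3)-H(10)", "C(1)-O(12)")

# flip the pyramid so its 10-atom base face becomes the upper plane, then
# rotate about z to aim a base edge at the molecule
ROTATED_NP = [((1.0, 0.0, 0.0), 180.0), ((0.0, 0.0, 1.0), 30.0)]


@dataclass
class ExperimentPreset:
    name: str
    include_graphene: bool = False
    include_nucleotide: bool = True
    include_np: bool = False
    sheet: tuple = (34.0, 34.0, 15.0)      # width, height, pore diameter (Å)
    placement: PlacementSpec = field(default_factory=PlacementSpec)
    config: SimulationConfig = field(default_factory=SimulationConfig)
    relax_np: bool = True


def _base_config(**over) -> SimulationConfig:
    defaults = dict(
        dt=0.05, n_steps=32768, record_stride=1,
        temperatures={"graphene": T_GRAPHENE, "nucleotide": T_NUCLEOTIDE,
                      "nanoparticle": T_NANOPARTICLE},
        equilibration_steps=2000, seed=0,
    )
    defaults.update(over)
    return SimulationConfig(**defaults)


_PRESETS = {
    "au20_alone": ExperimentPreset(
        name="au20_alone", include_nucleotide=False, include_np=True,
        config=_base_config(),
    ),
    "nucleotide_alone": ExperimentPreset(
        name="nucleotide_alone",
        placement=PlacementSpec(tilt_deg=30.0),
        config=_base_config(),
    ),
    "nucleotide_np_static": ExperimentPreset(
        name="nucleotide_np_static", include_np=True,
        placement=PlacementSpec(tilt_deg=30.0, np_gap=4.0),
        config=_base_config(),
    ),
    "nucleotide_np_rotated": ExperimentPreset(
        name="nucleotide_np_rotated", include_np=True,
        placement=PlacementSpec(tilt_deg=30.0, np_gap=4.0, np_rotation=ROTATED_NP),
        config=_base_config(),
    ),
    "translocation": ExperimentPreset(
        name="translocation", include_graphene=True, include_np=True,
        placement=PlacementSpec(tilt_deg=30.0, np_gap=4.0,
                                com_offset=(0.0, 0.0, -12.0)),
        config=_base_config(com_velocity=("nucleotide", (0.0, 0.0, VZ_DEFAULT))),
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def get_preset(name: str, **overrides) -> ExperimentPreset:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {preset_names()}")
    p = _PRESETS[name]
    cfg_over = {k: overrides.pop(k) for k in list(overrides)
                if hasattr(SimulationConfig, "__dataclass_fields__")
                and k in SimulationConfig.__dataclass_fields__}
    p = replace(p, **overrides)
    if cfg_over:
        p = replace(p, config=replace(p.config, **cfg_over))
    return p


def bundled_path(name: str):
    return resources.as_file(resources.files("sersmd.data") / name)


def load_nucleoside(kind: str = "cytidine") -> MolecularSystem:
    """Load a bundled idealized nucleoside fixture (cytidine or hmc)."""
    with bundled_path(f"{kind}.xyz") as xyz, bundled_path(f"{kind}.top") as top:
        return load_structure(xyz, top)


def build_preset_system(preset: ExperimentPreset | str,
                        nucleoside: str = "cytidine") -> MolecularSystem:
    """Assemble (and EAM-relax, where the nanoparticle is present) a preset."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    graphene = build_graphene_sheet(*preset.sheet) if preset.include_graphene else None
    npart = None
    if preset.include_np:
        npart = build_au20()
        if preset.relax_np:
            npart = relax_nanoparticle(npart, default_au_potential())
    if not preset.include_nucleotide:
        if npart is None:
            raise ValueError(f"preset {preset.name}: nothing to build")
        if graphene is None:
            npart.validate()
            return npart
        from .system import merge_systems
        merged = merge_systems(graphene, npart)
        return merged
    nuc = load_nucleoside(nucleoside)
    return place_components(graphene, nuc, npart, preset.placement)


def make_forces(system: MolecularSystem,
                params: ForceFieldParams | None = None) -> TotalForceField:
    """Force field covering every group present in the system."""
    return TotalForceField(system, params=params)


def panel_bond_indices(system: MolecularSystem) -> dict[str, tuple[int, int]]:
    """0-based atom index pairs of the four panel bonds of the cytosine base."""
    out = {}
    for label in CYTOSINE_PANEL_BONDS:
        a, b = label.split("-")
        i = int(a[a.index("(") + 1:a.index(")")]) - 1
        j = int(b[b.index("(") + 1:b.index(")")]) - 1
        nuc = system.groups["nucleotide"]
        out[label] = (int(nuc[i]), int(nuc[j]))
    return out


def measure_au20_cluster_mode(seed: int = 0, n_steps: int = 32768,
                              n_runs: int = 8, dt: float = 0.05,
                              equilibration_steps: int = 2000):
    """The basic cluster mode of the isolated, EAM-relaxed Au20.

    Runs ``n_runs`` NVE samplings at 300 K from independently thermalized
    initial states (run-to-run randomization), averages each vertex atom's
    summed-Cartesian DOS over runs, subtracts the transient decay, and
    detects modes per atom.  Returns ``(mode_cm1, per_atom_modes, bin_cm1)``
    where ``mode_cm1`` is the basic cluster mode: the highest-frequency
    mode common to all four apex-region atoms (matched within one
    frequency bin) inside the cluster's harmonic vibrational band.  The
    stiff apex band at the top of the spectrum is orientation-stable and
    characterises the whole cluster, unlike the interaction-sensitive soft
    shear band; candidates above the harmonic band edge (from the EAM
    Hessian) are background-subtraction artifacts and are excluded.
    """
    from .eam import default_au_potential, normal_mode_frequencies
    from .geometry import au20_vertex_indices
    from .md import run_simulation
    from .spectra import (average_spectra, detect_peaks, spectrum_of_series,
                          subtract_decay_twopass)
    au = build_preset_system("au20_alone")
    band_edge = float(normal_mode_frequencies(au, default_au_potential()).max())
    forces = make_forces(au)
    verts = au20_vertex_indices(au)
    raw: dict[int, list] = {int(a): [] for a in verts}
    for run in range(n_runs):
        cfg = SimulationConfig(dt=dt, n_steps=n_steps, record_stride=1,
                               temperatures={"nanoparticle": T_NANOPARTICLE},
                               equilibration_steps=equilibration_steps,
                               seed=seed + 1000 * run)
        traj = run_simulation(au, cfg, forces, record_atoms=verts)
        for a in verts:
            v = traj.velocity_of(int(a))
            raw[int(a)].append([
                spectrum_of_series(v[:, ax], traj.dt,
                                   source=f"atom {int(a) + 1} {'xyz'[ax]}")
                for ax in range(3)])
    # per atom: detect per Cartesian axis (a mode present in any axis is
    # present in the atom's spectra), union the axis mode lists
    per_atom = {}
    bin_cm1 = None
    for a, runs in raw.items():
        modes = []
        for ax in range(3):
            spec = subtract_decay_twopass(
                average_spectra([r[ax] for r in runs]))
            modes.extend(detect_peaks(spec, rel_threshold=0.1))
            bin_cm1 = spec.bin_cm1
        per_atom[a] = sorted(modes, key=lambda m: -m.intensity)
    lists = list(per_atom.values())
    candidates = sorted({m.freq_cm1 for lst in lists for m in lst
                         if m.freq_cm1 <= band_edge + bin_cm1 + 1e-9})
    common = [f for f in candidates
              if all(any(abs(o.freq_cm1 - f) <= bin_cm1 + 1e-9 for o in lst)
                     for lst in lists)]
    mode_cm1 = common[-1] if common else float("nan")
    return mode_cm1, per_atom, bin_cm1


def ring_bond_labels(system: MolecularSystem) -> list[str]:
    """Labels of the six pyrimidine ring bonds, in fixture numbering."""
    nuc = system.groups["nucleotide"]
    local = {int(a): n for n, a in enumerate(nuc)}
    ring = [local[int(i)] for i in system.ring]
    labels = []
    for t in range(len(ring)):
        i, j = ring[t], ring[(t + 1) % len(ring)]
        ei = system.elements[nuc[i]]
        ej = system.elements[nuc[j]]
        labels.append(f"{ei}({i + 1})-{ej}({j + 1})")
    return labels
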