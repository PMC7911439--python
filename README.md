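# sersmd

Desk-scale molecular-dynamics model of a SERS (surface-enhanced Raman
scattering) nanosensor, with a transient vibrational-spectroscopy pipeline.

A single DNA nucleoside passing a graphene nanopore is probed by a small
plasmonic enhancer — a 20-atom tetrahedral gold cluster (Au20) — and its
vibrational fingerprint shifts in response to the van der Waals contact.
`sersmd` simulates that system and extracts bond-resolved vibrational
density-of-states (DOS) maps, for people who want to predict which *marker
frequencies* identify a molecule–nanoparticle interaction condition before
doing the experiment.

## Model

* **Nucleotide** (bundled idealized 2′-deoxycytidine and
  5-hydroxymethyl-deoxycytidine fixtures): class-I intramolecular force
  field — harmonic-plus-cubic bond stretch `E = k Δr²(1 + c₃Δr)`, harmonic
  angle bend, cosine torsions — from an editable plain-text parameter table.
* **Graphene sheet with nanopore** (1.5 nm pore, edges along *y* fixed):
  harmonic bond/angle lattice terms about the ideal honeycomb geometry.
* **Au20 nanoparticle**: ideal FCC tetrahedron (layers 1/3/6/10) relaxed
  with a tabulated embedded-atom-method (EAM) potential,
  `E = Σᵢ F(ρᵢ) + ½ Σ V(rᵢⱼ)`; the bundled table is a Sutton–Chen
  parameterisation for Au.
* **Cross interactions**: Lennard-Jones 12-6 with Lorentz–Berthelot mixing
  (ε(Au–Au) = 0.039 kcal/mol, σ(Au–Au) = 2.9 Å); no electrostatics.
* **Dynamics**: velocity-Verlet, per-group velocity-rescaling equilibration
  (graphene 300 K, nucleotide 303.15 K), strictly NVE sampling; optional
  constant center-of-mass drive (default 25 Å/ps along +z) as the kinematic
  surrogate for field-driven translocation.

The analysis is the Wiener–Khinchin route to the vibrational DOS: the
normalized velocity autocorrelation function

    G(τ) = ⟨v(t₀)·v(t₀+τ)⟩ / ⟨v(t₀)·v(t₀)⟩,   I(f) = |∫ G(τ) e^(−2πifτ) dτ|

computed per reaction coordinate — each atom's velocity projected on the
instantaneous bond axis (stretch) or perpendicular to it within the angle
plane (bend). At the working resolution (Δt = 0.05 fs, 32 768 steps →
1.6384 ps window) the DOS grid spacing is 20 cm⁻¹. Transient spectra carry
an exponentially decaying background; a two-parameter fit `a·exp(b·f)` to
the low-frequency (head) or high-frequency (tail) region is subtracted
before peak detection. Modes are classified stretch / bend / breathing (a
frequency shared by all six ring bonds), and per-bond mode tables from two
interaction conditions are differenced into a marker-frequency shift table.

## Worked example

Simulate the isolated relaxed Au20 cluster at 300 K and look at a tip
atom's spectra:

```
$ sersmd build --preset au20_alone --out scratch/au20.xyz
[sersmd] group nanoparticle: 20 atoms
[sersmd] wrote scratch/au20.xyz and scratch/au20.top

$ sersmd run --preset au20_alone --steps 32768 --seed 1 --out scratch/au20.h5
[sersmd] run: 20 atoms, dt = 0.05 fs, 32768 steps (+2000 equilibration), seed = 1
[sersmd] wrote 32768 records to scratch/au20.h5

$ sersmd spectra --traj scratch/au20.h5 --atoms 1 --out-dir scratch/spec
[sersmd] atom 1: wrote x, y, z spectra
```

The spectrum CSVs have a 20.36 cm⁻¹ grid (1/(32 768 × 0.05 fs), converted
at 1 THz = 33.35641 cm⁻¹). Averaging the vertex atoms' spectra over eight
independently thermalized runs and subtracting the decay background (the
`measure_au20_cluster_mode` helper does exactly this) gives the basic
cluster mode:

```python
>>> from sersmd.presets import measure_au20_cluster_mode
>>> mode_cm1, per_atom, bin_cm1 = measure_au20_cluster_mode(seed=1)
>>> round(mode_cm1, 1), round(bin_cm1, 1)
(203.6, 20.4)
```

i.e. a stable cluster-characterising mode at 203.6 cm⁻¹ shared by all four
apex atoms — one grid bin of the harmonic band edge of the relaxed
cluster (the EAM Hessian puts the stiff apex modes at 183–187 cm⁻¹).
Comparing a cytosine run with and without the nanoparticle at a 4 Å gap
(`sersmd compare`) yields a shift table over the four base bonds
C(2)–C(3), C(2)–N(5), C(3)–H(10), C(1)–O(12) whose nonzero rows are the
interaction markers.

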