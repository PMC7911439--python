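# Methods

`sersmd` is a desk-scale model of a SERS nanosensor: one nucleoside, one
Au20 cluster, one graphene nanopore, classical dynamics, and a transient
vibrational-spectroscopy pipeline. This note records the model, the
parameter choices that matter, what the synthetic study conditions do and
do not emulate, and the numerical decisions a maintainer would want
spelled out.

## System and interactions

**Components.** The graphene sheet is a honeycomb lattice in the x-y plane
(C-C 1.42 Å) with a circular pore (default diameter 15 Å) cut at its
center; atoms left with a single bond after the cut are pruned, since rim
chemistry is not modelled. The default sheet (34 × 34 Å) leaves ≥ 8 Å of
intact lattice around the pore. The two edges running along y are held
fixed; the x edges are free. The Au20 cluster is built on ideal FCC sites
as a 4-layer tetrahedron (1/3/6/10 atoms, nearest-neighbour 2.885 Å) and
then relaxed in the EAM potential (L-BFGS on the analytic gradient).
Nucleosides ship as idealized fixtures: 2′-deoxycytidine (29 atoms) and
its 5-hydroxymethyl variant (33 atoms), with geometry from an MMFF-level
optimization and a plain-text topology sidecar (bonds; angles/torsions
derived; ring membership listed for breathing-mode classification). Atom
numbering is 1-based in file order, so bond labels such as C(2)-C(3) are
stable identifiers.

**Intramolecular force field (nucleoside).** Class-I terms:
stretch `E = k (r − r0)² [1 + c₃ (r − r0)]`, bend `E = kθ (θ − θ0)²`,
torsion `E = Σ (Vn/2)(1 + cos(nφ − γ))`. The parameter table
(`data/mm3_params.txt`) is pre-filled with published class-I magnitudes
for the classes present (sp2/sp3 C, N, carbonyl/hydroxyl O, H by host
atom); it is deliberately editable, and the cubic stretch coefficient is
exposed as a switch (`ForceFieldParams.cubic_default`, 0 by default,
−2.55 Å⁻¹ is the customary anharmonic value). Consequence: absolute
nucleoside peak positions are *not* calibrated against any published
spectrum; correctness is established by closed forms and
finite-difference gradient checks, and by frequency recovery of harmonic
oscillators through the whole pipeline.

**Graphene.** Harmonic bond (469 kcal/mol/Å², r0 = 1.42 Å) and angle
(63 kcal/mol/rad², 120°) terms about the ideal lattice. This is a
deliberate fidelity reduction from reactive bond-order chemistry: in this
model the sheet is a thermal and steric background (its own spectrum is
not an analysis target), so lattice-scale elasticity suffices.

**Gold.** Embedded-atom method, `E = Σ F(ρᵢ) + ½ Σ V(rᵢⱼ)`,
`ρᵢ = Σ φ(rᵢⱼ)`, table-driven with cubic-spline interpolation so forces
are exact gradients of the interpolated tables. The bundled table
(`data/au_suttonchen.eam.txt`, funcfl-style plain text, eV/Å, converted
to kcal/mol on load) is generated from the published Sutton–Chen
parameterisation for Au (n = 10, m = 8, ε = 1.2793·10⁻² eV, c = 34.408,
a = 4.08 Å) with a C¹ switching taper from 8.5 Å so V and φ vanish at the
10 Å cutoff. Any funcfl-style single-element table can be substituted.

**Cross interactions.** Lennard-Jones 12-6, energy-shifted to zero at a
10 Å cutoff, Lorentz–Berthelot mixing from per-class (ε, σ); Au-Au uses
ε = 0.039 kcal/mol, σ = 2.9 Å, and graphene carbon uses the sp3-carbon
values. Applied between every group pair and to intra-nucleoside pairs
beyond 1-2/1-3 exclusions. Electrostatics are omitted throughout — the
model treats all contacts as van der Waals, consistent with the absence
of solvent.

## Dynamics

Velocity Verlet in (Å, fs, amu, kcal/mol) units
(1 kcal/mol/Å/amu = 4.184·10⁻⁴ Å/fs²). Initial velocities are a
Maxwell-Boltzmann draw per group with group net momentum removed and an
exact rescale to the target temperature (graphene 300 K, nucleoside
303.15 K, nanoparticle 300 K). Equilibration uses plain velocity
rescaling every 10 steps — chosen over stronger thermostats because
sampling must be strictly NVE: any thermostat coupling during sampling
would contaminate the velocity autocorrelation. Fixed atoms never move;
free boundaries everywhere (no periodic images). Translocation is driven
kinematically: the nucleoside's center-of-mass velocity is re-pinned
every step (default 25 Å/ps along +z, configurable), preserving internal
velocities; this reproduces the steady drift of a field-driven molecule
without modelling the field. Initial-state randomization multiplies
displacements from the group c.o.m. and velocities by (1 + u),
u ~ U(−f, f), f up to 0.15, seeded. Runs are bit-reproducible for a fixed
seed and configuration.

Default study conditions: Δt = 0.05 fs and 32 768 sampling steps
(1.6384 ps window, 20.36 cm⁻¹ DOS bins; a half window gives 40.7 cm⁻¹),
2000-step equilibration; cluster-only relaxation runs use Δt = 0.1 fs,
3000 steps. Over the full window the nucleoside + Au20 system conserves
NVE energy to ~3·10⁻⁷ relative (tested bound 10⁻⁴).

## Spectroscopy pipeline

1. **Projection.** Stretch coordinate: each bond-end atom's velocity
   projected on the instantaneous unit bond vector (one series per end —
   the two ends carry different band sets). Bend coordinate: end-atom
   velocity component perpendicular to its bond within the instantaneous
   angle plane; out-of-plane motion is excluded by construction.
2. **VACF.** `G(τ)` is estimated over all admissible time origins with
   the FFT-based biased (1/N) estimator, normalized so G(0) = 1. The
   biased form is positive semidefinite, which guarantees |G(τ)| ≤ 1 and
   makes the DOS the exact Wiener-Khinchin counterpart of the estimator;
   the price is a (1 − τ/N) envelope on each harmonic component, i.e. a
   Fejér-kernel broadening of the spectrum rather than sidelobe ringing.
3. **DOS.** One-sided magnitude of the DFT of G over N lags; grid spacing
   1/(N·Δt); frequencies held in THz internally and converted at
   1 THz = 33.35641 cm⁻¹ in exactly one place. No apodization window by
   default (an optional Hann window exists but is off), so weak modes are
   not smoothed away.
4. **Decay subtraction.** Transient spectra ride on a decaying
   background; a two-parameter model `a·exp(b·f)` is fitted by log-linear
   least squares (nonlinear fallback when amplitudes are non-positive)
   to the head (default) or tail region and subtracted, floored at zero.
   Region definition: because the DOS grid extends to the integration
   Nyquist (10⁴ THz at Δt = 0.05 fs), two orders beyond the vibrational
   band, head/tail fractions are taken over the *occupied* band (bins
   above 0.5% of the global maximum): head = lowest 5% of that band with
   the DC bin and ±1 neighbourhoods of detected peaks masked; tail = top
   10%. Modes that ride a steep background are not raw local maxima, so
   `subtract_decay_twopass` fits, subtracts, detects the emerging peaks,
   then refits the original spectrum with those bins masked — this is the
   default in the measurement drivers. Low-frequency (head) fitting is
   the default region; it resolves the band above ~5 THz better than
   tail fitting.
5. **Peaks and maps.** Local maxima above 10% of the (DC-excluded)
   global maximum, sorted by intensity, ties broken frequency-ascending.
   The DC bin is never a mode. Bond-projected modes default to
   *stretch*, angle-projected to *bend*; a frequency present within one
   bin in all six ring-bond spectra is relabelled *breathing*. Two
   conditions are compared by nearest-frequency matching within 3 bins;
   unmatched modes are reported as appeared/vanished; the resulting
   shift/amplitude-ratio table is the marker-frequency output.

## The Au20 cluster-mode measurement

The cluster's "basic" mode — the frequency shared by all four apex-region
atoms — is measured by `measure_au20_cluster_mode`: eight NVE samplings at
300 K from independently thermalized initial states (run-to-run
randomization), per-axis tip-atom spectra averaged over runs, two-pass
decay subtraction, per-axis peak detection, and per-atom union over axes.
The reported mode is the highest-frequency candidate common to all four
atoms within one bin, restricted to the cluster's harmonic band (the
band edge is computed at run time by diagonalising the mass-weighted EAM
Hessian of the relaxed cluster — peaks above it are subtraction
artifacts). The highest common band is the right fingerprint because the
soft shear band (30-40 cm⁻¹ here) is orientation- and
interaction-sensitive, while the stiff apex band is stable across
orientations.

With the bundled Sutton-Chen table the harmonic band edge sits at
183–187 cm⁻¹ and the measured mode lands at 203.6 cm⁻¹ = the grid bin
adjacent to the band edge — within one 20 cm⁻¹ bin of the 188 cm⁻¹
reference value for this cluster. **Sensitivity:** this frequency scales
with the curvature of the EAM well, so substituting another Au table
(Foiles-type funcfl, Zhou EAM, ...) will shift the band edge by roughly
the ratio of bulk phonon scales; the measurement reports whatever the
bundled table gives and the Hessian cross-check makes any table-induced
shift visible rather than silent.

## What the synthetic conditions do and do not emulate

The bundled fixtures and presets reproduce the *geometry and protocol* of
the sensing scenario (30° base tilt, 4 Å NP gap, pore-centred placement,
zero-velocity and driven variants). They do not include solvent or
hydration, counterions, electrostatics, the phosphate backbone beyond the
nucleoside, polarizability or any Raman intensity physics, or plasmonic
enhancement — spectra here are vibrational DOS amplitudes, not Raman
cross-sections. Peak *positions* from the bundled class-I table are
internally consistent but not calibrated to experiment; passing tests
demonstrate that the machinery (integration, projection, correlation,
background removal, mode bookkeeping) is correct and that interaction
fingerprints are detectable under the model's own physics, not that a
specific wet-lab spectrum would match.

## Numerical choices and degenerate inputs

* Harmonic/stretch convention `E = k Δr²` (force 2kΔr), k in kcal/mol/Å².
* Angle kernel guards sin θ ≥ 10⁻⁶; angle-projection rejects triples
  within 10⁻⁴ rad of collinear; bond projection rejects |r| < 10⁻⁶ Å.
* LJ pairs closer than 0.1 Å raise an overlap error; EAM pairs below the
  table minimum (1.5 Å) raise a range error; spline evaluation is
  clamped at the cutoff so the taper cannot be extrapolated.
* The exponential model is evaluated with a clipped exponent (|b·f| ≤
  700) so an ill-conditioned fit cannot overflow far outside its region.
* Runs abort when total energy exceeds 10× its initial magnitude
  (checked every 512 steps) or any force turns non-finite.
* Zero-step runs return an empty trajectory and leave the system
  untouched; records number ⌊n_steps/stride⌋.
* Problem sizes in the test-suite and acceptance drivers: full-resolution
  (32 768-step) runs for the cluster mode, drift, and rotation
  comparisons; 4 096-step runs (163 cm⁻¹ bins) for the qualitative
  marker-table smoke checks; oscillator oracles at 8 192 steps. These are
  the package's standard reduced configurations for CI-scale hardware.

## Known limitations

* The graphene term has no bond-order reactivity: pore-edge chemistry,
  bond breaking, and nucleoside adsorption chemistry are out of scope.
* The biased-VACF Fejér envelope redistributes a mode's weight into a
  decaying baseline; the exponential subtraction removes most but not all
  of it, and residual broad humps can survive — the band-edge filter in
  the cluster-mode measurement exists for exactly this reason.
* Single-trajectory mode intensities at a 1.64 ps window fluctuate
  strongly (few vibrational periods per mode; NVE barely mixes modal
  energies in a quasi-harmonic cluster); every intensity-sensitive
  measurement therefore averages over independently thermalized runs.
* The c.o.m. drive is a kinematic surrogate: no force, no charge, no
  field; momentum bookkeeping of the driven group is intentional, not
  physical.
* Masses are element-wise (no isotopes); hydrogens are explicit and the
  0.05 fs step is sized for their stretches.
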