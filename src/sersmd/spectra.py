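"""Transient vibrational spectroscopy from MD velocities.

The pipeline is: project velocities onto reaction coordinates (bond stretch
or in-plane bend), form the normalized velocity autocorrelation function

    G(tau) = <v(t0) . v(t0 + tau)> / <v(t0) . v(t0)>,

take its one-sided Fourier magnitude (by the Wiener–Khinchin theorem, the
vibrational density of states I(f)), strip the transient exponential decay
background by a two-parameter fit ``a exp(b f)`` to the head (low-frequency)
or tail (high-frequency) region, and detect/classify the surviving peaks
into per-bond spectral maps whose shifts between interaction conditions are
the marker frequencies.

Frequencies are THz internally and wavenumbers (cm^-1) at the reporting
boundary.  No apodization window is applied by default so that weak modes
are not smoothed away; an optional Hann window is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .md import Trajectory
from .units import cm1_to_thz, thz_to_cm1  # noqa: F401  (re-exported)

ASSIGNMENTS = ("stretch", "bend", "breathing")


@dataclass
class VacfSeries:
    lag_fs: np.ndarray     # uniform lag grid, fs
    g: np.ndarray          # normalized autocorrelation, G(0) = 1
    source: str = ""       # "atom 7 z" | "bond C(2)-C(3) end C(2)" | ...

    def __post_init__(self):
        if abs(self.g[0] - 1.0) > 1e-9:
            raise ValueError("VACF must be normalized to G(0) = 1")


@dataclass
class Spectrum:
    freq_thz: np.ndarray   # uniform grid from 0 to Nyquist, THz
    amplitude: np.ndarray  # arbitrary units, >= 0
    source: str = ""
    decay_subtracted: bool = False
    fit_region: str = "none"   # head | tail | none
    dt_fs: float = 0.0
    n_samples: int = 0

    @property
    def freq_cm1(self) -> np.ndarray:
        return thz_to_cm1(self.freq_thz)

    @property
    def bin_thz(self) -> float:
        return float(self.freq_thz[1] - self.freq_thz[0])

    @property
    def bin_cm1(self) -> float:
        return thz_to_cm1(self.bin_thz)


@dataclass
class ExpDecayFit:
    a: float
    b: float               # per THz; expected < 0 for a decaying spectrum
    region: str            # head | tail
    indices: np.ndarray    # fitted bin indices
    residual: float        # rms misfit over the fitted bins

    def evaluate(self, freq_thz: np.ndarray) -> np.ndarray:
        # clamp the exponent: far beyond the fitted region the model is
        # extrapolation only and must not overflow
        return self.a * np.exp(np.clip(self.b * np.asarray(freq_thz), -700.0, 700.0))


@dataclass
class Mode:
    freq_cm1: float
    intensity: float
    assignment: str = "stretch"
    shift_cm1: float | None = None

    def __post_init__(self):
        if self.assignment not in ASSIGNMENTS:
            raise ValueError(f"assignment must be one of {ASSIGNMENTS}")


@dataclass
class SpectralMap:
    """Per-bond detected modes for one interaction condition."""

    condition: dict = field(default_factory=dict)   # geometry, vz, NP orientation...
    bin_cm1: float = 0.0
    bonds: dict = field(default_factory=dict)       # label -> list[Mode]

    def to_json(self, path) -> None:
        payload = {
            "condition": self.condition,
            "bin_cm1": self.bin_cm1,
            "bonds": {
                label: [{"freq_cm1": m.freq_cm1, "intensity": m.intensity,
                         "assignment": m.assignment, "shift_cm1": m.shift_cm1}
                        for m in modes]
                for label, modes in self.bonds.items()
            },
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path) -> "SpectralMap":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            condition=payload.get("condition", {}),
            bin_cm1=payload.get("bin_cm1", 0.0),
            bonds={label: [Mode(**m) for m in modes]
                   for label, modes in payload.get("bonds", {}).items()},
        )


# ---------------------------------------------------------------------------
# reaction-coordinate projections

def project_bond_velocity(traj: Trajectory, bond: tuple[int, int]):
    """Velocity of each bond-end atom projected on the instantaneous bond axis.

    Returns (series_i, series_j): one scalar series per bond end, so the two
    atoms of a bond each get their own spectrum.
    """
    i, j = bond
    ri, rj = traj.position_of(i), traj.position_of(j)
    d = rj - ri
    norm = np.linalg.norm(d, axis=1)
    if np.any(norm < 1e-6):
        raise ValueError(f"bond ({i}, {j}): coincident atoms (|r| < 1e-6 Å)")
    u = d / norm[:, None]
    return (np.einsum("ij,ij->i", traj.velocity_of(i), u),
            np.einsum("ij,ij->i", traj.velocity_of(j), u))


def project_angle_velocity(traj: Trajectory, angle: tuple[int, int, int],
                           end: int = 0) -> np.ndarray:
    """Bending coordinate: end-atom velocity perpendicular to its bond,
    within the instantaneous angle plane.

    ``end = 0`` projects the velocity of the first atom of the i-j-k triple
    (``end = 2`` the last).  Out-of-plane motion is excluded by definition.
    """
    i, j, k = angle
    if len({i, j, k}) != 3:
        raise ValueError("angle atoms must be distinct")
    ri, rj, rk = traj.position_of(i), traj.position_of(j), traj.position_of(k)
    if end == 0:
        a, other = ri - rj, rk - rj
        v = traj.velocity_of(i)
    elif end == 2:
        a, other = rk - rj, ri - rj
        v = traj.velocity_of(k)
    else:
        raise ValueError("end must be 0 or 2 (an end atom of the triple)")
    na = np.linalg.norm(a, axis=1)
    no = np.linalg.norm(other, axis=1)
    cosang = np.einsum("ij,ij->i", a, other) / (na * no)
    if np.any(np.abs(cosang) > np.cos(1e-4)):
        raise ValueError(f"angle ({i}, {j}, {k}) is collinear: bending plane degenerate")
    ahat = a / na[:, None]
    w = other - np.einsum("ij,ij->i", other, ahat)[:, None] * ahat
    w /= np.linalg.norm(w, axis=1)[:, None]
    return np.einsum("ij,ij->i", v, w)


# ---------------------------------------------------------------------------
# VACF and DOS

def vacf(series: np.ndarray, dt_fs: float, max_lag: int | None = None,
         source: str = "") -> VacfSeries:
    """Normalized velocity autocorrelation averaged over all time origins.

    Implemented as the FFT-based (1/N) autocorrelation estimator, which is
    positive semidefinite — guaranteeing |G(tau)| <= G(0) = 1 — and is the
    exact Wiener–Khinchin counterpart of the reported DOS.  ``series`` may
    be scalar (N,) or vector (N, d); components are dot-summed.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim == 1:
        s = s[:, None]
    n = s.shape[0]
    if max_lag is None:
        max_lag = n - 1
    if n < max_lag + 1:
        raise ValueError(f"series length {n} < max_lag + 1 = {max_lag + 1}")
    spec = np.abs(np.fft.rfft(s, n=2 * n, axis=0)) ** 2
    acf = np.fft.irfft(spec.sum(axis=1), n=2 * n)[: max_lag + 1] / n
    if acf[0] <= 0:
        raise ValueError("zero-variance series: VACF normalization undefined")
    return VacfSeries(lag_fs=dt_fs * np.arange(max_lag + 1), g=acf / acf[0],
                      source=source)


def dos(v: VacfSeries, dt_fs: float | None = None, window: str | None = None,
        ) -> Spectrum:
    """One-sided Fourier magnitude of G(tau): the vibrational DOS.

    Grid spacing is ``1/(N dt)`` with N the number of lags; length is
    ``N//2 + 1``.  No apodization by default (``window='hann'`` opts in).
    """
    if dt_fs is None:
        if len(v.lag_fs) < 2:
            raise ValueError("cannot infer dt from a single-lag VACF")
        dt_fs = float(v.lag_fs[1] - v.lag_fs[0])
    g = v.g
    if window == "hann":
        g = g * np.hanning(2 * len(g))[len(g):]
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    n = len(g)
    amp = np.abs(np.fft.rfft(g))
    freq_thz = np.fft.rfftfreq(n, d=dt_fs) * 1e3   # 1/fs -> THz
    return Spectrum(freq_thz=freq_thz, amplitude=amp, source=v.source,
                    dt_fs=dt_fs, n_samples=n)


def spectrum_of_series(series: np.ndarray, dt_fs: float, source: str = "",
                       window: str | None = None) -> Spectrum:
    """Convenience: DOS of a raw (projected or Cartesian) velocity series."""
    return dos(vacf(series, dt_fs, source=source), dt_fs, window=window)


def average_spectra(specs: list[Spectrum]) -> Spectrum:
    """Bin-wise mean of spectra on identical grids (run-to-run averaging)."""
    if not specs:
        raise ValueError("nothing to average")
    f0 = specs[0].freq_thz
    for s in specs[1:]:
        if len(s.freq_thz) != len(f0) or abs(s.freq_thz[1] - f0[1]) > 1e-12:
            raise ValueError("spectra are on different grids")
    return Spectrum(freq_thz=f0.copy(),
                    amplitude=np.mean([s.amplitude for s in specs], axis=0),
                    source=specs[0].source,
                    decay_subtracted=specs[0].decay_subtracted,
                    fit_region=specs[0].fit_region,
                    dt_fs=specs[0].dt_fs, n_samples=specs[0].n_samples)


# ---------------------------------------------------------------------------
# exponential decay background (transient-spectrum correction)

def _support(spec: Spectrum, floor: float = 0.005) -> int:
    """Last occupied bin: highest frequency with amplitude above ``floor``
    of the global max.  The DOS grid extends to the integration Nyquist,
    far beyond the vibrational band, so fit-region fractions are taken over
    the occupied band, not the raw grid."""
    amp = spec.amplitude
    above = np.nonzero(amp[1:] >= floor * amp.max())[0]
    last = int(above[-1]) + 1 if len(above) else len(amp) - 1
    return max(last, min(40, len(amp) - 1))


def _head_indices(spec: Spectrum, rel_threshold: float = 0.1,
                  head_fraction: float = 0.05) -> np.ndarray:
    """Low-frequency fit region: the lowest 5% of the occupied band, with
    the DC bin and the ±1 neighbourhood of every detected peak masked out
    (the decay background, not the modes, is what gets fitted)."""
    cap = max(8, int(np.floor(head_fraction * _support(spec))))
    peaks, _ = find_peaks(spec.amplitude,
                          height=rel_threshold * spec.amplitude.max())
    idx = np.arange(1, min(cap + 1, len(spec.amplitude)))
    if len(peaks):
        mask = np.concatenate([peaks - 1, peaks, peaks + 1])
        masked = idx[~np.isin(idx, mask)]
        if len(masked) < 3:    # peak-dense head: widen, then give up masking
            wide = np.arange(1, min(2 * cap + 1, len(spec.amplitude)))
            masked = wide[~np.isin(wide, mask)]
        if len(masked) >= 2:
            return masked
    return idx


def _tail_indices(spec: Spectrum, tail_fraction: float = 0.10) -> np.ndarray:
    """High-frequency fit region: the top 10% of the occupied band."""
    last = _support(spec)
    start = last - max(4, int(np.floor(tail_fraction * last)))
    return np.arange(max(start, 1), last + 1)


def fit_exp_decay(spec: Spectrum, region: str = "head",
                  rel_threshold: float = 0.1,
                  mask_bins: np.ndarray | None = None) -> ExpDecayFit:
    """Least-squares fit of ``a exp(b f)`` to the head or tail of a spectrum.

    head: the lowest 5% of the occupied band below/around the first peaks,
    with peak neighbourhoods masked; tail: the top 10% of the occupied
    band.  ``mask_bins`` removes additional bins from the region (used by
    the two-pass subtraction, which masks peaks found after a first
    subtraction).  A log-linear fit is used when all amplitudes in the
    region are positive, else a direct nonlinear fit.
    """
    if region == "head":
        idx = _head_indices(spec, rel_threshold)
    elif region == "tail":
        idx = _tail_indices(spec)
    else:
        raise ValueError("region must be 'head' or 'tail'")
    if mask_bins is not None and len(mask_bins):
        masked = idx[~np.isin(idx, np.asarray(mask_bins, dtype=int))]
        if len(masked) >= 2:
            idx = masked
    if len(idx) < 2:
        raise ValueError(f"{region} region too small to fit")
    f = spec.freq_thz[idx]
    y = spec.amplitude[idx]
    if np.all(y > 0):
        slope, intercept = np.polyfit(f, np.log(y), 1)
        a, b = float(np.exp(intercept)), float(slope)
    else:
        try:
            (a, b), _ = curve_fit(lambda x, a, b: a * np.exp(b * x), f, y,
                                  p0=(max(y.max(), 1e-12), -0.01), maxfev=10000)
        except RuntimeError as exc:
            raise ValueError(f"exponential fit failed on {region} region") from exc
    resid = float(np.sqrt(np.mean((y - a * np.exp(b * f)) ** 2)))
    return ExpDecayFit(a=a, b=b, region=region, indices=idx, residual=resid)


def subtract_decay(spec: Spectrum, fit: ExpDecayFit | None = None,
                   region: str = "head") -> Spectrum:
    """Subtract the fitted exponential decay, floored at zero.

    Default region is the head: low-frequency fitting resolves the spectrum
    above ~5 THz better than tail fitting on transient data.
    """
    if spec.decay_subtracted:
        raise ValueError("spectrum already decay-subtracted")
    if fit is None:
        fit = fit_exp_decay(spec, region=region)
    amp = np.maximum(spec.amplitude - fit.evaluate(spec.freq_thz), 0.0)
    return Spectrum(freq_thz=spec.freq_thz.copy(), amplitude=amp,
                    source=spec.source, decay_subtracted=True,
                    fit_region=fit.region, dt_fs=spec.dt_fs,
                    n_samples=spec.n_samples)


def subtract_decay_twopass(spec: Spectrum, region: str = "head",
                           rel_threshold: float = 0.1) -> Spectrum:
    """Decay subtraction with peak re-masking.

    Modes riding on a steep transient background are not local maxima of
    the raw spectrum, so a single-pass fit absorbs part of their intensity.
    This fits, subtracts, detects the emerging peaks, then refits the
    original spectrum with those peak bins (±1) masked and subtracts the
    refined background.
    """
    first = subtract_decay(spec, region=region)
    peak_bins = []
    for m in detect_peaks(first, rel_threshold=rel_threshold):
        k = int(round(cm1_to_thz(m.freq_cm1) / spec.bin_thz))
        peak_bins += [k - 1, k, k + 1]
    fit = fit_exp_decay(spec, region=region, mask_bins=np.asarray(peak_bins))
    return subtract_decay(spec, fit)


# ---------------------------------------------------------------------------
# peaks, classification, condition comparison

def detect_peaks(spec: Spectrum, rel_threshold: float = 0.1,
                 assignment: str = "stretch") -> list[Mode]:
    """Local maxima above ``rel_threshold`` x global max.

    Sorted by decreasing intensity; equal intensities tie-break in
    ascending frequency.  Only relatively intense modes are kept, mirroring
    how transient spectra are read.
    """
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in (0, 1]")
    amp = spec.amplitude
    # the DC bin is the squared mean of G, not a vibration; it neither sets
    # the threshold nor counts as a mode
    if len(amp) < 3 or amp[1:].max() <= 0:
        return []
    peaks, props = find_peaks(amp[1:], height=rel_threshold * amp[1:].max())
    peaks = peaks + 1
    order = sorted(range(len(peaks)),
                   key=lambda t: (-props["peak_heights"][t], peaks[t]))
    return [Mode(freq_cm1=float(spec.freq_cm1[peaks[t]]),
                 intensity=float(props["peak_heights"][t]),
                 assignment=assignment) for t in order]


def classify_modes(smap: SpectralMap, ring_bonds: list[str]) -> SpectralMap:
    """Relabel ring-breathing modes.

    A frequency present (within one bin) in the spectra of *all* bonds
    forming the ring is a collective ring mode and is relabelled
    ``breathing``; other bond modes keep their projection-default label.
    """
    ring_bonds = [b for b in ring_bonds]
    if not ring_bonds:
        return smap
    missing = [b for b in ring_bonds if b not in smap.bonds]
    if missing:
        raise KeyError(f"ring bonds absent from map: {missing}")
    tol = smap.bin_cm1 if smap.bin_cm1 > 0 else 1e-6
    out = SpectralMap(condition=dict(smap.condition), bin_cm1=smap.bin_cm1,
                      bonds={k: [Mode(m.freq_cm1, m.intensity, m.assignment,
                                      m.shift_cm1) for m in v]
                             for k, v in smap.bonds.items()})
    for label in ring_bonds:
        for mode in out.bonds[label]:
            shared = all(
                any(abs(other.freq_cm1 - mode.freq_cm1) <= tol + 1e-12
                    for other in out.bonds[rb])
                for rb in ring_bonds)
            if shared:
                mode.assignment = "breathing"
    return out


def compare_conditions(reference: SpectralMap, interacting: SpectralMap,
                       match_bins: float = 3.0) -> pd.DataFrame:
    """Marker-frequency table: per-bond mode shifts and amplitude ratios.

    Modes are matched to the nearest reference frequency within
    ``match_bins`` bins; unmatched modes are listed as appeared (only in
    the interacting map) or vanished (only in the reference).  Bonds
    present in a single map are reported with status ``bond_only_in_*``.
    """
    bin_cm1 = reference.bin_cm1 or interacting.bin_cm1
    tol = match_bins * bin_cm1 if bin_cm1 > 0 else np.inf
    rows = []
    all_bonds = sorted(set(reference.bonds) | set(interacting.bonds))
    for label in all_bonds:
        if label not in interacting.bonds:
            rows.append({"bond": label, "status": "bond_only_in_reference"})
            continue
        if label not in reference.bonds:
            rows.append({"bond": label, "status": "bond_only_in_interacting"})
            continue
        ref_modes = reference.bonds[label]
        int_modes = interacting.bonds[label]
        used = set()
        for m in int_modes:
            best, best_d = None, np.inf
            for ridx, r in enumerate(ref_modes):
                d = abs(r.freq_cm1 - m.freq_cm1)
                if ridx not in used and d < best_d:
                    best, best_d = ridx, d
            if best is not None and best_d <= tol:
                used.add(best)
                r = ref_modes[best]
                rows.append({
                    "bond": label, "status": "matched",
                    "freq_ref_cm1": r.freq_cm1, "freq_cm1": m.freq_cm1,
                    "shift_cm1": m.freq_cm1 - r.freq_cm1,
                    "amplitude_ratio": m.intensity / r.intensity
                    if r.intensity else np.inf,
                    "assignment": m.assignment,
                })
            else:
                rows.append({"bond": label, "status": "appeared",
                             "freq_cm1": m.freq_cm1, "assignment": m.assignment})
        for ridx, r in enumerate(ref_modes):
            if ridx not in used:
                rows.append({"bond": label, "status": "vanished",
                             "freq_ref_cm1": r.freq_cm1, "assignment": r.assignment})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV IO

def write_spectrum_csv(path, spec: Spectrum) -> None:
    with open(path, "w") as f:
        f.write(f"# source: {spec.source}\n")
        f.write(f"# decay_subtracted: {spec.decay_subtracted}\n")
        f.write(f"# fit_region: {spec.fit_region}\n")
        f.write(f"# dt_fs: {spec.dt_fs}\n")
        f.write(f"# n_samples: {spec.n_samples}\n")
        f.write("frequency_cm1,amplitude\n")
        for fc, a in zip(spec.freq_cm1, spec.amplitude):
            f.write(f"{fc:.6f},{a:.8e}\n")


def read_spectrum_csv(path) -> Spectrum:
    meta = {}
    with open(path) as f:
        lines = f.readlines()
    rows = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        elif not line.startswith("frequency"):
            fc, a = line.strip().split(",")
            rows.append((float(fc), float(a)))
    arr = np.asarray(rows)
    return Spectrum(
        freq_thz=cm1_to_thz(arr[:, 0]), amplitude=arr[:, 1],
        source=meta.get("source", ""),
        decay_subtracted=meta.get("decay_subtracted", "False") == "True",
        fit_region=meta.get("fit_region", "none"),
        dt_fs=float(meta.get("dt_fs", 0.0)),
        n_samples=int(meta.get("n_samples", 0)),
    )
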