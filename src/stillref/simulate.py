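"""Snapshot-dataset simulator.

Generates serial-crystallography test data entirely in software: a
table of synthetic "true" full intensities, and for each pattern a
Haar-random crystal orientation, the reflections excited by the beam
and landing on the detector, partial intensities

    I_partial = G * p * L * I_full + noise,

a per-pattern scale factor G, additive Gaussian noise with one constant
standard deviation for the whole dataset, and a perturbed copy of the
reciprocal basis standing in for the limited accuracy of indexing.

Default parameters describe a lysozyme-sized rhombohedral crystal
(a = 144.2 A, alpha = 113.78 deg, point symmetry 32) in an 8 keV beam
with 0.05% top-hat bandwidth and 1 mrad convergence, recorded on a
76.8 mm square detector 50 mm downstream; the reflection-sphere radius
is 5e-3 nm^-1, basis errors are uniform within +-0.1% per component and
scales are drawn from N(1, 0.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import (
    BeamModel,
    DetectorModel,
    SymmetryGroup,
    UnitCell,
    cell_to_reciprocal_basis,
    detector_resolution_limits,
    hkl_pack,
    random_orientation,
)
from .partiality import (
    clamp_distances,
    excitation_distances,
    lorentz,
    lorentz_normalization,
    partiality,
)

__all__ = [
    "SimulationConfig",
    "Pattern",
    "ReferenceIntensityTable",
    "TruthRecord",
    "SimulatedDataset",
    "generate_reference_intensities",
    "predict_reflections",
    "perturb_basis",
    "simulate_pattern",
    "simulate_dataset",
]

#: Columns of a pattern's reflection table.
REFLECTION_COLUMNS = [
    "h", "k", "l", "I", "sigma", "p", "L",
    "r_high", "r_low", "clamped_high", "clamped_low", "det_x", "det_y",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Dataset-level simulation parameters (defaults: see module docstring)."""

    n_patterns: int = 1000
    cell: UnitCell = field(default_factory=lambda: UnitCell(144.2, 113.78))
    symmetry: SymmetryGroup = field(
        default_factory=lambda: SymmetryGroup.from_spacegroup("R 3 2:R")
    )
    beam: BeamModel = field(
        default_factory=lambda: BeamModel(8.0, bandwidth_frac=5e-4, convergence_rad=1e-3)
    )
    detector: DetectorModel = field(default_factory=lambda: DetectorModel(76.8, 50.0))
    sphere_radius: float = 5e-3          # nm^-1
    basis_error_max_frac: float = 1e-3   # +-0.1% flat-top per component
    scale_mean: float = 1.0
    scale_sd: float = 0.3
    wilson_b: float = 50.0               # isotropic B factor [A^2] for reference intensities
    wilson_mean_intensity: float = 1000.0
    noise_sigma: float | None = None     # None -> highest-shell-mean rule
    noise_shells: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patterns < 0:
            raise ValueError("n_patterns must be >= 0")
        if not 0 <= self.basis_error_max_frac < 1:
            raise ValueError("basis_error_max_frac must lie in [0, 1)")
        if self.sphere_radius <= 0:
            raise ValueError("sphere radius must be positive")

    @property
    def k_lorentz(self) -> float:
        """Lorentz constant: slab thickness at the detector-edge resolution."""
        d_edge, _ = detector_resolution_limits(self.detector, self.beam.wavelength_angstrom)
        return lorentz_normalization(self.beam, d_edge)


@dataclass
class ReferenceIntensityTable:
    """Full intensities per canonical hkl, with packed-key lookup."""

    hkl: np.ndarray        # (M, 3) canonical indices
    intensity: np.ndarray  # (M,)
    d: np.ndarray          # (M,) angstrom

    keys: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        keys = hkl_pack(self.hkl)
        order = np.argsort(keys)
        self.hkl = np.asarray(self.hkl)[order]
        self.intensity = np.asarray(self.intensity, dtype=float)[order]
        self.d = np.asarray(self.d, dtype=float)[order]
        self.keys = keys[order]
        if np.any(self.intensity < 0):
            raise ValueError("reference intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.keys)

    def lookup(self, canonical_hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(values, found_mask) for an (N, 3) array of canonical indices."""
        q = hkl_pack(canonical_hkl)
        idx = np.searchsorted(self.keys, q)
        idx = np.clip(idx, 0, len(self.keys) - 1)
        found = self.keys[idx] == q
        vals = np.where(found, self.intensity[idx], np.nan)
        return vals, found

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "I": self.intensity,
                "d": self.d,
            }
        )

    def highest_shell_mean(self, n_shells: int = 20) -> float:
        """Mean intensity in the highest-resolution of ``n_shells`` equal-count shells."""
        order = np.argsort(self.d)  # ascending d = highest resolution first
        cut = max(1, len(self.d) // n_shells)
        return float(self.intensity[order[:cut]].mean())


@dataclass
class Pattern:
    """One snapshot: working geometry, scale estimate and reflection table."""

    pattern_id: int
    basis: np.ndarray             # working (perturbed / refined) reciprocal basis
    reflections: pd.DataFrame     # REFLECTION_COLUMNS
    scale: float = 1.0            # current scale estimate G_j

    @property
    def hkl(self) -> np.ndarray:
        return self.reflections[["h", "k", "l"]].to_numpy(dtype=np.int64)

    def n_reflections(self) -> int:
        return len(self.reflections)


@dataclass
class TruthRecord:
    """Ground truth kept aside for evaluation only."""

    true_bases: list
    true_scales: np.ndarray
    noise_sigma: float
    seed: int


@dataclass
class SimulatedDataset:
    patterns: list
    reference: ReferenceIntensityTable
    truth: TruthRecord
    config: SimulationConfig

    def mean_partiality(self) -> float:
        """Mean model partiality over every simulated observation (pre-rejection)."""
        total = sum(float(p.reflections["p"].sum()) for p in self.patterns)
        n = sum(p.n_reflections() for p in self.patterns)
        return total / n if n else float("nan")

    def max_partiality(self) -> float:
        return max(float(p.reflections["p"].max()) for p in self.patterns if len(p.reflections))

    def n_observations(self) -> int:
        return sum(p.n_reflections() for p in self.patterns)


@lru_cache(maxsize=4)
def _candidate_hkl_cached(cell: UnitCell, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    hkl, smod = _candidate_hkl_impl(cell, d_min)
    hkl.setflags(write=False)
    smod.setflags(write=False)
    return hkl, smod


def _candidate_hkl(cell: UnitCell, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    """All integer hkl with d >= d_min; cached per (cell, d_min), read-only arrays."""
    return _candidate_hkl_cached(cell, round(float(d_min), 9))


def _candidate_hkl_impl(cell: UnitCell, d_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive box scan for all integer hkl with d >= d_min; returns (hkl, |s| nm^-1)."""
    b0 = cell.reference_reciprocal_basis()
    s_max = 10.0 / d_min  # nm^-1
    # bounding box: |h_i| <= s_max * |a_i| (direct-cell row norms)
    direct = np.linalg.inv(b0).T  # rows a, b, c in nm
    lim = np.ceil(s_max * np.linalg.norm(direct, axis=1)).astype(int)
    h = np.arange(-lim[0], lim[0] + 1)
    k = np.arange(-lim[1], lim[1] + 1)
    l = np.arange(-lim[2], lim[2] + 1)
    hh, kk, ll = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.stack([hh.ravel(), kk.ravel(), ll.ravel()], axis=1).astype(np.int64)
    smod = np.linalg.norm(hkl @ b0.T, axis=1)
    keep = (smod <= s_max) & (smod > 0)
    return hkl[keep], smod[keep]


def generate_reference_intensities(
    cell: UnitCell,
    symmetry: SymmetryGroup,
    d_min: float,
    rng: np.random.Generator,
    wilson_b: float = 50.0,
    mean_intensity: float = 1000.0,
) -> ReferenceIntensityTable:
    """Synthetic full intensities for every unique hkl with d >= d_min.

    Intensities follow the acentric Wilson distribution (exponential)
    with a resolution-dependent mean <I>(s) = I0 exp(-B s^2 / 2)
    (s = 1/d in A^-1), emulating isotropic Debye-Waller fall-off.  The
    table is keyed by canonical (asymmetric-unit) indices.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    hkl, smod = _candidate_hkl(cell, d_min)
    canon = symmetry.canonicalize(hkl)
    keys = hkl_pack(canon)
    uniq_keys, first = np.unique(keys, return_index=True)
    uhkl = canon[first]
    d = 10.0 / smod[first]  # the orbit shares |s| for any sane merging symmetry
    s_inv_a = 1.0 / d       # A^-1
    mean = mean_intensity * np.exp(-wilson_b * s_inv_a**2 / 2.0)
    intens = rng.exponential(mean)
    return ReferenceIntensityTable(hkl=uhkl, intensity=intens, d=d)


def predict_reflections(
    basis: np.ndarray,
    beam: BeamModel,
    detector: DetectorModel,
    r: float,
    candidates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reflections excitable by the nest and landing on the detector.

    Parameters
    ----------
    candidates:
        (M, 3) integer hkl to test (typically every index inside the
        corner-resolution sphere; |s| is rotation-invariant so the list
        can be precomputed once per cell).

    Returns
    -------
    hkl : (N, 3) predicted indices (excluding (0,0,0))
    s : (N, 3) scattering vectors, nm^-1
    det_xy : (N, 2) spot positions on the detector, mm
    """
    cand = np.asarray(candidates, dtype=np.int64)
    cand = cand[np.any(cand != 0, axis=1)]
    s = cand @ np.asarray(basis).T
    # cheap prefilter on the nominal excitation error before the 4-sphere test
    r_ewald = beam.ewald_radius
    dist0 = np.sqrt(np.einsum("ij,ij->i", s, s) + 2.0 * r_ewald * s[:, 2] + r_ewald**2)
    e0 = r_ewald - dist0
    smod = np.linalg.norm(s, axis=1)
    # first-order half-thickness of the nest, inflated 20% to stay conservative
    margin = r + 0.6 * (smod * beam.convergence_rad + smod**2 * beam.wavelength_nm * beam.bandwidth_frac) + 1e-9
    near = np.abs(e0) <= margin
    cand, s = cand[near], s[near]
    if len(cand) == 0:
        return cand, s, np.empty((0, 2))

    geom = excitation_distances(s, beam, r)
    excited = (geom.r_high < r) & (geom.r_low > -r)
    cand, s = cand[excited], s[excited]
    if len(cand) == 0:
        return cand, s, np.empty((0, 2))

    # project the diffracted beam (from the nominal Ewald centre) onto the detector
    kout = s.copy()
    kout[:, 2] += r_ewald
    with np.errstate(divide="ignore", invalid="ignore"):
        det_xy = kout[:, :2] * (detector.distance_mm / kout[:, 2])[:, None]
    half = detector.side_mm / 2.0
    on_det = (kout[:, 2] > 0) & (np.abs(det_xy) <= half).all(axis=1)
    return cand[on_det], s[on_det], det_xy[on_det]


def perturb_basis(basis: np.ndarray, max_frac: float, rng: np.random.Generator) -> np.ndarray:
    """Multiply each of the nine components by (1 + u), u ~ U(-max_frac, +max_frac)."""
    if max_frac < 0:
        raise ValueError("max_frac must be non-negative")
    u = rng.uniform(-max_frac, max_frac, size=(3, 3))
    return np.asarray(basis) * (1.0 + u)


def _draw_scale(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated to positive values (resampled)."""
    for _ in range(100):
        g = rng.normal(mean, sd)
        if g > 0:
            return float(g)
    raise RuntimeError("could not draw a positive scale factor")


def simulate_pattern(
    reference: ReferenceIntensityTable,
    config: SimulationConfig,
    rng: np.random.Generator,
    candidates: np.ndarray,
    noise_sigma: float,
    pattern_id: int = 0,
) -> tuple[Pattern, np.ndarray, float]:
    """One snapshot; returns (pattern, true_basis, true_scale).

    The pattern's working basis is the perturbed copy; its stored p and
    L are the *true* model values used to generate the intensities
    (callers recompute them from the working basis before processing).
    """
    orientation = random_orientation(rng)
    true_basis = cell_to_reciprocal_basis(config.cell, orientation)
    g_true = _draw_scale(rng, config.scale_mean, config.scale_sd)

    hkl, s, det_xy = predict_reflections(
        true_basis, config.beam, config.detector, config.sphere_radius, candidates
    )
    geom = excitation_distances(s, config.beam, config.sphere_radius) if len(hkl) else None
    if len(hkl):
        cl = clamp_distances(geom)
        p = partiality(cl)
        L = lorentz(geom, config.k_lorentz)
        ifull, found = reference.lookup(config.symmetry.canonicalize(hkl))
        # drop predictions falling outside the reference table (corner margin)
        keep = found
        hkl, det_xy, p, L = hkl[keep], det_xy[keep], p[keep], L[keep]
        rh, rl = cl.r_high[keep], cl.r_low[keep]
        ch, clo = cl.clamped_high[keep], cl.clamped_low[keep]
        ifull = ifull[keep]
        noise = rng.normal(0.0, noise_sigma, size=len(hkl)) if noise_sigma > 0 else 0.0
        intensity = g_true * p * L * ifull + noise
    else:
        p = L = rh = rl = ch = clo = intensity = np.empty(0)
        det_xy = np.empty((0, 2))

    table = pd.DataFrame(
        {
            "h": hkl[:, 0] if len(hkl) else np.empty(0, dtype=np.int64),
            "k": hkl[:, 1] if len(hkl) else np.empty(0, dtype=np.int64),
            "l": hkl[:, 2] if len(hkl) else np.empty(0, dtype=np.int64),
            "I": intensity,
            "sigma": np.full(len(hkl), noise_sigma if noise_sigma > 0 else 1e-30),
            "p": p,
            "L": L,
            "r_high": rh,
            "r_low": rl,
            "clamped_high": np.asarray(ch, dtype=bool),
            "clamped_low": np.asarray(clo, dtype=bool),
            "det_x": det_xy[:, 0],
            "det_y": det_xy[:, 1],
        }
    )
    working = perturb_basis(true_basis, config.basis_error_max_frac, rng)
    return Pattern(pattern_id, working, table), true_basis, g_true


def simulate_dataset(config: SimulationConfig, seed: int | None = None) -> SimulatedDataset:
    """Simulate a full dataset; deterministic for a given config and seed.

    The reference table extends slightly past the detector-corner
    resolution so that every predictable reflection has a true
    intensity.  The noise level is the mean reference intensity in the
    highest-resolution shell unless the config fixes it explicitly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    _, d_corner = detector_resolution_limits(config.detector, config.beam.wavelength_angstrom)
    d_min = d_corner * 0.98  # margin: bandwidth/convergence excite slightly past the corner
    reference = generate_reference_intensities(
        config.cell, config.symmetry, d_min, rng,
        wilson_b=config.wilson_b, mean_intensity=config.wilson_mean_intensity,
    )
    if config.noise_sigma is not None:
        noise_sigma = config.noise_sigma
    else:
        noise_sigma = reference.highest_shell_mean(config.noise_shells)

    candidates, _ = _candidate_hkl(config.cell, d_min)
    patterns: list[Pattern] = []
    bases: list[np.ndarray] = []
    scales = np.empty(config.n_patterns)
    for j in range(config.n_patterns):
        pat, tb, tg = simulate_pattern(
            reference, config, rng, candidates, noise_sigma, pattern_id=j
        )
        patterns.append(pat)
        bases.append(tb)
        scales[j] = tg
    truth = TruthRecord(
        true_bases=bases,
        true_scales=scales,
        noise_sigma=noise_sigma,
        seed=config.seed if seed is None else seed,
    )
    return SimulatedDataset(patterns, reference, truth, config)
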