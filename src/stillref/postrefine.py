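"""Per-pattern post-refinement of the diffraction geometry.

Each snapshot's nine Cartesian reciprocal-basis components are refined
by nonlinear least squares to maximize the agreement between its
partial intensities and the current merged full-intensity estimates.
The residual for one measurement is

    dI_ej = I_ej,partial / (G_j L_ej) - p_ej * I_full(hkl),

and the objective is sum dI^2 over the selected reflections of the
pattern.  Gauss-Newton normal equations are built from the analytic
partiality gradients (the Lorentz gradient is taken as zero), rescaled
so all diagonal elements are 1 (Bricogne preconditioning) and solved by
SVD with small-eigenvalue elimination.  On generic still patterns
exactly one eigenvalue is eliminated: rotating the crystal about the
beam axis leaves every partiality unchanged, so the nine parameters
carry one redundant degree of freedom.

Selection rules for refinement: I >= 3 sigma, p >= p_min, and at least
one other scalable measurement of the same unique reflection anywhere
in the dataset.  Inner iterations stop when the largest partiality
change drops below 0.01, after 10 iterations, or when a step zeroes the
partialities of more than a third of the selected reflections (the
step is then reverted).

The outer driver alternates scaling/merging with refinement of every
pattern, the cycle structure being [scale+merge] then
n_cycles x [refine all -> scale+merge].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SymmetryGroup, basis_components, basis_from_components, hkl_pack
from .partiality import (
    clamp_distances,
    excitation_distances,
    lorentz,
    partiality,
    partiality_gradients,
)
from .scaling import (
    MergedIntensityTable,
    P_MIN_DEFAULT,
    ScaleSet,
    kabsch_scale_and_merge,
)
from .simulate import Pattern, SimulationConfig

__all__ = [
    "RefinementResult",
    "NormalEquations",
    "RefinementSettings",
    "residuals",
    "build_multiplicity_index",
    "select_refinable",
    "build_normal_equations",
    "solve_rescaled_svd",
    "refine_pattern",
    "update_pattern_model",
    "run_cycles",
    "CycleHistory",
]

MAX_INNER_ITERATIONS = 10
DELTA_P_CONVERGED = 0.01
REVERT_ZERO_FRACTION = 1.0 / 3.0


@dataclass(frozen=True)
class RefinementSettings:
    """Knobs of the least-squares refinement."""

    p_min: float = P_MIN_DEFAULT
    snr_min: float = 3.0          # I >= snr_min * sigma selection cut
    eig_frac: float = 1e-6        # eliminate eigenvalues below eig_frac * max
    max_iterations: int = MAX_INNER_ITERATIONS
    delta_p_converged: float = DELTA_P_CONVERGED
    weighted: bool = False        # 1/sigma^2 residual weights


@dataclass
class RefinementResult:
    basis: np.ndarray
    n_inner_iterations: int = 0
    eliminated_eigenvalues: list = field(default_factory=list)
    max_delta_p: list = field(default_factory=list)
    reverted: bool = False
    n_reflections_used: int = 0
    termination: str = "skipped"


@dataclass
class NormalEquations:
    matrix: np.ndarray       # 9x9 symmetric J^T J
    rhs: np.ndarray          # -J^T dI
    rescale: np.ndarray = field(init=False)  # Bricogne diagonal, filled on solve

    def __post_init__(self) -> None:
        if self.matrix.shape != (9, 9) or self.rhs.shape != (9,):
            raise ValueError("normal equations must be 9x9 with a 9-vector rhs")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("normal matrix must be symmetric")
        self.rescale = np.ones(9)


def residuals(
    intensity: np.ndarray,
    L: np.ndarray,
    p: np.ndarray,
    g: float,
    i_full: np.ndarray,
) -> np.ndarray:
    """dI = I_partial / (G L) - p * I_full per observation."""
    return np.asarray(intensity, float) / (g * np.asarray(L, float)) - np.asarray(p, float) * np.asarray(i_full, float)


def build_multiplicity_index(patterns: list, symmetry: SymmetryGroup, p_min: float = P_MIN_DEFAULT):
    """Count scalable measurements (p >= p_min) per unique hkl across the dataset.

    Returns (sorted packed keys, counts) for use by :func:`select_refinable`.
    """
    keys = []
    for pat in patterns:
        refl = pat.reflections
        if not len(refl):
            continue
        ok = (refl["p"].to_numpy() >= p_min) & (refl["L"].to_numpy() > 0)
        if ok.any():
            keys.append(hkl_pack(symmetry.canonicalize(pat.hkl[ok])))
    if not keys:
        return np.empty(0, np.int64), np.empty(0, int)
    allk = np.concatenate(keys)
    uniq, counts = np.unique(allk, return_counts=True)
    return uniq, counts


def select_refinable(
    pattern: Pattern,
    merged: MergedIntensityTable,
    symmetry: SymmetryGroup,
    multiplicity: tuple,
    settings: RefinementSettings = RefinementSettings(),
    p: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of observations entering the least squares.

    Keeps observations with I >= snr_min * sigma, p >= p_min, a merged
    full-intensity estimate, and dataset multiplicity >= 2 for the
    unique reflection (so at least one *other* scalable measurement
    exists, in this pattern or any other).
    """
    refl = pattern.reflections
    if not len(refl):
        return np.zeros(0, dtype=bool)
    if p is None:
        p = refl["p"].to_numpy()
    intensity = refl["I"].to_numpy()
    sigma = refl["sigma"].to_numpy()
    mask = (intensity >= settings.snr_min * sigma) & (p >= settings.p_min)
    canon = symmetry.canonicalize(pattern.hkl)
    _, found = merged.lookup(canon)
    mask &= found
    mkeys, mcounts = multiplicity
    q = hkl_pack(canon)
    idx = np.clip(np.searchsorted(mkeys, q), 0, max(len(mkeys) - 1, 0))
    mult = np.where((len(mkeys) > 0) & (mkeys[idx] == q), mcounts[idx] if len(mkeys) else 0, 0)
    mask &= mult >= 2
    return mask


def build_normal_equations(
    hkl: np.ndarray,
    basis: np.ndarray,
    config: SimulationConfig,
    intensity: np.ndarray,
    sigma: np.ndarray,
    g: float,
    i_full: np.ndarray,
    settings: RefinementSettings = RefinementSettings(),
) -> tuple[NormalEquations, np.ndarray, np.ndarray]:
    """Gauss-Newton normal equations for one pattern's selected reflections.

    The Jacobian row of observation e is d(dI_e)/dv = -I_full * dp/dv
    (nine components); the normal matrix is J^T W J and the right-hand
    side -J^T W dI with unit weights by default.  Also returns the
    current partialities and residuals.
    """
    p, grad = partiality_gradients(hkl, basis, config.beam, config.sphere_radius)
    s = hkl @ np.asarray(basis).T
    geom = excitation_distances(s, config.beam, config.sphere_radius)
    L = lorentz(geom, config.k_lorentz)
    d_i = residuals(intensity, L, p, g, i_full)
    jac = -np.asarray(i_full)[:, None] * grad
    w = 1.0 / np.asarray(sigma, float) ** 2 if settings.weighted else np.ones(len(d_i))
    a = (jac * w[:, None]).T @ jac
    b = -(jac * w[:, None]).T @ d_i
    return NormalEquations(matrix=a, rhs=b), p, d_i


def solve_rescaled_svd(ne: NormalEquations, eig_frac: float = 1e-6) -> tuple[np.ndarray, int]:
    """Solve the normal equations via Bricogne rescaling and filtered SVD.

    The matrix is pre- and post-multiplied by D = diag(1/sqrt(A_ii)) so
    every (nonzero) diagonal element becomes 1, making small eigenvalues
    diagnostic of parameter correlation rather than of scale.  The
    rescaled system is solved by SVD, zeroing singular values smaller
    than ``eig_frac`` times the largest.  Returns (step, n_eliminated),
    counting eliminated values among the active (nonzero-diagonal)
    parameters; frozen parameters get a zero step.
    """
    diag = np.diag(ne.matrix).copy()
    active = diag > 0
    if not active.any():
        return np.zeros(9), 0
    d = np.zeros(9)
    d[active] = 1.0 / np.sqrt(diag[active])
    ne.rescale = d
    a = (d[:, None] * ne.matrix) * d[None, :]
    b = d * ne.rhs
    a_act = a[np.ix_(active, active)]
    b_act = b[active]
    u, svals, vt = np.linalg.svd(a_act, hermitian=True)
    keep = svals >= eig_frac * svals[0]
    eliminated = int(np.count_nonzero(~keep))
    inv = np.where(keep, 1.0 / np.where(keep, svals, 1.0), 0.0)
    y = vt.T @ (inv * (u.T @ b_act))
    step = np.zeros(9)
    step[active] = d[active] * y
    return step, eliminated


def _pattern_partiality(hkl: np.ndarray, basis: np.ndarray, config: SimulationConfig):
    s = hkl @ np.asarray(basis).T
    geom = excitation_distances(s, config.beam, config.sphere_radius)
    cl = clamp_distances(geom)
    return partiality(cl), lorentz(geom, config.k_lorentz), cl


def update_pattern_model(pattern: Pattern, config: SimulationConfig) -> None:
    """Recompute p, L and excitation geometry of all observations from the working basis."""
    refl = pattern.reflections
    if not len(refl):
        return
    p, L, cl = _pattern_partiality(pattern.hkl, pattern.basis, config)
    refl["p"] = p
    refl["L"] = L
    refl["r_high"] = cl.r_high
    refl["r_low"] = cl.r_low
    refl["clamped_high"] = cl.clamped_high
    refl["clamped_low"] = cl.clamped_low


def refine_pattern(
    pattern: Pattern,
    merged: MergedIntensityTable,
    g: float,
    config: SimulationConfig,
    multiplicity: tuple,
    settings: RefinementSettings = RefinementSettings(),
) -> RefinementResult:
    """Refine one pattern's basis against the merged intensities.

    G_j is held fixed throughout the inner iterations (it is re-fitted
    at the next outer scaling step).  The pattern's working basis is
    updated in place on success; its stored p/L are NOT updated here
    (the outer driver refreshes all observations once per cycle).
    """
    refl = pattern.reflections
    result = RefinementResult(basis=pattern.basis.copy())
    if not len(refl):
        return result
    intensity = refl["I"].to_numpy()
    sigma = refl["sigma"].to_numpy()
    hkl_all = pattern.hkl
    canon = config.symmetry.canonicalize(hkl_all)
    i_full_all, _ = merged.lookup(canon)
    basis = pattern.basis.copy()

    for it in range(settings.max_iterations):
        p_now, _, _ = _pattern_partiality(hkl_all, basis, config)
        pattern_view = Pattern(pattern.pattern_id, basis, refl)
        sel = select_refinable(pattern_view, merged, config.symmetry, multiplicity, settings, p=p_now)
        if not sel.any():
            result.termination = "empty selection" if it == 0 else "selection exhausted"
            break
        hkl = hkl_all[sel]
        ne, p_sel, _ = build_normal_equations(
            hkl, basis, config, intensity[sel], sigma[sel], g, i_full_all[sel], settings
        )
        step, eliminated = solve_rescaled_svd(ne, settings.eig_frac)
        new_basis = basis_from_components(basis_components(basis) + step)
        p_new, _, _ = _pattern_partiality(hkl, new_basis, config)

        result.n_inner_iterations = it + 1
        result.eliminated_eigenvalues.append(eliminated)
        result.n_reflections_used = int(sel.sum())
        if np.mean(p_new == 0.0) > REVERT_ZERO_FRACTION:
            result.reverted = True
            result.termination = "step reverted"
            break
        basis = new_basis
        max_dp = float(np.abs(p_new - p_sel).max())
        result.max_delta_p.append(max_dp)
        if max_dp < settings.delta_p_converged:
            result.termination = "converged"
            break
    else:
        result.termination = "max iterations"

    pattern.basis = basis
    result.basis = basis.copy()
    return result


@dataclass
class CycleHistory:
    """State recorded after the initial merge and after each refinement cycle."""

    merged_tables: list = field(default_factory=list)   # MergedIntensityTable per cycle (0..n)
    scale_sets: list = field(default_factory=list)
    refinement_results: list = field(default_factory=list)  # list[list[RefinementResult]] per cycle >= 1
    partiality_correlation: list = field(default_factory=list)  # obs-vs-calc Pearson r per cycle

    @property
    def final_merged(self) -> MergedIntensityTable:
        return self.merged_tables[-1]

    @property
    def final_scales(self) -> ScaleSet:
        return self.scale_sets[-1]


def _pair_correlation(patterns, scales, merged, symmetry, p_min) -> float:
    from .evaluation import partiality_pairs  # local import to avoid a cycle

    _, corr = partiality_pairs(patterns, scales, merged, symmetry, subsample_target=None)
    return corr


def run_cycles(
    patterns: list,
    config: SimulationConfig,
    n_cycles: int = 3,
    mode: str = "standard",
    settings: RefinementSettings = RefinementSettings(),
    scaling_rounds: int = 3,
    track_correlation: bool = False,
) -> CycleHistory:
    """The full scale-merge-refine loop.

    ``mode`` selects the processing variant:

    * ``"standard"`` — scaling, merging and post-refinement as described
      in the module docstring; ``n_cycles = 0`` is the "no refinement"
      baseline (initial scaling and merging only).
    * ``"p_one"`` — all partialities forced to 1 (Lorentz correction
      only), Monte-Carlo-style merging with scaling; never refines.
    * ``"no_scaling"`` — all G = 1, no refinement.

    Patterns are modified in place (working basis, stored p/L, scale).
    """
    if mode not in ("standard", "p_one", "no_scaling"):
        raise ValueError(f"unknown mode {mode!r}")
    history = CycleHistory()
    symmetry = config.symmetry

    for pat in patterns:
        update_pattern_model(pat, config)
    if mode == "p_one":
        for pat in patterns:
            if len(pat.reflections):
                pat.reflections["p"] = 1.0

    if mode == "no_scaling":
        from .scaling import merge

        ids = np.array([p.pattern_id for p in patterns], dtype=int)
        scales = ScaleSet(np.ones(len(patterns)), ids, np.zeros(len(patterns), bool))
        merged = merge(patterns, scales, symmetry, p_min=settings.p_min)
    else:
        scales, merged = kabsch_scale_and_merge(
            patterns, symmetry, n_rounds=scaling_rounds, p_min=settings.p_min,
            weighted=settings.weighted,
        )
    history.merged_tables.append(merged)
    history.scale_sets.append(scales)
    if track_correlation:
        history.partiality_correlation.append(
            _pair_correlation(patterns, scales, merged, symmetry, settings.p_min)
        )

    if mode != "standard":
        return history

    for _ in range(n_cycles):
        multiplicity = build_multiplicity_index(patterns, symmetry, settings.p_min)
        cycle_results = []
        for pos, pat in enumerate(patterns):
            res = refine_pattern(
                pat, merged, float(scales.scales[pos]), config, multiplicity, settings
            )
            cycle_results.append(res)
            update_pattern_model(pat, config)
        history.refinement_results.append(cycle_results)
        scales, merged = kabsch_scale_and_merge(
            patterns, symmetry, n_rounds=scaling_rounds, p_min=settings.p_min,
            weighted=settings.weighted,
        )
        history.merged_tables.append(merged)
        history.scale_sets.append(scales)
        if track_correlation:
            history.partiality_correlation.append(
                _pair_correlation(patterns, scales, merged, symmetry, settings.p_min)
            )
    return history
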