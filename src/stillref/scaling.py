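"""Scaled-partials merging and iterative per-pattern scaling.

Full intensities are estimated by the "method of scaled partials":
each partial measurement is divided by its model partiality and Lorentz
factor, corrected by the pattern's overall scale factor G_j, and the
estimates for all symmetry equivalents are averaged:

    I_full(hkl) = sum_j sum_e I_ej,partial / (G_j p_ej L_ej) / N(hkl).

Measurements with partiality below ``p_min`` (default 0.1) are excluded
everywhere — tiny partialities amplify noise without bound.

Scale factors come from a linear-cost iterative scheme in the spirit of
Kabsch: merge with equal scales, fit each pattern's scale against the
merged table by least squares, re-merge, repeat a small number of
times.  The gauge (overall scale of the dataset) is fixed by
normalizing the mean G to 1 after each round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SymmetryGroup, hkl_pack, hkl_unpack
from .simulate import Pattern

__all__ = [
    "MergedIntensityTable",
    "ScaleSet",
    "scale_up",
    "merge",
    "fit_scale",
    "kabsch_scale_and_merge",
]

P_MIN_DEFAULT = 0.1


@dataclass
class MergedIntensityTable:
    """Merged full-intensity estimates keyed by packed canonical hkl."""

    keys: np.ndarray       # sorted packed canonical hkl
    intensity: np.ndarray  # mean scaled-up estimate
    n_meas: np.ndarray     # contributing measurements per hkl
    sigma: np.ndarray      # scatter-based error: sample sd / sqrt(n)
    d: np.ndarray          # angstrom

    def __post_init__(self) -> None:
        if np.any(self.n_meas < 1):
            raise ValueError("merged entries must have at least one contribution")

    def __len__(self) -> int:
        return len(self.keys)

    @property
    def hkl(self) -> np.ndarray:
        return hkl_unpack(self.keys)

    def lookup(self, canonical_hkl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(values, found_mask) for (N, 3) canonical indices."""
        q = hkl_pack(canonical_hkl)
        idx = np.clip(np.searchsorted(self.keys, q), 0, len(self.keys) - 1)
        found = (self.keys[idx] == q) if len(self.keys) else np.zeros(len(q), bool)
        vals = np.where(found, self.intensity[idx] if len(self.keys) else np.nan, np.nan)
        return vals, found

    def to_frame(self) -> pd.DataFrame:
        hkl = self.hkl
        return pd.DataFrame(
            {
                "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2],
                "I": self.intensity, "sigma": self.sigma,
                "nmeas": self.n_meas, "d": self.d,
            }
        )


@dataclass
class ScaleSet:
    """Per-pattern scale factors plus the fitting history."""

    scales: np.ndarray                     # indexed by position in the pattern list
    pattern_ids: np.ndarray
    unscaled: np.ndarray                   # patterns with no usable observations
    delta_history: list = field(default_factory=list)  # mean |dG| per round

    def __post_init__(self) -> None:
        if np.any(self.scales[~self.unscaled] <= 0):
            raise ValueError("fitted scale factors must be positive")

    def get(self, pattern_id: int) -> float:
        pos = int(np.flatnonzero(self.pattern_ids == pattern_id)[0])
        return float(self.scales[pos])


def scale_up(intensity: np.ndarray, p: np.ndarray, L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-observation full-intensity estimates I / (p L).

    Returns (estimates, valid_mask); observations with non-positive or
    non-finite p or L are flagged invalid (estimate NaN) rather than
    raising, since downstream rejection handles them.
    """
    p = np.asarray(p, dtype=float)
    L = np.asarray(L, dtype=float)
    valid = (p > 0) & (L > 0) & np.isfinite(p) & np.isfinite(L)
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.asarray(intensity, dtype=float) / (p * L)
    return np.where(valid, est, np.nan), valid


def _usable(pattern: Pattern, p_min: float) -> np.ndarray:
    p = pattern.reflections["p"].to_numpy()
    L = pattern.reflections["L"].to_numpy()
    return (p >= p_min) & (p > 0) & np.isfinite(L) & (L > 0)


def merge(
    patterns: list,
    scales: ScaleSet | None,
    symmetry: SymmetryGroup,
    p_min: float = P_MIN_DEFAULT,
    weighted: bool = False,
) -> MergedIntensityTable:
    """Merge all patterns into one table of full-intensity estimates.

    ``scales=None`` uses G_j = 1 for every pattern.  Estimates are the
    plain mean of G-corrected scaled-up values over all symmetry
    equivalents in all patterns (``weighted=True`` switches to inverse
    variance weights derived from each observation's sigma).
    """
    keys_all, est_all, w_all, d_all = [], [], [], []
    for pos, pat in enumerate(patterns):
        refl = pat.reflections
        if not len(refl):
            continue
        g = 1.0 if scales is None else float(scales.scales[pos])
        est, valid = scale_up(refl["I"].to_numpy(), refl["p"].to_numpy(), refl["L"].to_numpy())
        keep = valid & (refl["p"].to_numpy() >= p_min)
        if not keep.any():
            continue
        canon = symmetry.canonicalize(pat.hkl[keep])
        keys_all.append(hkl_pack(canon))
        est_all.append(est[keep] / g)
        if weighted:
            sig = refl["sigma"].to_numpy()[keep] / (
                refl["p"].to_numpy()[keep] * refl["L"].to_numpy()[keep] * g
            )
            w_all.append(1.0 / sig**2)
        smod = np.linalg.norm(pat.hkl[keep] @ np.asarray(pat.basis).T, axis=1)
        d_all.append(10.0 / smod)
    if not keys_all:
        return MergedIntensityTable(
            keys=np.empty(0, np.int64), intensity=np.empty(0), n_meas=np.empty(0, int),
            sigma=np.empty(0), d=np.empty(0),
        )
    keys = np.concatenate(keys_all)
    est = np.concatenate(est_all)
    d = np.concatenate(d_all)
    w = np.concatenate(w_all) if weighted else np.ones_like(est)

    uniq, inv = np.unique(keys, return_inverse=True)
    wsum = np.bincount(inv, weights=w)
    mean = np.bincount(inv, weights=w * est) / wsum
    n = np.bincount(inv).astype(int)
    # scatter-based sigma: sd of contributions / sqrt(n) (0 where n == 1)
    var = np.bincount(inv, weights=w * est**2) / wsum - mean**2
    sigma = np.sqrt(np.maximum(var, 0.0) / np.maximum(n, 1))
    d_mean = np.bincount(inv, weights=d) / np.maximum(np.bincount(inv), 1)
    return MergedIntensityTable(keys=uniq, intensity=mean, n_meas=n, sigma=sigma, d=d_mean)


def fit_scale(
    pattern: Pattern,
    reference: MergedIntensityTable,
    symmetry: SymmetryGroup,
    p_min: float = P_MIN_DEFAULT,
) -> tuple[float, bool]:
    """Least-squares scale of one pattern against a merged table.

    Minimizes sum (I_full,e - G Ihat)^2 over usable observations with a
    reference entry: G = sum(I_full,e Ihat) / sum(Ihat^2).  Returns
    (G, fitted); patterns with no usable overlap get (1.0, False).
    """
    refl = pattern.reflections
    if not len(refl):
        return 1.0, False
    est, valid = scale_up(refl["I"].to_numpy(), refl["p"].to_numpy(), refl["L"].to_numpy())
    keep = valid & (refl["p"].to_numpy() >= p_min)
    if not keep.any():
        return 1.0, False
    ref_vals, found = reference.lookup(symmetry.canonicalize(pattern.hkl[keep]))
    use = found & (ref_vals != 0)
    if not use.any():
        return 1.0, False
    num = float(np.sum(est[keep][use] * ref_vals[use]))
    den = float(np.sum(ref_vals[use] ** 2))
    if den <= 0 or num <= 0:
        return 1.0, False
    return num / den, True


def kabsch_scale_and_merge(
    patterns: list,
    symmetry: SymmetryGroup,
    n_rounds: int = 3,
    p_min: float = P_MIN_DEFAULT,
    weighted: bool = False,
) -> tuple[ScaleSet, MergedIntensityTable]:
    """Iterative scale determination and merging.

    Round 0 merges with all G = 1; each subsequent round fits every
    pattern's G against the current merged table, renormalizes mean G
    to 1, and re-merges.  Cost is linear in the number of patterns.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    ids = np.array([p.pattern_id for p in patterns], dtype=int)
    n = len(patterns)
    scales = ScaleSet(np.ones(n), ids, np.zeros(n, dtype=bool))
    merged = merge(patterns, None, symmetry, p_min=p_min, weighted=weighted)
    for _ in range(n_rounds):
        new = np.ones(n)
        unscaled = np.zeros(n, dtype=bool)
        for pos, pat in enumerate(patterns):
            g, ok = fit_scale(pat, merged, symmetry, p_min=p_min)
            new[pos] = g
            unscaled[pos] = not ok
        if (~unscaled).any():
            new[~unscaled] /= new[~unscaled].mean()
        delta = float(np.abs(new - scales.scales).mean())
        scales = ScaleSet(new, ids, unscaled, scales.delta_history + [delta])
        merged = merge(patterns, scales, symmetry, p_min=p_min, weighted=weighted)
    for pos, pat in enumerate(patterns):
        pat.scale = float(scales.scales[pos])
    return scales, merged
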