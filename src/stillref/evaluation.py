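"""Quality diagnostics: R-factors in resolution shells and partiality plots.

The headline statistic is the intensity R-factor between the merged
table and the reference intensities that generated the test data,

    R = sum |I_merged - k I_ref| / sum k I_ref,

with a single least-squares scale k fitted over all common reflections
(the simulator's intensity units are arbitrary, so R must be gauge
invariant).  R is reported overall and in equal-count resolution
shells.

The "observed partiality" of a measurement is its intensity corrected
for the pattern scale and Lorentz factor but NOT for partiality,
divided by the current full-intensity estimate:

    p_obs = I_partial / (G_j L_ej I_full).

Plotted against the model ("calculated") partiality it shows directly
how informative the geometric model is; the Pearson correlation over
all pairs summarizes it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SymmetryGroup, hkl_pack
from .scaling import MergedIntensityTable, ScaleSet
from .simulate import ReferenceIntensityTable

__all__ = [
    "ShellTable",
    "r_factor_shells",
    "partiality_pairs",
    "shell_statistics",
]


@dataclass
class ShellTable:
    """Per-shell statistic plus the overall value."""

    table: pd.DataFrame  # columns: d_max, d_min, n, value
    overall: float
    statistic: str

    def __len__(self) -> int:
        return len(self.table)


def _match_tables(merged: MergedIntensityTable, reference: ReferenceIntensityTable):
    common, mi, ri = np.intersect1d(merged.keys, reference.keys, return_indices=True)
    if len(common) == 0:
        raise ValueError("merged and reference tables share no reflections")
    return merged.intensity[mi], reference.intensity[ri], reference.d[ri]


def r_factor_shells(
    merged: MergedIntensityTable,
    reference: ReferenceIntensityTable,
    n_shells: int = 10,
) -> ShellTable:
    """Intensity R-factor overall and in equal-count resolution shells.

    One overall scale k = sum(I_m I_r) / sum(I_r^2) is fitted across all
    common reflections and used in every shell, so R vanishes for
    tables identical up to a constant factor.
    """
    i_m, i_r, d = _match_tables(merged, reference)
    k = float(np.sum(i_m * i_r) / np.sum(i_r**2))
    overall = float(np.sum(np.abs(i_m - k * i_r)) / np.sum(k * i_r))

    order = np.argsort(-d)  # low resolution (large d) first
    edges = np.array_split(order, min(n_shells, len(order)))
    rows = []
    for shell in edges:
        if len(shell) == 0:
            continue
        num = np.sum(np.abs(i_m[shell] - k * i_r[shell]))
        den = np.sum(k * i_r[shell])
        rows.append(
            {
                "d_max": float(d[shell].max()),
                "d_min": float(d[shell].min()),
                "n": int(len(shell)),
                "value": float(num / den),
            }
        )
    return ShellTable(pd.DataFrame(rows), overall, "R-factor")


def partiality_pairs(
    patterns: list,
    scales: ScaleSet,
    merged: MergedIntensityTable,
    symmetry: SymmetryGroup,
    subsample_target: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, float]:
    """Observed-vs-calculated partiality pairs and their Pearson correlation.

    Pairs whose full-intensity estimate is missing or zero are skipped.
    The summary Pearson correlation is computed over the pairs whose
    full-intensity estimate is *significant* (at least two contributing
    measurements and I_full > 3x its standard error): p_obs is a ratio
    with I_full in the denominator, so near-zero estimates produce
    unbounded outliers that would otherwise dominate the correlation of
    an arbitrarily large sample.  The returned frame keeps all pairs
    (optionally subsampled to about ``subsample_target`` points, the
    typical single-pattern reflection count, for plotting) with a
    ``significant`` flag column.
    """
    p_calc_all, p_obs_all, sig_all, hkl_h, hkl_k, hkl_l, pid = [], [], [], [], [], [], []
    for pos, pat in enumerate(patterns):
        refl = pat.reflections
        if not len(refl):
            continue
        g = float(scales.scales[pos])
        canon = symmetry.canonicalize(pat.hkl)
        i_full, found = merged.lookup(canon)
        q = hkl_pack(canon)
        idx = np.clip(np.searchsorted(merged.keys, q), 0, max(len(merged.keys) - 1, 0))
        n_meas = np.where(found, merged.n_meas[idx] if len(merged.keys) else 0, 0)
        i_se = np.where(found, merged.sigma[idx] if len(merged.keys) else np.inf, np.inf)
        L = refl["L"].to_numpy()
        ok = found & (i_full != 0) & np.isfinite(L) & (L > 0)
        if not ok.any():
            continue
        p_obs = refl["I"].to_numpy()[ok] / (g * L[ok] * i_full[ok])
        p_calc_all.append(refl["p"].to_numpy()[ok])
        p_obs_all.append(p_obs)
        sig_all.append((n_meas[ok] >= 2) & (i_full[ok] > 3.0 * i_se[ok]))
        hkl = pat.hkl[ok]
        hkl_h.append(hkl[:, 0]); hkl_k.append(hkl[:, 1]); hkl_l.append(hkl[:, 2])
        pid.append(np.full(ok.sum(), pat.pattern_id))
    if not p_calc_all:
        return (
            pd.DataFrame(columns=["h", "k", "l", "pattern", "p_calc", "p_obs", "significant"]),
            float("nan"),
        )
    frame = pd.DataFrame(
        {
            "h": np.concatenate(hkl_h),
            "k": np.concatenate(hkl_k),
            "l": np.concatenate(hkl_l),
            "pattern": np.concatenate(pid),
            "p_calc": np.concatenate(p_calc_all),
            "p_obs": np.concatenate(p_obs_all),
            "significant": np.concatenate(sig_all),
        }
    )
    sig = frame[frame["significant"]]
    if len(sig) > 1 and sig["p_calc"].std() > 0 and sig["p_obs"].std() > 0:
        corr = float(np.corrcoef(sig["p_calc"], sig["p_obs"])[0, 1])
    else:
        corr = float("nan")
    if subsample_target is not None and len(frame) > subsample_target:
        rng = rng or np.random.default_rng(0)
        take = rng.random(len(frame)) < subsample_target / len(frame)
        frame = frame[take].reset_index(drop=True)
    return frame, corr


def shell_statistics(patterns: list, n_shells: int = 20) -> dict:
    """Reflection count, mean and max partiality in equal-1/d-width shells.

    Computed over every simulated observation (before any rejection),
    mirroring how the raw test dataset is characterized.
    """
    d_all, p_all = [], []
    for pat in patterns:
        refl = pat.reflections
        if not len(refl):
            continue
        smod = np.linalg.norm(pat.hkl @ np.asarray(pat.basis).T, axis=1)
        d_all.append(10.0 / smod)
        p_all.append(refl["p"].to_numpy())
    if not d_all:
        raise ValueError("no observations to bin")
    d = np.concatenate(d_all)
    p = np.concatenate(p_all)
    inv_d = 1.0 / d
    edges = np.linspace(inv_d.min(), inv_d.max(), n_shells + 1)
    which = np.clip(np.digitize(inv_d, edges) - 1, 0, n_shells - 1)

    rows = []
    for i in range(n_shells):
        m = which == i
        rows.append(
            {
                "d_max": 1.0 / edges[i] if edges[i] > 0 else np.inf,
                "d_min": 1.0 / edges[i + 1],
                "n": int(m.sum()),
                "mean_p": float(p[m].mean()) if m.any() else np.nan,
                "max_p": float(p[m].max()) if m.any() else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    return {
        "n_reflections": ShellTable(frame[["d_max", "d_min", "n"]].assign(value=frame["n"]), float(len(d)), "count"),
        "mean_p": ShellTable(frame[["d_max", "d_min", "n"]].assign(value=frame["mean_p"]), float(p.mean()), "mean partiality"),
        "max_p": ShellTable(frame[["d_max", "d_min", "n"]].assign(value=frame["max_p"]), float(p.max()), "max partiality"),
    }
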