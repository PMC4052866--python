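"""Text file formats: per-pattern reflection streams, HKL tables, config.

A dataset directory holds:

* ``patterns.stream`` — per-pattern blocks delimited by begin/end
  markers, each with the nine working-basis components (nm^-1), the
  current scale factor, and one line per reflection
  ``h k l I sigma p L``;
* ``reference.hkl`` / ``merged.hkl`` — whitespace-separated tables with
  a comment header (``h k l I`` plus optional columns);
* ``truth.json`` — ground truth (true bases, true scales, noise sigma)
  kept separately so that processing code cannot see it by accident.

Intensities are printed at %.6e and basis components at %.8e, and a
write-then-read round trip reproduces every numeric field to that
precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import (
    BeamModel,
    DetectorModel,
    SymmetryGroup,
    UnitCell,
    basis_components,
    basis_from_components,
)
from .scaling import MergedIntensityTable
from .simulate import (
    Pattern,
    ReferenceIntensityTable,
    SimulatedDataset,
    SimulationConfig,
    TruthRecord,
)

__all__ = [
    "write_patterns",
    "read_patterns",
    "write_hkl",
    "read_reference_hkl",
    "write_merged_hkl",
    "read_merged_hkl",
    "write_dataset",
    "read_dataset",
    "load_config",
]

_BEGIN = "----- begin pattern"
_END = "----- end pattern"


class StreamFormatError(ValueError):
    """Malformed stream or HKL file; message names the offending line."""


def write_patterns(path, patterns: list) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# stillref reflection stream, version 1\n")
        for pat in patterns:
            fh.write(f"{_BEGIN}\n")
            fh.write(f"id {pat.pattern_id}\n")
            comps = " ".join(f"{v:.8e}" for v in basis_components(pat.basis))
            fh.write(f"basis {comps}\n")
            fh.write(f"scale {pat.scale:.8e}\n")
            fh.write(f"nrefl {len(pat.reflections)}\n")
            refl = pat.reflections
            for row in refl.itertuples(index=False):
                fh.write(
                    f"{int(row.h)} {int(row.k)} {int(row.l)} "
                    f"{row.I:.6e} {row.sigma:.6e} {row.p:.6e} {row.L:.6e}\n"
                )
            fh.write(f"{_END}\n")


def _parse_int(tok: str, lineno: int, what: str) -> int:
    try:
        return int(tok)
    except ValueError:
        raise StreamFormatError(f"line {lineno}: non-integer {what}: {tok!r}") from None


def read_patterns(path) -> list:
    """Parse a reflection stream; raises :class:`StreamFormatError` with line numbers."""
    path = Path(path)
    patterns: list[Pattern] = []
    state = None  # None | dict while inside a block
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == _BEGIN:
                if state is not None:
                    raise StreamFormatError(f"line {lineno}: nested pattern block")
                state = {"rows": [], "id": len(patterns), "basis": None, "scale": 1.0}
                continue
            if line == _END:
                if state is None:
                    raise StreamFormatError(f"line {lineno}: end marker outside block")
                if state["basis"] is None:
                    raise StreamFormatError(f"line {lineno}: pattern block missing basis")
                rows = state["rows"]
                frame = pd.DataFrame(
                    rows, columns=["h", "k", "l", "I", "sigma", "p", "L"]
                ) if rows else pd.DataFrame(columns=["h", "k", "l", "I", "sigma", "p", "L"])
                for extra in ("r_high", "r_low", "det_x", "det_y"):
                    frame[extra] = np.nan
                frame["clamped_high"] = False
                frame["clamped_low"] = False
                patterns.append(
                    Pattern(state["id"], state["basis"], frame, scale=state["scale"])
                )
                state = None
                continue
            if state is None:
                raise StreamFormatError(f"line {lineno}: content outside pattern block")
            toks = line.split()
            if toks[0] == "id":
                state["id"] = _parse_int(toks[1], lineno, "pattern id")
            elif toks[0] == "basis":
                if len(toks) != 10:
                    raise StreamFormatError(f"line {lineno}: basis needs nine components")
                state["basis"] = basis_from_components([float(t) for t in toks[1:]])
            elif toks[0] == "scale":
                state["scale"] = float(toks[1])
            elif toks[0] == "nrefl":
                state["expected"] = _parse_int(toks[1], lineno, "reflection count")
            else:
                if len(toks) != 7:
                    raise StreamFormatError(
                        f"line {lineno}: expected 'h k l I sigma p L', got {len(toks)} fields"
                    )
                h = _parse_int(toks[0], lineno, "h")
                k = _parse_int(toks[1], lineno, "k")
                l = _parse_int(toks[2], lineno, "l")
                state["rows"].append((h, k, l, *[float(t) for t in toks[3:]]))
    if state is not None:
        raise StreamFormatError("unterminated pattern block at end of file")
    return patterns


def write_hkl(path, frame: pd.DataFrame, columns: list, header: str) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {header}\n")
        fh.write("# " + " ".join(columns) + "\n")
        for row in frame[columns].itertuples(index=False):
            parts = []
            for name, val in zip(columns, row):
                if name in ("h", "k", "l", "nmeas"):
                    parts.append(str(int(val)))
                else:
                    parts.append(f"{val:.6e}")
            fh.write(" ".join(parts) + "\n")


def _read_table(path, columns: list) -> pd.DataFrame:
    rows = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != len(columns):
                raise StreamFormatError(
                    f"line {lineno}: expected {len(columns)} fields, got {len(toks)}"
                )
            row = []
            for name, tok in zip(columns, toks):
                if name in ("h", "k", "l", "nmeas"):
                    row.append(_parse_int(tok, lineno, name))
                else:
                    row.append(float(tok))
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def read_reference_hkl(path) -> ReferenceIntensityTable:
    frame = _read_table(path, ["h", "k", "l", "I", "d"])
    return ReferenceIntensityTable(
        hkl=frame[["h", "k", "l"]].to_numpy(np.int64),
        intensity=frame["I"].to_numpy(),
        d=frame["d"].to_numpy(),
    )


def write_merged_hkl(path, merged: MergedIntensityTable) -> None:
    write_hkl(
        path, merged.to_frame(), ["h", "k", "l", "I", "sigma", "nmeas", "d"],
        "stillref merged intensities",
    )


def read_merged_hkl(path) -> MergedIntensityTable:
    frame = _read_table(path, ["h", "k", "l", "I", "sigma", "nmeas", "d"])
    from .geometry import hkl_pack

    keys = hkl_pack(frame[["h", "k", "l"]].to_numpy(np.int64))
    order = np.argsort(keys)
    return MergedIntensityTable(
        keys=keys[order],
        intensity=frame["I"].to_numpy()[order],
        n_meas=frame["nmeas"].to_numpy(int)[order],
        sigma=frame["sigma"].to_numpy()[order],
        d=frame["d"].to_numpy()[order],
    )


def write_dataset(out_dir, dataset: SimulatedDataset) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_patterns(out / "patterns.stream", dataset.patterns)
    write_hkl(
        out / "reference.hkl", dataset.reference.to_frame(), ["h", "k", "l", "I", "d"],
        "stillref reference (true full) intensities",
    )
    truth = {
        "noise_sigma": dataset.truth.noise_sigma,
        "seed": dataset.truth.seed,
        "true_scales": [float(g) for g in dataset.truth.true_scales],
        "true_bases": [list(map(float, basis_components(b))) for b in dataset.truth.true_bases],
    }
    (out / "truth.json").write_text(json.dumps(truth))


def read_dataset(in_dir, config: SimulationConfig) -> SimulatedDataset:
    """Load a dataset directory written by :func:`write_dataset`.

    The config supplies the beam/detector/symmetry context, which the
    text files do not carry.
    """
    in_dir = Path(in_dir)
    patterns = read_patterns(in_dir / "patterns.stream")
    reference = read_reference_hkl(in_dir / "reference.hkl")
    truth_raw = json.loads((in_dir / "truth.json").read_text())
    truth = TruthRecord(
        true_bases=[basis_from_components(v) for v in truth_raw["true_bases"]],
        true_scales=np.asarray(truth_raw["true_scales"]),
        noise_sigma=truth_raw["noise_sigma"],
        seed=truth_raw["seed"],
    )
    return SimulatedDataset(patterns, reference, truth, config)


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a flat YAML mapping.

    Recognized keys (all optional, defaults as in SimulationConfig):
    n_patterns, cell_a_rh, cell_alpha_deg, symmetry (space-group label,
    or "P1"), merge_friedel, photon_energy_kev, bandwidth_frac,
    convergence_rad, detector_side_mm, detector_distance_mm,
    sphere_radius_nm_inv, basis_error_max_frac, scale_mean, scale_sd,
    wilson_b, wilson_mean_intensity, noise_sigma, seed.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cell = UnitCell(raw.get("cell_a_rh", 144.2), raw.get("cell_alpha_deg", 113.78))
    label = raw.get("symmetry", "R 3 2:R")
    if label.strip().upper() == "P1":
        sym = SymmetryGroup.from_spacegroup("P 1", laue=raw.get("merge_friedel", True))
    else:
        sym = SymmetryGroup.from_spacegroup(label, laue=raw.get("merge_friedel", True))
    beam = BeamModel(
        raw.get("photon_energy_kev", 8.0),
        bandwidth_frac=raw.get("bandwidth_frac", 5e-4),
        convergence_rad=raw.get("convergence_rad", 1e-3),
    )
    det = DetectorModel(raw.get("detector_side_mm", 76.8), raw.get("detector_distance_mm", 50.0))
    return SimulationConfig(
        n_patterns=raw.get("n_patterns", 1000),
        cell=cell,
        symmetry=sym,
        beam=beam,
        detector=det,
        sphere_radius=raw.get("sphere_radius_nm_inv", 5e-3),
        basis_error_max_frac=raw.get("basis_error_max_frac", 1e-3),
        scale_mean=raw.get("scale_mean", 1.0),
        scale_sd=raw.get("scale_sd", 0.3),
        wilson_b=raw.get("wilson_b", 50.0),
        wilson_mean_intensity=raw.get("wilson_mean_intensity", 1000.0),
        noise_sigma=raw.get("noise_sigma"),
        seed=raw.get("seed", 0),
    )
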