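"""Unit cells, beam/detector models, reciprocal bases and symmetry folding.

Conventions used throughout the package:

* Reciprocal space is expressed in nm^-1.  Wavelengths are quoted in
  angstrom at the API boundary and converted internally.
* The incident beam travels along +z.  The nominal Ewald sphere has
  radius 1/lambda and is centred at (0, 0, -1/lambda) in nm^-1, so the
  origin of reciprocal space lies on the sphere.
* A reciprocal basis is a 3x3 ``numpy`` array whose *columns* are the
  Cartesian components of a*, b* and c* in nm^-1, so the scattering
  vector of reflection (h, k, l) is ``basis @ (h, k, l)``.  The flat
  nine-component order used for serialization and refinement is
  (a*x, a*y, a*z, b*x, b*y, b*z, c*x, c*y, c*z), i.e. ``basis.T.ravel()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

#: Photon energy [keV] times wavelength [angstrom] (CODATA, rounded).
HC_KEV_ANGSTROM = 12.39842


def energy_to_wavelength(energy_kev: float) -> float:
    """Convert a photon energy in keV to a wavelength in angstrom."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def wavelength_to_energy(wavelength_angstrom: float) -> float:
    """Inverse of :func:`energy_to_wavelength`."""
    if wavelength_angstrom <= 0:
        raise ValueError("wavelength must be positive")
    return HC_KEV_ANGSTROM / wavelength_angstrom


@dataclass(frozen=True)
class UnitCell:
    """Rhombohedral unit cell with derived hexagonal setting.

    Parameters
    ----------
    a_rh:
        Rhombohedral cell edge in angstrom.
    alpha_rh:
        Rhombohedral cell angle in degrees; must lie in (0, 120) so the
        hexagonal c axis is real.
    setting:
        Which axes Miller indices refer to ("rhombohedral" uses the
        primitive cell; "hexagonal" the triple obverse cell).
    """

    a_rh: float
    alpha_rh: float
    setting: str = "rhombohedral"

    def __post_init__(self) -> None:
        if self.a_rh <= 0:
            raise ValueError("cell edge must be positive")
        if not 0 < self.alpha_rh < 120:
            raise ValueError("rhombohedral alpha must lie in (0, 120) degrees")
        if self.setting not in ("rhombohedral", "hexagonal"):
            raise ValueError(f"unknown setting {self.setting!r}")

    @property
    def a_hex(self) -> float:
        """Hexagonal a axis [angstrom]: 2 a_rh sin(alpha/2)."""
        return 2.0 * self.a_rh * np.sin(np.radians(self.alpha_rh) / 2.0)

    @property
    def c_hex(self) -> float:
        """Hexagonal c axis [angstrom]: a_rh sqrt(3 (1 + 2 cos alpha))."""
        ca = np.cos(np.radians(self.alpha_rh))
        return self.a_rh * np.sqrt(3.0 * (1.0 + 2.0 * ca))

    def gemmi_cell(self) -> gemmi.UnitCell:
        """The cell in the active setting as a :class:`gemmi.UnitCell`."""
        if self.setting == "rhombohedral":
            a, al = self.a_rh, self.alpha_rh
            return gemmi.UnitCell(a, a, a, al, al, al)
        return gemmi.UnitCell(self.a_hex, self.a_hex, self.c_hex, 90.0, 90.0, 120.0)

    @property
    def volume(self) -> float:
        """Cell volume in the active setting [angstrom^3]."""
        return self.gemmi_cell().volume

    def reference_reciprocal_basis(self) -> np.ndarray:
        """Reciprocal basis B0 (columns a*, b*, c*) in nm^-1, unrotated.

        Uses the standard crystallographic orthogonalization: the rows
        of the fractionalization matrix are a*, b*, c* in angstrom^-1.
        """
        frac = np.asarray(self.gemmi_cell().frac.mat)
        return frac.T * 10.0  # A^-1 -> nm^-1


@dataclass(frozen=True)
class BeamModel:
    """Incident beam: nominal energy plus top-hat bandwidth and convergence.

    ``bandwidth_frac`` is the *full* fractional width of a top-hat
    spectrum, i.e. wavelengths cover lambda0 * [1 - bw/2, 1 + bw/2];
    ``convergence`` is the full convergence angle in radians, i.e. the
    incident direction tilts by up to convergence/2 away from +z.
    """

    photon_energy_kev: float
    bandwidth_frac: float = 0.0
    convergence_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.photon_energy_kev <= 0:
            raise ValueError("photon energy must be positive")
        if self.bandwidth_frac < 0 or self.convergence_rad < 0:
            raise ValueError("bandwidth and convergence must be non-negative")

    @property
    def wavelength_angstrom(self) -> float:
        return energy_to_wavelength(self.photon_energy_kev)

    @property
    def wavelength_nm(self) -> float:
        return self.wavelength_angstrom * 0.1

    @property
    def ewald_radius(self) -> float:
        """Radius of the nominal Ewald sphere [nm^-1]."""
        return 1.0 / self.wavelength_nm


@dataclass(frozen=True)
class DetectorModel:
    """Square detector centred on and normal to the beam axis."""

    side_mm: float
    distance_mm: float

    def __post_init__(self) -> None:
        if self.side_mm <= 0 or self.distance_mm <= 0:
            raise ValueError("detector side and distance must be positive")


def detector_resolution_limits(det: DetectorModel, wavelength_angstrom: float) -> tuple[float, float]:
    """Resolution (d, angstrom) at the detector edge midpoint and corner.

    A spot at radius rho on the detector scatters through
    2 theta = atan(rho / distance), hence d = lambda / (2 sin theta).
    """
    if wavelength_angstrom <= 0:
        raise ValueError("wavelength must be positive")
    half = det.side_mm / 2.0

    def d_at(rho: float) -> float:
        theta = 0.5 * np.arctan2(rho, det.distance_mm)
        return wavelength_angstrom / (2.0 * np.sin(theta))

    return d_at(half), d_at(half * np.sqrt(2.0))


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """A rotation matrix drawn uniformly (Haar measure) via unit quaternions."""
    return Rotation.random(random_state=rng).as_matrix()


def cell_to_reciprocal_basis(cell: UnitCell, orientation: np.ndarray | None = None) -> np.ndarray:
    """Reciprocal basis of ``cell`` rotated by ``orientation`` (nm^-1).

    ``orientation`` must be a proper rotation matrix; ``None`` means the
    reference (unrotated) setting.
    """
    b0 = cell.reference_reciprocal_basis()
    if orientation is None:
        return b0
    r = np.asarray(orientation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-9) or np.linalg.det(r) < 0:
        raise ValueError("orientation must be a proper rotation matrix")
    return r @ b0


def check_basis(basis: np.ndarray) -> np.ndarray:
    """Validate a reciprocal basis: 3x3, non-singular, positive cell volume."""
    b = np.asarray(basis, dtype=float)
    if b.shape != (3, 3):
        raise ValueError("reciprocal basis must be a 3x3 matrix")
    if abs(np.linalg.det(b)) < 1e-30:
        raise ValueError("reciprocal basis is singular")
    return b


def basis_components(basis: np.ndarray) -> np.ndarray:
    """Flatten a basis to the nine-component order (a*x ... c*z)."""
    return np.asarray(basis).T.ravel().copy()


def basis_from_components(v: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`basis_components`."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (9,):
        raise ValueError("expected nine components")
    return arr.reshape(3, 3).T.copy()


def scattering_vectors(hkl: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Scattering vectors s = h a* + k b* + l c* [nm^-1] for (N, 3) hkl."""
    h = np.atleast_2d(np.asarray(hkl))
    return h @ np.asarray(basis).T


def resolution_d(hkl: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """d-spacing [angstrom] per reflection; (0,0,0) maps to +inf."""
    s = scattering_vectors(hkl, basis)
    mod = np.linalg.norm(s, axis=-1)
    with np.errstate(divide="ignore"):
        return np.where(mod > 0, 10.0 / np.where(mod > 0, mod, 1.0), np.inf)


# ---------------------------------------------------------------------------
# Symmetry

def _dedupe(mats: Iterable[np.ndarray]) -> list[np.ndarray]:
    seen: dict[bytes, np.ndarray] = {}
    for m in mats:
        seen.setdefault(np.asarray(m, dtype=np.int64).tobytes(), np.asarray(m, dtype=np.int64))
    return list(seen.values())


@dataclass(frozen=True)
class SymmetryGroup:
    """A finite group of integer matrices acting on (h, k, l) columns.

    Used as the merging symmetry.  Validated on construction: must
    contain the identity, be closed under composition, and every matrix
    must have determinant +-1.
    """

    matrices: tuple = ()
    label: str = "P1"

    def __post_init__(self) -> None:
        mats = _dedupe(self.matrices) if self.matrices else [np.eye(3, dtype=np.int64)]
        object.__setattr__(self, "matrices", tuple(m for m in mats))
        keys = {m.tobytes() for m in self.matrices}
        if np.eye(3, dtype=np.int64).tobytes() not in keys:
            raise ValueError("symmetry group must contain the identity")
        for m in self.matrices:
            if round(abs(np.linalg.det(m))) != 1:
                raise ValueError("symmetry matrices must have determinant +-1")
            for n in self.matrices:
                if (m @ n).astype(np.int64).tobytes() not in keys:
                    raise ValueError("symmetry group is not closed under composition")

    @property
    def order(self) -> int:
        return len(self.matrices)

    @classmethod
    def identity_only(cls) -> "SymmetryGroup":
        return cls((np.eye(3, dtype=np.int64),), "P1")

    @classmethod
    def from_spacegroup(cls, name: str, laue: bool = True) -> "SymmetryGroup":
        """Rotational (point-group) part of a space group, by gemmi name.

        Reflections transform by the transpose of the real-space
        rotation part; translations are irrelevant for merging.  With
        ``laue=True`` (default) the inversion is adjoined so Friedel
        mates merge together.
        """
        sg = gemmi.find_spacegroup_by_name(name)
        if sg is None:
            raise ValueError(f"unknown space group {name!r}")
        mats = []
        for op in sg.operations():
            rot = np.asarray(op.rot, dtype=np.int64)
            if np.any(rot % op.DEN):
                continue  # centering-induced fractional parts never occur in rot
            mats.append((rot // op.DEN).T)
        if laue:
            mats.extend([-m for m in mats])
        return cls(tuple(_dedupe(mats)), name if not laue else f"Laue({name})")

    def orbit(self, hkl: Sequence[int]) -> set[tuple[int, int, int]]:
        """All symmetry equivalents of one reflection."""
        v = np.asarray(hkl, dtype=np.int64)
        return {tuple(int(x) for x in m @ v) for m in self.matrices}

    def canonicalize(self, hkl: np.ndarray) -> np.ndarray:
        """Canonical (asymmetric-unit) representative per reflection.

        The representative is the lexicographically greatest (h, k, l)
        in the orbit — a fixed total order, hence idempotent and stable.
        Vectorized over an (N, 3) array.
        """
        h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        best = h @ self.matrices[0].T
        for m in self.matrices[1:]:
            cand = h @ m.T
            gt = (
                (cand[:, 0] > best[:, 0])
                | ((cand[:, 0] == best[:, 0]) & (cand[:, 1] > best[:, 1]))
                | (
                    (cand[:, 0] == best[:, 0])
                    & (cand[:, 1] == best[:, 1])
                    & (cand[:, 2] > best[:, 2])
                )
            )
            best[gt] = cand[gt]
        return best if np.asarray(hkl).ndim == 2 else best[0]

    def canonical(self, hkl: Sequence[int]) -> tuple[int, int, int]:
        return tuple(int(x) for x in self.canonicalize(np.asarray(hkl)))


# Packed integer keys for fast hkl table lookups (|index| < 512).
_SHIFT = 10
_OFFSET = 512


def hkl_pack(hkl: np.ndarray) -> np.ndarray:
    """Pack (N, 3) integer hkl into sortable int64 keys."""
    h = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
    if np.any(np.abs(h) >= _OFFSET):
        raise ValueError("Miller indices out of packable range (|h|<512)")
    return ((h[:, 0] + _OFFSET) << (2 * _SHIFT)) | ((h[:, 1] + _OFFSET) << _SHIFT) | (h[:, 2] + _OFFSET)


def hkl_unpack(keys: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hkl_pack`."""
    k = np.asarray(keys, dtype=np.int64)
    mask = (1 << _SHIFT) - 1
    return np.stack(
        [(k >> (2 * _SHIFT)) - _OFFSET, ((k >> _SHIFT) & mask) - _OFFSET, (k & mask) - _OFFSET],
        axis=-1,
    )
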