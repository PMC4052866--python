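"""Geometric partiality model for still (snapshot) diffraction.

Each reciprocal lattice point carries a sphere of scattering density of
radius ``r`` (a model constant, nm^-1).  The beam's spectral bandwidth
and convergence generate a nest of Ewald spheres; the partiality of a
reflection is the volume fraction of its sphere lying between the two
limiting (extreme) Ewald spheres of the nest.

Signed distances ``r_high <= r_low`` locate the two limiting sphere
surfaces relative to the point centre, measured radially from the Ewald
sphere centre: for a limiting sphere of radius R centred at c the
distance is ``e = R - |s - c|``, negative when the sphere surface lies
closer to the Ewald centre than the point does.  Over the extent of the
reflection sphere the two surfaces are treated as parallel planes (the
sphere radius, ~5e-3 nm^-1, is three orders of magnitude below the
Ewald radius), so the excited volume is a slab cut from the sphere and
its fraction follows from spherical-cap volumes.

The nest is sampled at its four extreme members: the two wavelength
extremes of the top-hat spectrum crossed with the incident-beam tilt of
+-convergence/2 in the plane containing the beam axis and s.  In-plane
tilt extremizes the excitation distance over the tilt cone, so these
four spheres bound the full nest exactly to first order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BeamModel

__all__ = [
    "ExcitationGeometry",
    "excitation_distances",
    "excitation_distances_and_sgrad",
    "clamp_distances",
    "cap_fraction",
    "cap_fraction_derivative",
    "partiality",
    "lorentz",
    "lorentz_normalization",
    "partiality_gradients",
]


@dataclass
class ExcitationGeometry:
    """Signed distances to the limiting Ewald spheres, vectorized.

    ``r_high <= r_low`` element-wise (r_low belongs to the limiting
    sphere whose surface lies farther from the Ewald centre).  Clamp
    flags are set by :func:`clamp_distances`.
    """

    r_high: np.ndarray
    r_low: np.ndarray
    r: float
    clamped_high: np.ndarray | None = None
    clamped_low: np.ndarray | None = None

    @property
    def clamped(self) -> bool:
        return self.clamped_high is not None


def _nest_extreme_spheres(s: np.ndarray, beam: BeamModel) -> tuple[np.ndarray, np.ndarray]:
    """Centres (4, N, 3) and radii (4,) of the four extreme Ewald spheres.

    The tilt plane contains the beam axis and s, so centres depend on
    the azimuth of each s.
    """
    lam0 = beam.wavelength_nm
    radii = np.array(
        [
            1.0 / (lam0 * (1.0 - beam.bandwidth_frac / 2.0)),
            1.0 / (lam0 * (1.0 - beam.bandwidth_frac / 2.0)),
            1.0 / (lam0 * (1.0 + beam.bandwidth_frac / 2.0)),
            1.0 / (lam0 * (1.0 + beam.bandwidth_frac / 2.0)),
        ]
    )
    tilts = np.array([+0.5, -0.5, +0.5, -0.5]) * beam.convergence_rad

    sxy = np.hypot(s[:, 0], s[:, 1])
    # unit azimuth of s in the xy plane; arbitrary (x) for on-axis points
    ok = sxy > 0
    ux = np.where(ok, s[:, 0] / np.where(ok, sxy, 1.0), 1.0)
    uy = np.where(ok, s[:, 1] / np.where(ok, sxy, 1.0), 0.0)

    centres = np.empty((4, s.shape[0], 3))
    for i in range(4):
        st, ct = np.sin(tilts[i]), np.cos(tilts[i])
        # incident direction tilted by tilts[i] toward the azimuth of s
        centres[i, :, 0] = -radii[i] * st * ux
        centres[i, :, 1] = -radii[i] * st * uy
        centres[i, :, 2] = -radii[i] * ct
    return centres, radii


def excitation_distances(s: np.ndarray, beam: BeamModel, r: float) -> ExcitationGeometry:
    """Unclamped signed distances to the limiting Ewald spheres.

    Parameters
    ----------
    s:
        (N, 3) scattering vectors in nm^-1; zero vectors are rejected.
    beam:
        Beam model supplying the nest of Ewald spheres.
    r:
        Reflection-sphere radius (model constant, nm^-1), carried along
        for clamping and partiality.
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    if np.any(np.linalg.norm(s, axis=1) == 0):
        raise ValueError("zero-length scattering vector has no excitation geometry")
    centres, radii = _nest_extreme_spheres(s, beam)
    dist = np.linalg.norm(s[None, :, :] - centres, axis=2)
    e = radii[:, None] - dist
    return ExcitationGeometry(r_high=e.min(axis=0), r_low=e.max(axis=0), r=r)


def excitation_distances_and_sgrad(
    s: np.ndarray, beam: BeamModel, r: float
) -> tuple[ExcitationGeometry, np.ndarray, np.ndarray]:
    """Excitation distances plus d(r_high)/ds and d(r_low)/ds, each (N, 3).

    The gradient of each extreme is that of its active nest member with
    the member's centre held fixed; the dependence of the tilt plane on
    s drops out to first order because the in-plane tilt extremizes the
    distance over the tilt cone (envelope argument).
    """
    s = np.atleast_2d(np.asarray(s, dtype=float))
    centres, radii = _nest_extreme_spheres(s, beam)
    diff = s[None, :, :] - centres
    dist = np.linalg.norm(diff, axis=2)
    e = radii[:, None] - dist
    i_high = e.argmin(axis=0)
    i_low = e.argmax(axis=0)
    n = np.arange(s.shape[0])
    # de/ds = -(s - c)/|s - c|
    g_high = -diff[i_high, n, :] / dist[i_high, n][:, None]
    g_low = -diff[i_low, n, :] / dist[i_low, n][:, None]
    geom = ExcitationGeometry(r_high=e.min(axis=0), r_low=e.max(axis=0), r=r)
    return geom, g_high, g_low


def clamp_distances(geom: ExcitationGeometry) -> ExcitationGeometry:
    """Clamp both distances into [-r, +r], recording which were clamped.

    Clamping freezes the corresponding gradient: a limiting sphere that
    does not cut the reflection sphere cannot change the partiality by
    an infinitesimal move.
    """
    r = geom.r
    if r <= 0:
        raise ValueError("reflection-sphere radius must be positive")
    rh = np.clip(geom.r_high, -r, r)
    rl = np.clip(geom.r_low, -r, r)
    return ExcitationGeometry(
        r_high=rh,
        r_low=rl,
        r=r,
        clamped_high=rh != geom.r_high,
        clamped_low=rl != geom.r_low,
    )


def cap_fraction(t: np.ndarray, r: float) -> np.ndarray:
    """Fraction of a sphere's volume with signed radial coordinate >= t.

    f(t) = (r - t)^2 (2r + t) / (4 r^3); f(-r) = 1, f(0) = 1/2, f(r) = 0,
    monotonically decreasing on [-r, r].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < -r - 1e-12 * r) or np.any(t > r + 1e-12 * r):
        raise ValueError("cap coordinate outside [-r, +r]")
    return (r - t) ** 2 * (2.0 * r + t) / (4.0 * r**3)


def cap_fraction_derivative(t: np.ndarray, r: float) -> np.ndarray:
    """d/dt of :func:`cap_fraction`: -3 (r^2 - t^2) / (4 r^3); zero at +-r."""
    t = np.asarray(t, dtype=float)
    return -3.0 * (r**2 - t**2) / (4.0 * r**3)


def partiality(geom: ExcitationGeometry) -> np.ndarray:
    """Partiality p = f(r_high) - f(r_low) of a clamped geometry.

    The slab of reciprocal space between the limiting spheres covers the
    radial interval [r_high, r_low] of the reflection sphere, so its
    volume fraction is the difference of the two cap fractions.
    """
    if not geom.clamped:
        geom = clamp_distances(geom)
    p = cap_fraction(geom.r_high, geom.r) - cap_fraction(geom.r_low, geom.r)
    return np.clip(p, 0.0, 1.0)


def lorentz(geom: ExcitationGeometry, k_lorentz: float) -> np.ndarray:
    """Lorentz factor L = k_L / (r_low - r_high), from UNCLAMPED distances.

    The factor undoes the dilution of incident intensity over the
    thicker excited slab at higher scattering angle.  Degenerate slabs
    (r_low == r_high) yield +inf; callers flag those observations.
    """
    thickness = geom.r_low - geom.r_high
    with np.errstate(divide="ignore"):
        return np.where(thickness > 0, k_lorentz / np.where(thickness > 0, thickness, 1.0), np.inf)


def lorentz_normalization(beam: BeamModel, d_angstrom: float) -> float:
    """Slab thickness (r_low - r_high, nm^-1) at resolution d on the nominal sphere.

    Used as the Lorentz constant k_L so that L = 1 for a reflection
    sitting exactly on the nominal Ewald sphere at that resolution
    (conventionally the detector-edge resolution).  Only the
    proportionality L ~ 1/(r_low - r_high) is physical; the constant is
    absorbed by the per-pattern scale factors.
    """
    smod = 10.0 / d_angstrom  # nm^-1
    lam = beam.wavelength_nm
    sz = -0.5 * smod**2 * lam
    sx = np.sqrt(max(smod**2 - sz**2, 0.0))
    geom = excitation_distances(np.array([[sx, 0.0, sz]]), beam, r=1.0)
    return float(geom.r_low[0] - geom.r_high[0])


def partiality_gradients(
    hkl: np.ndarray, basis: np.ndarray, beam: BeamModel, r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Partiality and its gradient w.r.t. the nine basis components.

    Returns ``(p, grad)`` with ``grad`` of shape (N, 9) in the flat
    component order (a*x ... c*z).  By the chain rule

        dp/dv = f'(r_high) d(r_high)/dv - f'(r_low) d(r_low)/dv,

    where a clamped bound contributes zero (f' vanishes at +-r, so the
    gradient is also continuous across the clamping boundary), and
    d(e)/d(a*x) = h * d(e)/d(s_x) etc. — the Miller index multiplying
    the geometric factor is h for a* components, k for b*, l for c*.
    The Lorentz factor is deliberately excluded (dL/dv = 0).
    """
    hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
    s = hkl @ np.asarray(basis).T
    geom, gs_high, gs_low = excitation_distances_and_sgrad(s, beam, r)
    cl = clamp_distances(geom)
    p = partiality(cl)

    dp_drh = cap_fraction_derivative(cl.r_high, r)
    dp_drl = -cap_fraction_derivative(cl.r_low, r)
    dp_drh = np.where(cl.clamped_high, 0.0, dp_drh)
    dp_drl = np.where(cl.clamped_low, 0.0, dp_drl)

    # dp/ds (N, 3), then outer product with (h, k, l)
    dp_ds = dp_drh[:, None] * gs_high + dp_drl[:, None] * gs_low
    grad = (hkl[:, :, None] * dp_ds[:, None, :]).reshape(-1, 9)
    return p, grad
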