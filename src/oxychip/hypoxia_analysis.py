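"""Oxygen read-outs of the tumor model.

Three quantities characterize hypoxia in the device: the radial oxygen
profile across the tumor disc at its mid-plane, the difference between the
profiles with and without the engineered vasculature, and the fractional
approach of the transient to steady state at tracked radial positions
(from which the "hypoxia is established within 30 minutes" claim follows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .device_geometry import DeviceGeometry, RegionGrid
from .rd_solver import OxygenField, TransientResult


@dataclass
class RadialProfile:
    """Mid-plane concentration vs radius, center outward."""

    r: np.ndarray  # m, strictly increasing
    C: np.ndarray  # mol/m^3
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r must be strictly increasing")
        if self.r.shape != self.C.shape:
            raise ValueError("r and C must have matching shapes")


@dataclass
class ApproachCurve:
    """Fractional completion of the transient per tracked radius.

    f[i, k] is the completion fraction at radius positions[i], time t[k]:
    0 at the start, 1 at steady state, clipped to [0, 1.05].
    """

    t: np.ndarray
    positions: np.ndarray  # m
    f: np.ndarray  # shape (len(positions), len(t))


def default_tracked_radii(tumor_radius: float) -> np.ndarray:
    """Radial stations tracked through the transient: 0 .. 0.95 R."""
    return tumor_radius * np.array([0.0, 0.25, 0.5, 0.75, 0.95])


def radial_profile(
    field: OxygenField, geom: DeviceGeometry | None = None, label: str = ""
) -> RadialProfile:
    """Sample C along radius at the tumor mid-plane z = thickness / 2.

    Restricted to the tumor region (center to edge). In axisymmetric mode
    nodes are azimuthal averages by construction; in planar mode the single
    cross-section row is returned.
    """
    grid = field.grid
    geom = geom or grid.geometry
    if geom is None:
        raise ValueError("no geometry associated with this field")
    iz = int(np.argmin(np.abs(grid.z - geom.tumor_thickness / 2.0)))
    mask = grid.r < geom.tumor_radius
    r = grid.r[mask]
    C = field.C[mask, iz]
    if np.any(np.isnan(C)):
        raise ValueError("field/geometry mismatch: solid nodes on the mid-plane")
    return RadialProfile(r=r, C=C, label=label)


def vascular_difference(p_with: RadialProfile, p_without: RadialProfile) -> RadialProfile:
    """Difference profile dC(r) = C_without(r) - C_with(r).

    Positive where removing the vasculature leaves more oxygen (at the
    tumor edge); near zero at the anoxic center.
    """
    if p_with.r.shape != p_without.r.shape or not np.allclose(
        p_with.r, p_without.r, rtol=0, atol=1e-12
    ):
        raise ValueError("profiles are on different radial grids")
    return RadialProfile(
        r=p_with.r.copy(), C=p_without.C - p_with.C, label="without - with"
    )


def approach_fraction(
    series: TransientResult,
    C_ss: OxygenField,
    positions=None,
    geom: DeviceGeometry | None = None,
    denominator_floor: float = 1.0e-3,
) -> ApproachCurve:
    """Fractional completion of the normoxic-to-steady-state transition.

        f(t; r) = (C(r, 0) - C(r, t)) / (C(r, 0) - C_ss(r))

    evaluated at the tumor mid-plane. Positions whose total excursion
    |C(0) - C_ss| falls below ``denominator_floor`` (as a fraction of the
    initial value) are excluded with a warning — the fraction is undefined
    there. Results are clipped to [0, 1.05]. The fraction is invariant to a
    uniform rescaling of concentration units.
    """
    grid = C_ss.grid
    geom = geom or grid.geometry
    if geom is None:
        raise ValueError("no geometry associated with this field")
    if positions is None:
        positions = default_tracked_radii(geom.tumor_radius)
    positions = np.asarray(positions, dtype=float)
    iz = int(np.argmin(np.abs(grid.z - geom.tumor_thickness / 2.0)))
    ir = np.array([int(np.argmin(np.abs(grid.r - p))) for p in positions])

    C0 = series.fields[0].C[ir, iz]
    Css = C_ss.C[ir, iz]
    denom = C0 - Css
    scale = np.maximum(np.abs(C0), np.abs(Css))
    ok = np.abs(denom) > denominator_floor * np.maximum(scale, 1e-300)
    if not np.all(ok):
        excluded = positions[~ok]
        warnings.warn(
            f"approach fraction undefined at r = {excluded} "
            "(steady state equals initial value); excluded",
            RuntimeWarning,
        )
    ir, positions, C0, denom = ir[ok], positions[ok], C0[ok], denom[ok]
    Ct = np.stack([fld.C[ir, iz] for fld in series.fields], axis=1)
    f = (C0[:, None] - Ct) / denom[:, None]
    f = np.clip(f, 0.0, 1.05)
    return ApproachCurve(t=series.times.copy(), positions=positions, f=f)
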