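"""Microdevice geometry and its rasterization to a labeled grid.

The device is a composite of four regions sitting on a glass slide:

* a thin tumor disc (cancer cells in GelMA) trapped under an oxygen-barrier
  pillar whose clearance to the glass sets the disc thickness;
* the culture-media chamber surrounding the pillar, open to the atmosphere
  at its top surface;
* an engineered vessel running around the tumor — a lumen inside a collagen
  block, its wall lined by a thin endothelial layer;
* the impermeable solids (glass, polycarbonate pillar, PDMS walls).

The oxygen PDE is solved on a cell-centered finite-difference grid over this
geometry, by default in axisymmetric (r, z) coordinates with r = 0 at the
tumor center and z = 0 at the glass; a planar cross-section mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import IntEnum

import numpy as np


class Region(IntEnum):
    """Node labels of the rasterized device."""

    BARRIER_SOLID = 0
    TUMOR_GEL = 1
    MEDIA = 2
    COLLAGEN = 3
    LUMEN = 4
    ENDOTHELIUM = 5


class InvalidDimensionError(ValueError):
    """A geometry dimension is missing, non-positive, or inconsistent."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Parametric description of the device. All lengths in meters.

    ``tumor_radius`` and ``tumor_thickness`` follow the 6 mm barrier pillar
    with a 100 um clearance; the vessel is an annular channel of
    ``channel_width`` x ``channel_height`` cross-section whose centerline
    sits ``channel_offset`` outward of the tumor edge, embedded in a collagen
    block padded by ``collagen_padding`` on each side.
    """

    tumor_radius: float = 3.0e-3
    tumor_thickness: float = 100.0e-6
    media_gap_height: float = 1.0e-3
    chamber_radius: float = 6.0e-3
    channel_width: float = 600.0e-6
    channel_height: float = 100.0e-6
    channel_offset: float = 1.0e-3
    has_vascular_channel: bool = True
    endothelium_thickness: float = 10.0e-6
    collagen_padding: float = 100.0e-6

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "has_vascular_channel":
                continue
            if not np.isfinite(v) or v <= 0:
                raise InvalidDimensionError(
                    f"{f.name} must be strictly positive, got {v!r}"
                )
        if self.tumor_radius >= self.chamber_radius:
            raise InvalidDimensionError(
                "tumor_radius must be smaller than chamber_radius "
                f"({self.tumor_radius} >= {self.chamber_radius})"
            )
        if self.tumor_thickness > self.media_gap_height:
            raise InvalidDimensionError(
                "tumor_thickness cannot exceed media_gap_height "
                f"({self.tumor_thickness} > {self.media_gap_height})"
            )
        if self.has_vascular_channel:
            inner = self.channel_center - self.channel_width / 2 - self.collagen_padding
            outer = self.channel_center + self.channel_width / 2 + self.collagen_padding
            if inner <= self.tumor_radius:
                raise InvalidDimensionError(
                    "channel_offset: vascular channel overlaps the tumor disc"
                )
            if outer >= self.chamber_radius:
                raise InvalidDimensionError(
                    "channel_offset: vascular channel extends past chamber_radius"
                )
            if self.channel_height + 2 * self.collagen_padding > self.media_gap_height:
                raise InvalidDimensionError(
                    "channel_height: collagen block taller than media gap"
                )

    @property
    def channel_center(self) -> float:
        """Radial position of the lumen centerline."""
        return self.tumor_radius + self.channel_offset

    def without_channel(self) -> "DeviceGeometry":
        return replace(self, has_vascular_channel=False)


def build_geometry(config: dict | None = None) -> DeviceGeometry:
    """Build a validated :class:`DeviceGeometry` from a parameter table.

    Missing entries fall back to the device defaults (6 mm tumor disc,
    100 um thickness, 600 x 100 um channel). Unknown keys are rejected.
    """
    config = dict(config or {})
    known = {f.name for f in fields(DeviceGeometry)}
    unknown = set(config) - known
    if unknown:
        raise InvalidDimensionError(f"unknown geometry field(s): {sorted(unknown)}")
    return DeviceGeometry(**config)


@dataclass
class RegionGrid:
    """Cell-centered labeled grid over the device.

    ``labels`` has shape (nr, nz); node (i, j) is the half-open cell
    [i*h, (i+1)*h) x [j*h, (j+1)*h) with center (r[i], z[j]). ``mode`` is
    'axisymmetric' (cells are annuli of volume 2*pi*r*h^2) or 'planar'
    (unit-depth cells of volume h^2, mirror symmetry at r = 0).
    ``dirichlet`` marks atmosphere-contact nodes.
    """

    labels: np.ndarray
    spacing: float
    mode: str = "axisymmetric"
    dirichlet: np.ndarray | None = None
    geometry: DeviceGeometry | None = None
    r: np.ndarray = field(init=False)
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in ("axisymmetric", "planar"):
            raise ValueError(f"unknown grid mode {self.mode!r}")
        nr, nz = self.labels.shape
        h = self.spacing
        self.r = (np.arange(nr) + 0.5) * h
        self.z = (np.arange(nz) + 0.5) * h
        if self.dirichlet is None:
            self.dirichlet = np.zeros_like(self.labels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def free(self) -> np.ndarray:
        """Nodes that belong to the PDE domain (not solid)."""
        return self.labels != Region.BARRIER_SOLID

    def node_volumes(self) -> np.ndarray:
        """Volume of each cell (m^3; per unit depth in planar mode)."""
        h = self.spacing
        if self.mode == "axisymmetric":
            return (2.0 * np.pi * self.r * h * h)[:, None] * np.ones(
                (1, self.labels.shape[1])
            )
        return np.full(self.labels.shape, h * h)

    def region_volume(self, label: Region) -> float:
        return float(self.node_volumes()[self.labels == label].sum())


def rasterize(
    geom: DeviceGeometry, spacing: float, mode: str = "axisymmetric"
) -> RegionGrid:
    """Rasterize the device to a labeled grid.

    ``spacing`` must resolve the tumor thickness with at least 4 node layers.
    Deterministic: a given (geometry, spacing, mode) always yields the same
    grid. Labels are assigned by cell-center membership, so region volumes
    converge at first order in ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if spacing > geom.tumor_thickness / 4:
        raise ValueError(
            f"spacing {spacing:g} m too coarse: need >= 4 nodes across the "
            f"tumor thickness (max {geom.tumor_thickness / 4:g} m)"
        )
    nr = int(np.ceil(geom.chamber_radius / spacing))
    nz = int(np.ceil(geom.media_gap_height / spacing))
    labels = np.full((nr, nz), int(Region.MEDIA), dtype=np.int8)
    r = (np.arange(nr) + 0.5) * spacing
    z = (np.arange(nz) + 0.5) * spacing
    R, Z = np.meshgrid(r, z, indexing="ij")

    in_pillar_col = R < geom.tumor_radius
    labels[in_pillar_col & (Z < geom.tumor_thickness)] = int(Region.TUMOR_GEL)
    labels[in_pillar_col & (Z >= geom.tumor_thickness)] = int(Region.BARRIER_SOLID)

    if geom.has_vascular_channel:
        rc = geom.channel_center
        pad = geom.collagen_padding
        col = (np.abs(R - rc) < geom.channel_width / 2 + pad) & (
            Z < geom.channel_height + 2 * pad
        )
        labels[col] = int(Region.COLLAGEN)
        lum = (np.abs(R - rc) < geom.channel_width / 2) & (
            (Z >= pad) & (Z < pad + geom.channel_height)
        )
        labels[lum] = int(Region.LUMEN)
        _shell_to_endothelium(labels)

    # Atmosphere contact: top surface of the media chamber.
    dirichlet = np.zeros_like(labels, dtype=bool)
    dirichlet[:, -1] = labels[:, -1] == int(Region.MEDIA)
    return RegionGrid(
        labels=labels, spacing=spacing, mode=mode, dirichlet=dirichlet, geometry=geom
    )


def _shell_to_endothelium(labels: np.ndarray) -> None:
    """Relabel lumen nodes that touch collagen (4-connectivity) as endothelium."""
    lum = labels == int(Region.LUMEN)
    col = labels == int(Region.COLLAGEN)
    touch = np.zeros_like(lum)
    touch[1:, :] |= col[:-1, :]
    touch[:-1, :] |= col[1:, :]
    touch[:, 1:] |= col[:, :-1]
    touch[:, :-1] |= col[:, 1:]
    labels[lum & touch] = int(Region.ENDOTHELIUM)
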