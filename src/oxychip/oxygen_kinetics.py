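"""Cellular oxygen consumption kinetics.

Consumption follows Michaelis-Menten kinetics gated by a smoothed step-down
below a critical concentration:

    R(C) = Rmax_bulk * C / (C + kMM) * H(C - Ccr)

where H is a continuously differentiable, overshoot-free step (0 below the
critical band, 1 above it). The per-cell-volume maximum rate Rmax_cell is
scaled to a bulk rate by the cell volume fraction, Rmax_bulk =
Rmax_cell * cell_density * cell_volume, so that a 10 million cells/mL
suspension of ~2000 um^3 cells occupies 2% of the gel volume.

Only cell-bearing regions consume: the tumor gel at the full bulk rate and
the endothelial lining at a small fraction of it (endothelial metabolism is
predominantly glycolytic); media, collagen and the cell-free lumen interior
consume nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .device_geometry import Region


@dataclass(frozen=True)
class KineticsParams:
    """All constants of the consumption law and transport. SI units.

    Rmax_cell : mol s^-1 m^-3, maximum consumption rate per cell volume.
    kMM : mol/m^3, oxygen level of half-maximal consumption.
    Ccr : mol/m^3, critical level below which consumption ceases.
    smooth_width : mol/m^3, half-width of the step-smoothing band.
    D : m^2/s, oxygen diffusion coefficient (gas in water).
    C_atm : mol/m^3, dissolved-oxygen level in equilibrium with atmosphere.
    cell_density : cells/m^3; cell_volume : m^3/cell.
    endothelial_rate_fraction : endothelial sink as a fraction of the tumor
        bulk rate, in [0, 1].
    """

    Rmax_cell: float = 0.02
    kMM: float = 0.005
    Ccr: float = 0.0005
    smooth_width: float = 0.0002
    D: float = 3.0e-9
    C_atm: float = 0.2
    cell_density: float = 1.0e13
    cell_volume: float = 2.0e-15
    endothelial_rate_fraction: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "Rmax_cell", "kMM", "Ccr", "smooth_width", "D", "C_atm",
            "cell_density", "cell_volume",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.smooth_width == 0:
            raise ValueError("smooth_width must be positive")
        if not 0 <= self.endothelial_rate_fraction <= 1:
            raise ValueError("endothelial_rate_fraction must be in [0, 1]")
        if not self.Ccr + self.smooth_width < self.kMM < self.C_atm:
            raise ValueError(
                "require Ccr + smooth_width < kMM < C_atm, got "
                f"{self.Ccr} + {self.smooth_width} / {self.kMM} / {self.C_atm}"
            )
        if self.cell_density * self.cell_volume > 1:
            raise ValueError("cell volume fraction exceeds 1")

    @property
    def Rmax_bulk(self) -> float:
        """Maximum bulk consumption rate, mol s^-1 m^-3 of tissue."""
        return self.Rmax_cell * self.cell_density * self.cell_volume


def smoothed_heaviside(x, width: float):
    """Overshoot-free C^1 step: 0 for x <= -width, 1 for x >= width.

    Cubic smoothstep ramp over [-width, width]; value 1/2 at x = 0,
    derivative continuous (and zero) at both band edges, monotone
    non-decreasing, bounded in [0, 1].
    """
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.clip((np.asarray(x, dtype=float) + width) / (2.0 * width), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


_RATE_FRACTION_KEY = {
    int(Region.TUMOR_GEL): "full",
    int(Region.ENDOTHELIUM): "endothelial",
}


def region_rate_fraction(labels, params: KineticsParams) -> np.ndarray:
    """Fraction of Rmax_bulk that applies at each node label."""
    labels = np.asarray(labels)
    frac = np.zeros(labels.shape, dtype=float)
    frac[labels == int(Region.TUMOR_GEL)] = 1.0
    frac[labels == int(Region.ENDOTHELIUM)] = params.endothelial_rate_fraction
    return frac


def consumption_rate(C, params: KineticsParams, region_label=int(Region.TUMOR_GEL)):
    """Volumetric consumption rate R(C), mol s^-1 m^-3.

    ``region_label`` may be a scalar or an array broadcastable to ``C``.
    Bounded by Rmax_bulk, monotone non-decreasing in C, zero at C = 0.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("negative oxygen concentration")
    frac = region_rate_fraction(region_label, params)
    mm = np.divide(C, C + params.kMM, out=np.zeros_like(C), where=(C + params.kMM) > 0)
    return (
        frac
        * params.Rmax_bulk
        * mm
        * smoothed_heaviside(C - params.Ccr, params.smooth_width)
    )


def smoothed_heaviside_derivative(x, width: float):
    """Derivative of :func:`smoothed_heaviside`; continuous, zero outside the band."""
    if width <= 0:
        raise ValueError("width must be positive")
    t = np.clip((np.asarray(x, dtype=float) + width) / (2.0 * width), 0.0, 1.0)
    return 6.0 * t * (1.0 - t) / (2.0 * width)


def consumption_rate_derivative(C, params: KineticsParams, frac=1.0):
    """dR/dC, non-negative everywhere (R is monotone in C); used by Newton."""
    C = np.asarray(C, dtype=float)
    mm = C / (C + params.kMM)
    dmm = params.kMM / (C + params.kMM) ** 2
    H = smoothed_heaviside(C - params.Ccr, params.smooth_width)
    dH = smoothed_heaviside_derivative(C - params.Ccr, params.smooth_width)
    return np.asarray(frac, dtype=float) * params.Rmax_bulk * (dmm * H + mm * dH)


def linearized_rate_coeff(C, params: KineticsParams, frac=1.0):
    """q(C) such that R = q(C) * C; used for monotone Picard linearization."""
    C = np.asarray(C, dtype=float)
    return (
        np.asarray(frac, dtype=float)
        * params.Rmax_bulk
        * smoothed_heaviside(C - params.Ccr, params.smooth_width)
        / (C + params.kMM)
    )
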