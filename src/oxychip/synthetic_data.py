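"""Synthetic inputs with known ground truth.

Three generators emulate the experimental read-outs the image pipeline
consumes, each seed-deterministic and paired with its ground truth:

* lumen masks — a ~600 um wide vessel whose walls carry smooth band-limited
  irregularity, standing in for the wall waviness left by the viscous-
  fingering fabrication of the collagen lumen;
* cell tracks — a mixed population of cells advected with the flow, cells
  arrested on the endothelium (positional jitter only), and cells crawling
  slowly against the flow;
* longitudinal morphometry series — per-day vessel measurements drawn from
  a stable mean or from a mean that decays by a set fraction over the
  observation week, for power-testing the stability ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_quant import LumenMask, VesselMeasurement

#: per-day sample sizes of the week-long vessel observation series
DEFAULT_PER_DAY_N = (12, 14, 15, 15, 9, 9, 6, 6)


@dataclass(frozen=True)
class LumenGenParams:
    """Ground-truth parameters of a synthetic lumen mask."""

    nominal_width: float = 600.0e-6
    length: float = 3.0e-3
    irregularity_amplitude: float = 0.1  # fraction of nominal_width (wall SD)
    irregularity_wavelength: float = 300.0e-6
    pixel_size: float = 1.0e-6
    orientation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.irregularity_amplitude < 0.5:
            raise ValueError("irregularity_amplitude must be in [0, 0.5)")
        if self.irregularity_wavelength <= 0:
            raise ValueError("irregularity_wavelength must be positive")
        for name in ("nominal_width", "length", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TrackGenParams:
    """Ground-truth parameters of a synthetic track table.

    Defaults emulate a small tracked cohort (8 cells: 5 advected with the
    flow, 2 arrested, 1 crawling against the flow).
    """

    n_flowing: int = 5
    n_arrested: int = 2
    n_against_flow: int = 1
    flow_speed: float = 50.0e-6  # m/s
    crawl_speed: float = 0.5e-6  # m/s
    noise_sd: float = 0.3e-6  # m per frame, isotropic
    frame_interval: float = 1.0  # s
    n_frames: int = 60
    seed: int = 0
    flow_axis: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.n_flowing, self.n_arrested, self.n_against_flow) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.n_flowing + self.n_arrested + self.n_against_flow == 0:
            raise ValueError("need at least one cell")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")


def _band_limited_noise(n: int, wavelength_px: float, rng: np.random.Generator):
    """Smooth zero-mean unit-SD 1-D noise with correlation length ~wavelength."""
    raw = rng.standard_normal(n + int(6 * wavelength_px))
    sm = ndimage.gaussian_filter1d(raw, sigma=wavelength_px / (2 * np.pi), mode="wrap")
    sm = sm[: n]
    sd = sm.std()
    return sm / sd if sd > 0 else np.zeros(n)


def gen_lumen_mask(params: LumenGenParams) -> tuple[LumenMask, pd.DataFrame]:
    """Generate a lumen mask plus its ground-truth local widths.

    The two walls are the nominal edges displaced by independent smooth
    noise of SD ``irregularity_amplitude * nominal_width`` (clipped at
    0.45 * width so walls never cross). The ground-truth table records the
    true width at each along-axis position. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    px = params.pixel_size
    w_px = params.nominal_width / px
    len_px = int(round(params.length / px))
    amp_px = params.irregularity_amplitude * w_px
    if len_px < 8:
        raise ValueError("image too small along the vessel axis")

    wav_px = max(params.irregularity_wavelength / px, 2.0)
    eta_u = _band_limited_noise(len_px, wav_px, rng) * amp_px
    eta_l = _band_limited_noise(len_px, wav_px, rng) * amp_px
    clip = 0.45 * w_px
    eta_u, eta_l = np.clip(eta_u, -clip, clip), np.clip(eta_l, -clip, clip)

    theta = np.deg2rad(params.orientation_deg)
    ax = np.array([np.cos(theta), np.sin(theta)])  # (col, row) unit axis
    nrm = np.array([-ax[1], ax[0]])

    half_v = w_px / 2 + amp_px * 3 + 2  # cross-axis half-extent of the band
    n_cols = int(np.ceil(len_px * abs(ax[0]) + 2 * half_v * abs(nrm[0]))) + 8
    n_rows = int(np.ceil(len_px * abs(ax[1]) + 2 * half_v * abs(nrm[1]))) + 8
    if len_px <= w_px:
        raise ValueError("image too small for the nominal width (length <= width)")
    center = np.array([(n_cols - 1) / 2.0, (n_rows - 1) / 2.0])
    origin = center - ax * (len_px / 2.0)  # segment midpoint at image center

    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    u = (cols - origin[0]) * ax[0] + (rows - origin[1]) * ax[1]  # along axis
    v = (cols - origin[0]) * nrm[0] + (rows - origin[1]) * nrm[1]  # across
    ui = np.clip(u, 0, len_px - 1)
    upper = w_px / 2 + np.interp(ui.ravel(), np.arange(len_px), eta_u).reshape(u.shape)
    lower = -w_px / 2 + np.interp(ui.ravel(), np.arange(len_px), eta_l).reshape(u.shape)
    fg = (u >= 0) & (u <= len_px - 1) & (v >= lower) & (v <= upper)

    mask = LumenMask(
        pixels=fg,
        pixel_size=px,
        flow_axis=np.array([ax[1], ax[0]]),  # (row, col) convention
    )
    truth = pd.DataFrame(
        {
            "position_m": np.arange(len_px) * px,
            "true_width_m": (w_px / 2 + eta_u) - (-w_px / 2 + eta_l),
        }
    )
    truth["true_width_m"] *= px
    return mask, truth


def gen_tracks(params: TrackGenParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a track table plus per-cell ground-truth labels.

    Flowing cells advect at ``flow_speed`` along the flow axis, arrested
    cells only jitter, against-flow cells drift at ``-crawl_speed``; all
    motion carries isotropic Gaussian positional noise of ``noise_sd`` per
    frame. Deterministic per seed.
    """
    rng = np.random.default_rng(params.seed)
    axis = np.asarray(params.flow_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.arange(params.n_frames) * params.frame_interval
    rows, labels = [], []
    cid = 0
    for cls, n, v in (
        ("flowing", params.n_flowing, params.flow_speed),
        ("arrested", params.n_arrested, 0.0),
        ("against_flow", params.n_against_flow, -params.crawl_speed),
    ):
        for _ in range(n):
            start = rng.uniform(0, 200e-6, size=2)
            drift = start[None, :] + np.outer(v * t, axis)
            noise = rng.normal(0.0, params.noise_sd, size=(params.n_frames, 2))
            xy = drift + noise
            rows.append(
                pd.DataFrame(
                    {"cell_id": cid, "t": t, "x": xy[:, 0], "y": xy[:, 1]}
                )
            )
            labels.append({"cell_id": cid, "class": cls, "true_speed": abs(v)})
            cid += 1
    return pd.concat(rows, ignore_index=True), pd.DataFrame(labels)


def gen_longitudinal_series(
    stable: bool = True,
    n_days: int = 8,
    per_day_n: tuple[int, ...] = DEFAULT_PER_DAY_N,
    decay_fraction: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
    base_mean: float = 600.0e-6,
) -> list[VesselMeasurement]:
    """Per-day vessel measurements from a stable or decaying mean.

    ``noise_sd`` is a fraction of ``base_mean``. A decaying series ramps the
    mean linearly down to ``(1 - decay_fraction) * base_mean`` on the final
    day. Deterministic per seed.
    """
    if len(per_day_n) != n_days:
        raise ValueError("per_day_n must have one count per day")
    if any(n <= 0 for n in per_day_n):
        raise ValueError("per-day counts must be positive")
    rng = np.random.default_rng(seed)
    out: list[VesselMeasurement] = []
    for day, n in enumerate(per_day_n):
        ramp = 0.0 if stable or n_days == 1 else decay_fraction * day / (n_days - 1)
        mean_d = base_mean * (1.0 - ramp)
        vals = mean_d + rng.normal(0.0, noise_sd * base_mean, size=n)
        for v in vals:
            out.append(
                VesselMeasurement(
                    positions=[0.0], diameters=[v], density=v / base_mean * 0.5,
                    day=day,
                )
            )
    return out
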