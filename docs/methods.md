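# Methods

## The physical model

The device holds a thin disc of cancer cells embedded in GelMA (radius
R = 3 mm, thickness 100 µm) between a glass slide and an impermeable
oxygen-barrier pillar, surrounded by culture media whose top surface is in
equilibrium with the incubator atmosphere. An engineered vessel — a lumen
of ≈600 × 100 µm cross-section formed in collagen and lined by an
endothelial monolayer — runs alongside the tumor disc. Because the pillar
blocks vertical oxygen supply, the disc is fed only radially through its
thin edge, and cellular consumption carves a centripetal gradient with
near-anoxia at the center.

Oxygen transport is passive diffusion with a cellular sink:

    ∂C/∂t = D ∇²C − R(C),
    R(C) = Rmax · C/(C + k_MM) · δ(C − C_cr),

with Michaelis–Menten kinetics and a smoothed step-down δ that switches
consumption off below a critical level C_cr (necrotic cells stop
consuming). δ is implemented as the cubic smoothstep over
[C_cr − w, C_cr + w]: any ramp that is C¹, monotone, overshoot-free and
0/1 outside the band satisfies the contract; only those properties — not
the particular polynomial — matter, and the solver relies on them (C¹ for
the Newton Jacobian, monotonicity for the maximum principle). Consumption
is gated to exactly zero below the band; no basal rate is retained.

Boundary conditions follow the stated device approximation: Dirichlet
C = C_atm = 0.2 mol/m³ on the media surface in contact with the
atmosphere, zero flux everywhere else (glass, polycarbonate pillar,
chamber walls). PDMS is in reality quite oxygen-permeable; modelling it as
impermeable reproduces the device model as characterized, not a refined
one.

## Parameters

| symbol | meaning | default | origin |
|---|---|---|---|
| D | oxygen diffusivity (gas in water) | 3 × 10⁻⁹ m²/s | device characterization |
| C_atm | normoxic dissolved O₂ | 0.2 mol/m³ | device characterization |
| Rmax_cell | max consumption per cell volume | 0.02 mol s⁻¹ m⁻³ | device characterization |
| cell_density | cells per gel volume | 10¹³ m⁻³ (10⁷/mL) | seeding density |
| cell_volume | average cancer-cell volume | 2 × 10⁻¹⁵ m³ | chosen; typical ~2000 µm³ cell |
| k_MM | half-maximal O₂ level | 0.005 mol/m³ | chosen within spheroid-oxygenation literature range |
| C_cr | critical (necrotic) O₂ level | 0.0005 mol/m³ | chosen within literature range |
| smooth_width | half-width of the δ band | 0.0002 mol/m³ | numerical regularization |
| endothelial_rate_fraction | endothelial sink relative to tumor bulk | 0.1 | see below |

The bulk maximum rate is the per-cell-volume rate scaled by the cell
volume fraction: Rmax = Rmax_cell · cell_density · cell_volume
= 4 × 10⁻⁴ mol s⁻¹ m⁻³ at the defaults (2% volume fraction). k_MM and
C_cr are not precisely known for this system; the headline transient
result is therefore verified across a ±2× sweep of both (varied one at a
time) in the test suite.

**Endothelial consumption.** Endothelial metabolism is predominantly
glycolytic, so the endothelium consumes little — but not zero — oxygen.
With a strictly zero endothelial sink the with/without-vasculature fields
are identical (the channel regions would differ from media in label only),
and the characteristic difference profile — slightly less oxygen at the
immediate tumor edge when the vessel is present, centers untouched —
cannot arise. The default therefore assigns the endothelial shell 10% of
the tumor bulk rate; 0 remains available as a sensitivity setting. The
shell is thinner than a grid cell, so the one-voxel endothelium layer
carries its rate scaled by (physical thickness / grid spacing), keeping
the integrated sink independent of resolution.

## Geometry and discretization

The solve domain is 2-D axisymmetric (r, z), r = 0 at the disc center,
z = 0 at the glass: the disc and the centripetal gradient are axisymmetric
to good approximation, and the vessel is represented as an annular ring at
its radial offset. A planar cross-section mode exists for 1-D/2-D slab
verification problems. Chamber radius (6 mm), media gap height (1 mm) and
channel offset (1 mm) are not characterized dimensions; the defaults are
order-of-magnitude consistent with the device photographs and are
config-exposed, as is the atmosphere-surface placement (top of the media
column) whose exact position is likewise uncharacterized.

Rasterization is cell-centered with half-open voxels (no double counting
at interfaces); labeled region volumes converge to the analytic volumes at
first order in spacing (the tumor disc volume is within 0.5% of πR²Δh at
10 µm spacing). Default spacing is 25 µm — 4 node layers across the disc
thickness, a 240 × 40 grid.

The spatial operator is a conservative finite-volume Laplacian: face
fluxes D·A·ΔC/h with the exact 2πr metric in face areas and cell volumes,
no flux across faces to solid nodes. Because the same face flux enters
both adjacent cells, the discrete steady state closes its mass balance
(atmosphere influx = total consumption) to solver precision — the ≤1%
closure check in the tests passes at ~10⁻¹³.

## Solvers

*Transient:* backward Euler, default dt = 1 s, with the sink linearized as
R = q(C̃)·C (q ≥ 0) and resolved by Picard iteration (tolerance
10⁻⁶ mol/m³, cap 50; typically 2–3 iterations). The resulting matrix is an
M-matrix at every iteration, so 0 ≤ C ≤ C_atm holds unconditionally in dt
(discrete maximum principle). Initial condition is uniform C_atm — cells
placed into oxygenated medium at t = 0.

*Steady state:* Newton with the exact Jacobian of the C¹ rate law
(R′ ≥ 0 keeps the Jacobian an M-matrix), a halving line search on the
residual norm, and a short damped-Picard warmup. Pure Picard limit-cycles
near the consumption gate at this problem's parameters; Newton converges
in ~6 iterations to a residual of ~10⁻¹⁵. Verified against the closed-form
parabola for a zeroth-order 1-D slab (< 0.05% at 200 nodes) and against a
fine-step explicit-Euler oracle on small grids (< 10⁻⁴ mol/m³).

*Approach fraction:* the "reaches >90% of steady state in 30 min" read-out
is computed as fractional completion of the transient,
f(t; r) = (C(r,0) − C(r,t)) / (C(r,0) − C_ss(r)), at tumor mid-plane
positions r ∈ {0, R/4, R/2, 3R/4, 0.95R}. The alternative reading (ratio
of current to steady concentration) diverges where C_ss ≈ 0, i.e. at the
very positions of interest, so only the completion reading is
well-defined everywhere. f is clipped to [0, 1.05]; positions whose total
excursion is below a floor are excluded with a warning. The difference
profile sign convention is (without − with), so the vessel's edge effect
appears as a positive peak.

## Image quantification

*Diameter:* the manual rule — wall-to-wall distance perpendicular to the
vessel direction — is automated as: dominant connected component →
morphological skeleton → longest geodesic path through the skeleton graph
(which prunes side spurs and resolves branch points toward the longest
continuation) → local direction by a ±10 px secant → perpendicular chord
through the bilinearly interpolated mask with sub-pixel root refinement.
Path points whose inscribed radius drops below 70% of the path median
(end spurs running toward mask corners) are discarded, then 5% of the
remaining path is trimmed at each end. Exact on axis-aligned rectangles,
rotation- and translation-invariant within 1 px, and recovers the
generator's ground-truth width within 5% in the seed-ensemble mean (wavy
walls bias single realizations by a few percent because a perpendicular
chord through a locally tilted band slightly exceeds the cross-axis
width).

*Density:* vessel density is not a standardized quantity; here it is the
lumen coverage area fraction within a region of interest — the simplest
mask-computable interpretation. This is an interpretation, stated
prominently.

*Longitudinal stability:* per-day mean ± SD and a one-way ANOVA across
days, grouping either one mean per measurement ("device") or all sampled
positions ("pooled"). A series with zero between-day variation returns
p = 1 (scipy's ANOVA is indeterminate at 0/0). The test behaves as a
test: ~5% false-positive rate on stable synthetic series and ~100% power
against a 20% decay over the week at 5% measurement noise.

*Velocimetry:* per cell, mean speed = path length / elapsed time; signed
along-flow velocity = net displacement projected on the flow axis /
elapsed time; arrested if mean speed < 1 µm/s (an order below the flowing
speeds the generator produces — only the flag, not the statistics, depends
on this threshold). Classification calls a cell "against the flow" when
its along-flow velocity is below −0.1 µm/s (an order below the default
crawl speed), "arrested" when slow and not counter-moving, else "flowing".

## Synthetic data

The generators define the study conditions and emit ground truth alongside
every dataset; all are deterministic per seed.

*Lumen masks:* a 600 µm nominal band, 3 mm long at 1 µm/px, each wall
displaced by independent Gaussian-smoothed noise (correlation length
~300 µm, SD = 10% of width, clipped at 0.45·width so walls never cross) —
a geometric emulation of the wall waviness left by viscous-fingering
fabrication, not a physical Saffman–Taylor simulation, since only the
geometric consequence matters downstream. An optional orientation angle
rotates the band analytically for invariance tests.

*Tracks:* 8 cells per cohort (5 flowing at 50 µm/s, 2 arrested, 1 crawling
against flow at 0.5 µm/s — matching the composition of the tracked
intravascular cohort, where a minority of cells arrest and one crawls
upstream), 60 frames at 1 s intervals, isotropic Gaussian positional noise
of 0.3 µm per frame — the simplest motion model sufficient to test
classification and velocimetry.

*Longitudinal series:* per-day cohort sizes (12, 14, 15, 15, 9, 9, 6, 6)
for days 0–7; stable series draw every day from one mean, decaying series
ramp the mean linearly to (1 − decay) by day 7; noise SD 5% of the mean.

What the generators do **not** emulate: photon noise, point-spread blur,
segmentation errors, uneven illumination, out-of-focus wall shadows, cell
divisions or track fragmentation. Passing recovery tests therefore
demonstrates the correctness of the measurement algorithms on clean
segmentations and tracks, not robustness to real microscopy artifacts.

## Problem sizes and numerical choices

Default runs use the 240 × 40 axisymmetric grid (25 µm), dt = 1 s for the
30-minute transient, Picard tolerance 10⁻⁶ mol/m³, steady Newton tolerance
10⁻¹² on the volume-normalized residual. Halving the spacing changes the
steady mid-plane profile by well under 2% of C_atm. Degenerate inputs
(all-solid grids, masks without an elongated component, single-frame
tracks, one-day series) raise typed errors rather than returning
placeholder values.

## Known limitations

- The axisymmetric vessel is an annulus, not a straight channel to one
  side; its oxygen effect is correspondingly azimuthally averaged.
- No convection in the lumen (static culture) and no PDMS permeability.
- The endothelial sink magnitude (10% of tumor bulk) is an assumption;
  only the sign and localization of the vascular difference, not its
  magnitude, should be read from the defaults.
- Diameter measurement assumes a single dominant, roughly tubular lumen;
  branching networks are out of scope.
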