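# Methods

This note documents the models behind each pipeline stage, the defaults
of the synthetic-data generator, and the numerical choices made where the
design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Reporter band model

Thiophenol (benzenethiol) chemisorbs on gold through S–H cleavage,
forming a phenylthiolate self-assembled monolayer. Its vibrational
signature is modelled as eight normal modes with a spontaneous-Raman and
(for seven of them) a SERS position:

| Raman (cm⁻¹) | SERS (cm⁻¹) | assignment |
|---|---|---|
| 920 | — | S–H in-plane bending |
| 1003 | 1002 | ring out-of-plane deformation / C–H out-of-plane bending |
| 1028 | 1027 | ring in-plane deformation / C–C symmetric stretching |
| 1096 | 1078 | C–C anti-symmetric stretching |
| 1122 | 1117 | (unassigned) |
| 1161 | 1159 | C–H in-plane bending |
| 1184 | 1182 | C–H in-plane bending |
| 1587 | 1576 | C–C symmetric stretching |

The 920 cm⁻¹ S–H bend has no SERS counterpart: the bond it involves is
cleaved on binding, so its absence is the spectroscopic signature of
chemisorption and the band-shift table treats absences as data, not
errors. Synthetic bands are unit-height pseudo-Voigt profiles
(η = 0.5 Lorentzian fraction) with a default FWHM of 10 cm⁻¹ — the
lineshape and width are modelling choices, picked narrow because the
reporter's bands are molecularly sharp. One relative amplitude per mode
serves both modes, chosen so the two C–C stretches dominate with
1078 ≥ 1576 > all others (amplitudes 1.00 and 0.95 against 0.12–0.55).
The default wavenumber axis is 600–1800 cm⁻¹ at 2 cm⁻¹ spacing,
exposure 3 s.

## Synthetic micrographs

Particles are dark, anti-aliased disks (5×5 subpixel coverage sampling)
on a bright background: gray levels 40 on 220, additive Gaussian noise
sd 8. Diameters follow a Gaussian with mean 24 nm and sd
FWHM/2.3548 = 4.29 nm (FWHM 10.1 nm), truncated below 8 nm; the optional
low-side shoulder component of real preparations is not modelled. A
deterministic `round(n × rod_fraction)` of the population (default 3%)
is drawn as 2.5:1 ellipses with the same area as the sphere they
replace, so rods do not distort the equivalent-diameter distribution.
Placement is random sequential adsorption with non-touching
circumscribed circles (2 px clearance) fully inside the frame; a bounded
retry budget turns over-packed requests into a named error.

The default frame is 1024×1024 px at 0.5 nm/px (100 particles ≈ 17%
area fraction). The pixel size matters: at 0.5 nm/px a 24 nm particle
spans 48 px and caliper-diameter discretization error is ~1–2%, keeping
rasterized spheres safely above the R ≥ 0.85 classification threshold;
much coarser sampling would push small spheres into the intermediate
class for purely numerical reasons.

## Particle measurement

Binarization uses Otsu's inter-class-variance threshold (the standard
automatic histogram method; the dark class is inclusive of the returned
threshold). Regions are 8-connected; regions under 9 px or touching the
frame border (partial particles) are discarded by default. *d*max in the
roundness formula is the maximum Feret diameter, measured by rotating
calipers on the convex hull of the region's 0.5-level marching-squares
outline — the same outline scikit-image's Feret estimator uses, chosen
over a pixel-corner hull because the latter inflates diameters by about
half a pixel per side. A fitted-ellipse major-axis estimator is
available behind `dmax_estimator="ellipse"`. The minimum Feret diameter
comes from the same hull (minimum caliper width over edge orientations).
Single-pixel regions yield a flagged degenerate record rather than an
exception. An allowance of ε = 0.05 above the analytic bound R ≤ 1
absorbs rasterization overshoot.

The histogram FWHM interpolates the half-maximum crossings linearly
between adjacent bin centers on each side of the modal bin (default
2 nm bins on equivalent diameter); a single occupied bin degenerates to
one bin width, and a half-maximum never crossed on one side is a named
error. Whether the population's "mean diameter" should be the mean
equivalent diameter or the mean Feret diameter is ambiguous in practice;
both are reported and equivalent diameter is primary.

## UV-Vis model and quantification

The synthetic LSPR band is a Gaussian centered at 526 nm (sd 40 nm) with
absorbance = concentration × extinction × band shape; the default
extinction (2400 AU per mol/L of Au, path length folded in) sets
convenient absorbance scales and cancels out of every ratio the module
computes. Concentrations are total gold molarity (complete-reduction
basis), not particle molarity; the two unit systems are never converted
silently. Peak location refines the discrete maximum with a 3-point
parabola. The Beer-Lambert fit is constrained through the origin, with
R² computed against the through-origin model (uncentered total sum of
squares). Ageing stability uses a 10% relative-drop threshold on the
concentration-normalized LSPR height — a configurable convention, since
no quantitative criterion is standard. The aggregation index is
A(650 nm)/A(λ_LSPR): 650 nm sits between the 526 nm monomer band and
typical aggregate bands, so the index is ~0 for a monomeric colloid and
grows monotonically with a synthetic shoulder (Gaussian at 680 nm).

## Enhancement-factor chain

Internal units are cm, g, L and counts/s, converted only at I/O
boundaries. For the nominal colloid (r = 12×10⁻⁷ cm, D_Au = 19.32
g/cm³, ρ = 5.7×10⁻¹⁵ cm² taken as a given constant):
V_NP = 7.24×10⁻¹⁸ cm³, m_NP = 1.40×10⁻¹⁶ g, S_NP = 1.81×10⁻¹¹ cm², and
S_NP/ρ ≈ 3175 molecules per particle (reported rounded; downstream math
uses the exact value). The colloid's gold mass concentration is a
required input — the default 0.294 g/L is back-derived from the nominal
total-surface budget S_T = 3.8×10⁴ cm²/L, which is otherwise not
reproducible. N_REF uses an ideal-mixing solution density for the
10 wt% thiophenol/ethanol reference (1/ρ_mix = w/ρ_TP + (1−w)/ρ_EtOH
with ρ_TP = 1.0766, ρ_EtOH = 0.789 g/mL, M = 110.18 g/mol), giving
4.43×10²³ molecules/L; the mixing rule is an explicit assumption since
the true solution density is not specified. Intensities are
exposure-normalized integrated areas of the matched C–C stretching pair
(1576 cm⁻¹ SERS / 1587 cm⁻¹ Raman).

The generator's default SERS/Raman intensity ratio (22.595) is a
calibration constant: it is the ratio that closes the chain on the
nominal EF of 1.5×10⁶ given this module's default N_REF and N_SERS.
Because both band areas share one lineshape, the pipeline's recovered EF
differs from nominal only through band-extraction asymmetries (window
gridding, baseline endpoints), about 1% in practice.

## Cell maps and the I₁₀₇₈ statistic

A cell map is a 30×30 grid at 2.0 μm steps (cell-sized field of view)
with one spectrum per pixel, 3 s exposure. Pixels inside an elliptical
cell mask (semi-axes 11×8 grid units) receive reporter signal with
per-pixel scale drawn from a load field; outside pixels carry baseline
(constant 50 counts plus a broad 30-count autofluorescence hump at
1350 cm⁻¹, FWHM 500 cm⁻¹) and Gaussian noise (sd 5 counts; optional
Poisson shot noise). `base_load` = 100 counts per unit multiplier puts
the per-pixel SNR at the 1078 band near 20.

Load multipliers encode the uptake kinetics relative to the normal line
at 2 h: PNT2 = 1 at 2, 4 and 6 h (uptake plateaus), PC3 = 3.6 at 2 h
and 10.5 at 6 h — calibrated so the downstream percent-excess statistic
(PC3 − PNT2)/PNT2 × 100 equals 260% and 950% — with the unreported 4 h
value linearly interpolated (7.05). "X% higher" is read as
(A−B)/B × 100 throughout; generator and comparator share the convention,
so the recovery tests are self-consistent. Spatially, PNT2 load is
concentrated in 1–2 compact spots (Gaussian blobs, σ = 0.8 px, truncated
at 5% of peak, ≥ 90% of mask pixels empty) while PC3 load is spread over
every mask pixel (gamma-distributed, shape 4). Cell-to-cell variability
is lognormal with CV 0.15 — deliberately modest biological scatter so
that 30-cell group means resolve the injected contrasts; real uptake
distributions are typically broader, which the recovery tests do not
probe.

I₁₀₇₈ is the baseline-corrected band **height** at 1078 cm⁻¹ of the
cell-body sum-spectrum, divided by exposure; height matches the "peak
intensity" reading of the statistic, and integrated area is available
via `mode="area"`. The local baseline is the straight line through the
±20 cm⁻¹ window endpoints — adequate for a single analytical band, with
no global fluorescence model. Note the area statistic is exactly
additive over pixels (sum of per-pixel band areas equals the area of
the sum-spectrum), whereas height of a sum is not the sum of heights;
the default height mode relies on all pixels sharing the band center.
Negative corrected values (blank cells) are floored at zero and
flagged. The linear-endpoint baseline leaves ~1.5% of the band's own
tails inside the correction, so recovered heights sit slightly below
generator truth — well within the 5% recovery tolerance and common to
both cell lines, hence cancelled in every contrast. Ground-truth masks
come from the generator; with real data the mask would be drawn on a
co-registered visible image (registration itself is out of scope), and a
full-map mask is the default when none is supplied.

Band-shift detection searches ±15 cm⁻¹ around the spontaneous-Raman
position and, on the SERS side, a window spanning both nominal positions
(so an unshifted band is still matched). A peak counts as present when
its corrected height exceeds 3× the robust local noise (1.4826×MAD) and
5% of the spectrum's strongest band — the floor prevents noise-free
traces, whose MAD is nearly zero, from "detecting" far tails of
neighbouring bands.

## Problem sizes and determinism

Every generator is a pure function of its spec and seed. The acceptance
script uses 30 cells per line per time (the study's replicate count),
20 micrographs of 100 particles (~2000 particles), and derives all
per-cell/per-image seeds from the single `--seed` argument; the full run
takes well under a minute on one core. Observed run-to-run spread across
seeds: percent-excess contrasts vary by a few percent relative (n = 30
per group), histogram FWHM by ~±5%, the deterministic chain not at all.

## Known limitations

* The generator is phenomenological: no electromagnetic (Mie/FDTD)
  plasmon simulation, no TEM contrast physics, no DLS/zeta-potential or
  cytotoxicity modelling, and solvent (ethanol) bands are off by default
  with unvalidated positions.
* Touching particles are not split (no watershed); the generator
  guarantees non-overlap, so count recovery on synthetic images says
  nothing about aggregated real samples.
* The SERS band positions follow the reference table (1096→1078,
  1587→1576, i.e. shifts of −18 and −11 cm⁻¹); the module reports
  detected shifts and does not arbitrate alternative shift readings.
* Passing recovery tests demonstrates correctness of the measurement
  chain under the generator's assumptions (shared band centers, modest
  cell-to-cell scatter, ellipse masks), not performance on real cubes
  with drift, cosmic rays or fluorescence backgrounds beyond the smooth
  hump modelled here.
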