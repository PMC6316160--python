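# nanosers

Analysis pipeline for thiophenol-functionalized gold nanospheres used as
SERS (Surface Enhanced Raman Spectroscopy) probes of single-cell
nanoparticle uptake. It is aimed at spectroscopists and bio-imaging
groups who characterize plasmonic colloids and quantify their
internalization in cultured cells — here, discriminating normal (PNT2)
from tumor (PC3) prostatic lines by how much probe each cell takes up.

The package covers four measurement chains, plus a ground-truthed
synthetic-data generator that emulates every input, so the whole pipeline
is testable without instrument data:

* **Particle morphometry** (`nanosers.particles`) — statistical image
  analysis of particle micrographs: automatic (Otsu) binarization,
  8-connected labelling, per-particle descriptors including the roundness

  *R* = 4*A* / (π·*d*²max),

  with *A* the particle area and *d*max the maximum Feret diameter.
  *R* = 1 for a circle and *b*/*a* for an ellipse, so it classifies
  nanospheres (*R* ≥ 0.85) vs nanorods (*R* ≤ 0.6). Population statistics
  include the equivalent-diameter histogram and its FWHM.
* **UV-Vis quantification** (`nanosers.uvvis`) — localized surface
  plasmon resonance (LSPR) peak detection (~526 nm for ~24 nm gold
  spheres), Beer-Lambert calibration constrained through the origin,
  concentration estimation, ageing-stability series and an aggregation
  index A(650 nm)/A(λ_LSPR).
* **Enhancement factor** (`nanosers.ef`) — the geometric SERS
  enhancement-factor chain

  EF = (I_SERS / I_REF) · (N_REF / N_SERS),

  where N_SERS comes from monolayer packing on the total gold surface:
  V_NP = (4/3)πr³, m_NP = V_NP·D_Au, N_NP/L = c/m_NP,
  S_T = 4πr²·N_NP/L, N_SERS/L = S_T/ρ with ρ the equatorial
  cross-section of thiophenol (5.7×10⁻¹⁵ cm²), and N_REF from the
  molarity of a 10 wt% thiophenol/ethanol reference.
* **Hyperspectral maps** (`nanosers.maps`) — single-cell Raman cubes:
  band-intensity images, the cell-body sum-spectrum, and the uptake
  statistic **I₁₀₇₈** (baseline-corrected, exposure-normalized intensity
  of the 1078 cm⁻¹ C–C anti-symmetric stretching band of gold-bound
  thiophenol), with replicate averaging and tumor-vs-normal contrasts.

## Worked example

```python
import dataclasses
import numpy as np
from nanosers import ef, maps, synthetic as syn

result = ef.default_enhancement_factor()
print(f"TP molecules per particle = {result.molecules_per_np}")
print(f"N_SERS = {result.n_sers_per_l:.3g} /L")
print(f"EF     = {result.ef:.3g}")

rng = np.random.default_rng(0)
results = []
for line in ("PNT2", "PC3"):
    for t in (2.0, 6.0):
        for k in range(30):
            spec = dataclasses.replace(syn.MapSpec(), seed=int(rng.integers(0, 2**31)))
            hmap, mask, _ = syn.generate_cell_map(line, t, spec)
            results.append(maps.compute_i1078(hmap, mask, cell_line=line, time_h=t))
summary = maps.summarize_uptake(results)
for (line, t), g in sorted(summary.groups.items()):
    print(f"{line} {t:g} h: I1078 = {g.mean:.0f} +/- {g.sem:.0f} counts/s (n={g.n_cells})")
for t, pe in sorted(summary.percent_excess.items()):
    print(f"PC3 vs PNT2 at {t:g} h: {pe:.0f}% higher")
```

prints

```
TP molecules per particle = 3175
N_SERS = 6.67e+18 /L
EF     = 1.52e+06
PC3 2 h: I1078 = 32937 +/- 904 counts/s (n=30)
PC3 6 h: I1078 = 90796 +/- 2844 counts/s (n=30)
PNT2 2 h: I1078 = 8980 +/- 278 counts/s (n=30)
PNT2 6 h: I1078 = 8983 +/- 203 counts/s (n=30)
PC3 vs PNT2 at 2 h: 267% higher
PC3 vs PNT2 at 6 h: 911% higher
```

Each gold sphere carries ~3175 reporter molecules; the surface enhances
their Raman signal about 1.5 million-fold, which is what makes a single
cell's worth of internalized particles measurable. The uptake experiment
shows the behaviour the probes are designed to detect: the normal line's
I₁₀₇₈ is flat between 2 h and 6 h (uptake stops), while the tumor line's
keeps growing — roughly 260% higher than normal at 2 h and 950% higher
at 6 h under the default generator conditions.

A `nanosers` console script exposes the same stages from the shell
(`nanosers simulate cellmap ...`, `nanosers sia ...`, `nanosers uvvis ...`,
`nanosers ef ...`, `nanosers map-image/uptake/compare ...`); run
`nanosers --help` for the full tree.

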