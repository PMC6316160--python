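"""Geometric SERS enhancement-factor model.

The absolute enhancement factor compares the per-molecule signal of
reporter molecules bound to the gold surface against the same molecules
free in solution:

    EF = (I_SERS / I_REF) x (N_REF / N_SERS)

where the intensities are exposure-normalized integrated band areas of a
matched band pair (1576 cm^-1 in SERS, 1587 cm^-1 in spontaneous Raman)
and the molecule numbers per unit sampling volume come from geometry:

    V_NP = (4/3) pi r^3          single-particle volume
    m_NP = V_NP x D_Au           single-particle mass (D_Au = 19.32 g/cm^3)
    N_NP/L = c_mass / m_NP       particles per litre of colloid
    S_T  = S_NP x N_NP/L         total gold surface per litre, S_NP = 4 pi r^2
    N_SERS/L = S_T / rho         bound monolayer molecules per litre

with rho the equatorial Van der Waals cross-section of thiophenol
(5.7e-15 cm^2, a given constant).  N_REF comes from the molarity of the
reference thiophenol/ethanol solution, using an ideal-mixing density.

Internal unit system: cm, g, L, counts/s.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maps import Spectrum, band_intensity

__all__ = [
    "ReferenceSolution",
    "ColloidModel",
    "SurfaceBudget",
    "EFResult",
    "PhysicalValueError",
    "particle_geometry",
    "particle_mass",
    "surface_budget",
    "reference_number_density",
    "enhancement_factor",
    "evaluate_colloid",
    "ef_from_spectra",
    "default_enhancement_factor",
    "AVOGADRO",
    "GOLD_DENSITY_G_CM3",
    "TP_CROSS_SECTION_CM2",
    "DEFAULT_R_NP_CM",
    "DEFAULT_MASS_CONCENTRATION_G_L",
]

AVOGADRO = 6.02214076e23            # 1/mol
GOLD_DENSITY_G_CM3 = 19.32
TP_CROSS_SECTION_CM2 = 5.7e-15      # thiophenol equatorial cross-section
DEFAULT_R_NP_CM = 12e-7             # 24 nm mean diameter
# Default colloid gold mass concentration; back-derived from the nominal
# total-surface budget of 3.8e4 cm^2/L for 24 nm particles.
DEFAULT_MASS_CONCENTRATION_G_L = 0.294


class PhysicalValueError(ValueError):
    """Raised for non-physical (zero or negative) model inputs."""


@dataclass(frozen=True)
class ReferenceSolution:
    """Thiophenol/ethanol reference: 10 wt% by default."""

    tp_weight_fraction: float = 0.10
    tp_molar_mass: float = 110.18       # g/mol
    tp_density: float = 1.0766          # g/mL
    solvent_density: float = 0.789      # g/mL (ethanol)


@dataclass(frozen=True)
class ColloidModel:
    r_np_cm: float = DEFAULT_R_NP_CM
    gold_density: float = GOLD_DENSITY_G_CM3
    mass_concentration_g_l: float = DEFAULT_MASS_CONCENTRATION_G_L
    cross_section_cm2: float = TP_CROSS_SECTION_CM2
    reference: ReferenceSolution = field(default_factory=ReferenceSolution)

    def validate(self) -> None:
        for name in ("r_np_cm", "gold_density", "mass_concentration_g_l", "cross_section_cm2"):
            if not getattr(self, name) > 0:
                raise PhysicalValueError(f"{name} must be > 0, got {getattr(self, name)}")


def particle_geometry(r_np_cm: float) -> tuple[float, float]:
    """(volume cm^3, surface cm^2) of a sphere; 3V/S == r exactly."""
    if not r_np_cm > 0:
        raise PhysicalValueError(f"radius must be > 0 cm, got {r_np_cm}")
    v = 4.0 / 3.0 * math.pi * r_np_cm**3
    s = 4.0 * math.pi * r_np_cm**2
    return v, s


def particle_mass(v_np_cm3: float, gold_density: float = GOLD_DENSITY_G_CM3) -> float:
    """Single-particle mass in grams: m = V x D."""
    if not (v_np_cm3 > 0 and gold_density > 0):
        raise PhysicalValueError("volume and density must be > 0")
    return v_np_cm3 * gold_density


@dataclass(frozen=True)
class SurfaceBudget:
    n_np_per_l: float            # nanoparticles per litre
    s_t_cm2_per_l: float         # total gold surface per litre
    molecules_per_np: int        # monolayer molecules on one particle (reported)
    molecules_per_np_exact: float
    n_sers_per_l: float          # SERS-active molecules per litre


def surface_budget(
    mass_concentration_g_l: float,
    m_np_g: float,
    s_np_cm2: float,
    cross_section_cm2: float = TP_CROSS_SECTION_CM2,
) -> SurfaceBudget:
    """Partition the colloid's gold mass into particle count, total surface
    and monolayer molecule numbers.

    ``molecules_per_np`` is rounded to the nearest integer for reporting;
    all downstream quantities use the exact value.
    """
    for name, v in (
        ("mass_concentration", mass_concentration_g_l),
        ("m_np", m_np_g),
        ("s_np", s_np_cm2),
        ("cross_section", cross_section_cm2),
    ):
        if not v > 0:
            raise PhysicalValueError(f"{name} must be > 0, got {v}")
    n_np = mass_concentration_g_l / m_np_g
    s_t = s_np_cm2 * n_np
    per_np = s_np_cm2 / cross_section_cm2
    return SurfaceBudget(
        n_np_per_l=n_np,
        s_t_cm2_per_l=s_t,
        molecules_per_np=int(round(per_np)),
        molecules_per_np_exact=per_np,
        n_sers_per_l=s_t / cross_section_cm2,
    )


def reference_number_density(reference: ReferenceSolution = ReferenceSolution()) -> float:
    """Molecules of thiophenol per litre of the reference solution.

    The solution density follows ideal mixing of the two components:
    1/rho_mix = w/rho_TP + (1-w)/rho_solvent; molarity = w rho_mix 1000 / M.
    """
    w = reference.tp_weight_fraction
    if not 0.0 < w < 1.0:
        raise PhysicalValueError(f"weight fraction must be in (0, 1), got {w}")
    rho_mix = 1.0 / (w / reference.tp_density + (1.0 - w) / reference.solvent_density)
    molarity = w * rho_mix * 1000.0 / reference.tp_molar_mass   # mol/L
    return molarity * AVOGADRO


def enhancement_factor(
    i_sers: float, i_ref: float, n_ref_per_l: float, n_sers_per_l: float
) -> float:
    """EF = (I_SERS/I_REF) x (N_REF/N_SERS); intensities exposure-normalized."""
    for name, v in (
        ("i_sers", i_sers),
        ("i_ref", i_ref),
        ("n_ref_per_l", n_ref_per_l),
        ("n_sers_per_l", n_sers_per_l),
    ):
        if not v > 0:
            raise PhysicalValueError(f"{name} must be > 0, got {v}")
    return (i_sers / i_ref) * (n_ref_per_l / n_sers_per_l)


@dataclass(frozen=True)
class EFResult:
    """Every intermediate of the geometric EF chain."""

    v_np_cm3: float
    m_np_g: float
    s_np_cm2: float
    n_np_per_l: float
    s_t_cm2_per_l: float
    molecules_per_np: int
    n_sers_per_l: float
    n_ref_per_l: float
    i_sers: float
    i_ref: float
    ef: float


def evaluate_colloid(model: ColloidModel, i_sers: float, i_ref: float) -> EFResult:
    """Run the full chain from colloid geometry and a band-intensity pair."""
    model.validate()
    v, s = particle_geometry(model.r_np_cm)
    m = particle_mass(v, model.gold_density)
    budget = surface_budget(
        model.mass_concentration_g_l, m, s, model.cross_section_cm2
    )
    n_ref = reference_number_density(model.reference)
    ef = enhancement_factor(i_sers, i_ref, n_ref, budget.n_sers_per_l)
    return EFResult(
        v_np_cm3=v,
        m_np_g=m,
        s_np_cm2=s,
        n_np_per_l=budget.n_np_per_l,
        s_t_cm2_per_l=budget.s_t_cm2_per_l,
        molecules_per_np=budget.molecules_per_np,
        n_sers_per_l=budget.n_sers_per_l,
        n_ref_per_l=n_ref,
        i_sers=i_sers,
        i_ref=i_ref,
        ef=ef,
    )


def ef_from_spectra(
    sers_spectrum: Spectrum,
    raman_spectrum: Spectrum,
    model: ColloidModel | None = None,
    sers_band_cm1: float = 1576.0,
    raman_band_cm1: float = 1587.0,
    half_window: float = 20.0,
) -> EFResult:
    """EF from a colloid SERS spectrum and a reference Raman spectrum.

    Intensities are the exposure-normalized integrated areas of the
    matched C-C stretching band pair (1576 / 1587 cm^-1).
    """
    model = model or ColloidModel()
    i_sers = band_intensity(sers_spectrum, center=sers_band_cm1,
                            half_window=half_window, mode="area")
    i_ref = band_intensity(raman_spectrum, center=raman_band_cm1,
                           half_window=half_window, mode="area")
    return evaluate_colloid(model, i_sers, i_ref)


def default_enhancement_factor(model: ColloidModel | None = None) -> EFResult:
    """EF of the default calibrated pipeline: generate the default noise-free
    paired spectra and push them through the chain."""
    from .synthetic import generate_tp_spectrum

    sers = generate_tp_spectrum("sers", noise_sd=0.0)
    raman = generate_tp_spectrum("raman", noise_sd=0.0)
    return ef_from_spectra(sers, raman, model)
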