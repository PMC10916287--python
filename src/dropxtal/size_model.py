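"""Mass-balance prediction of crystal size from droplet volume.

A droplet of volume ``V`` holding protein at concentration ``c₀`` above the
residual solubility ``c_s`` can deposit a protein mass ``V·(c₀ − c_s)`` into
crystals.  With ``k`` crystals sharing the droplet and a crystal packing
density ``ρ`` (protein mass per crystal volume), each crystal reaches

    crystal_volume = V (c₀ − c_s) / (ρ k)

so the length of a square-prism habit with aspect ratio ``a`` (length:width)
scales as ``V^(1/3)`` at fixed ``k`` — the droplet volume *is* the size dial.
The same balance gives the cube-root seed-dilution law: diluting seeds
``x``-fold leaves ``x`` times more protein per seed, so lengths grow by
``x^(1/3)`` (an upper bound; incomplete depletion in real droplets falls
short of it).

Elongated habits are additionally capped by the droplet diameter
(:func:`axial_ratio_cap`), and reaction-triggering feasibility is governed by
the into-crystal substrate diffusion time (:func:`diffusion_time_into_crystal`),
computed from the Fourier-series solution for a slab with faces held at the
bath concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .units import UM3_PER_PL, s_to_ms, ms_to_s

__all__ = [
    "CrystallizationRecipe",
    "CrystalPrediction",
    "AxialRatioResult",
    "final_concentration",
    "predict_crystal_length",
    "volume_for_length",
    "seed_dilution_length",
    "axial_ratio_cap",
    "diffusion_time_into_crystal",
    "diffusivity_from_time",
    "linear_length_fit",
]


@dataclass(frozen=True)
class CrystallizationRecipe:
    """Batch/droplet crystallization mix and crystal habit parameters.

    Parameters
    ----------
    protein_stock:
        Protein stock concentration, mg ml⁻¹.
    mix_parts_protein, mix_parts_other:
        Volumetric mixing ratio, e.g. one part protein to four parts mother
        liquor is ``(1, 4)``; a seeded 1:1:1 mix is ``(1, 2)``.
    residual_solubility:
        Protein left in solution at equilibrium, mg ml⁻¹.  Default 0
        (high-salt lysozyme condition drives near-complete depletion).
    crystal_packing_density:
        Protein mass per crystal volume ρ, mg ml⁻¹.  Default 800 (typical
        tetragonal lysozyme).  Always configurable — predictions scale with
        ρ^(−1/3).
    habit_aspect:
        Length:width of the square-prism habit, ≥ 1.  Default 2.7.
    """

    protein_stock: float
    mix_parts_protein: float = 1.0
    mix_parts_other: float = 0.0
    residual_solubility: float = 0.0
    crystal_packing_density: float = 800.0
    habit_aspect: float = 2.7

    def __post_init__(self) -> None:
        if self.protein_stock < 0:
            raise ValueError("protein_stock must be >= 0 mg/ml")
        if self.mix_parts_protein <= 0 or self.mix_parts_other < 0:
            raise ValueError("mixing parts must be positive (protein) / >= 0 (other)")
        if self.residual_solubility < 0:
            raise ValueError("residual_solubility must be >= 0 mg/ml")
        if self.crystal_packing_density <= 0:
            raise ValueError("crystal_packing_density must be > 0 mg/ml")
        if self.habit_aspect < 1:
            raise ValueError("habit_aspect must be >= 1 (length:width)")

    @property
    def final_concentration(self) -> float:
        """Protein concentration after mixing, mg ml⁻¹."""
        return final_concentration(self)

    @property
    def supersaturation_excess(self) -> float:
        """Crystallizable concentration c₀ − c_s, mg ml⁻¹ (can be ≤ 0)."""
        return self.final_concentration - self.residual_solubility


def final_concentration(recipe: CrystallizationRecipe) -> float:
    """Post-mix protein concentration: stock × parts/(total parts)."""
    total = recipe.mix_parts_protein + recipe.mix_parts_other
    if total <= 0:
        raise ValueError("total mixing parts must be > 0")
    return recipe.protein_stock * recipe.mix_parts_protein / total


@dataclass(frozen=True)
class CrystalPrediction:
    """Predicted single-crystal dimensions inside one droplet.

    ``crystal_volume`` is in µm³; ``length``/``width`` in µm for a square
    prism with ``length = (volume · a²)^(1/3)`` and ``width = length / a``;
    ``per_crystal_share`` is the number of crystals k sharing the droplet.
    ``no_growth`` flags a recipe at or below the residual solubility.
    """

    crystal_volume: float
    length: float
    width: float
    per_crystal_share: int
    no_growth: bool = False


def predict_crystal_length(
    volume: float,
    recipe: CrystallizationRecipe,
    k: int = 1,
) -> CrystalPrediction:
    """Mass-balance crystal size for a droplet of ``volume`` pl shared by ``k``.

    The available protein mass ``V·(c₀ − c_s)`` is converted to crystal
    volume through the packing density ρ and split equally among ``k``
    crystals.  Concentrations enter only as the dimensionless ratio
    ``(c₀ − c_s)/ρ``, so the droplet volume in pl maps to crystal volume in
    pl, reported in µm³.

    A recipe with ``c₀ ≤ c_s`` yields a zero-size prediction flagged
    ``no_growth`` rather than an error: it is a physically meaningful
    "nothing crystallizes" outcome.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0 pl")
    if k < 1 or int(k) != k:
        raise ValueError("k must be an integer >= 1")
    k = int(k)
    excess = recipe.supersaturation_excess
    if excess <= 0:
        return CrystalPrediction(0.0, 0.0, 0.0, k, no_growth=True)
    crystal_volume_um3 = volume * excess / recipe.crystal_packing_density / k * UM3_PER_PL
    a = recipe.habit_aspect
    length = (crystal_volume_um3 * a * a) ** (1.0 / 3.0)
    return CrystalPrediction(crystal_volume_um3, length, length / a, k)


def volume_for_length(
    target_length: float,
    recipe: CrystallizationRecipe,
    k: int = 1,
) -> float:
    """Droplet volume (pl) needed for a ``target_length`` µm crystal.

    Closed-form inverse of :func:`predict_crystal_length`.
    """
    if target_length <= 0:
        raise ValueError("target_length must be > 0 µm")
    excess = recipe.supersaturation_excess
    if excess <= 0:
        raise ValueError("recipe has no crystallizable excess (c0 <= cs)")
    a = recipe.habit_aspect
    crystal_volume_um3 = target_length**3 / (a * a)
    return crystal_volume_um3 / UM3_PER_PL * recipe.crystal_packing_density * int(k) / excess


def seed_dilution_length(base_length: float, dilution_factor: float) -> float:
    """Crystal length after diluting the seed stock ``dilution_factor``-fold.

    Constant total protein shared among ``1/dilution`` as many seeds gives
    ``L = L₀ · dilution^(1/3)``.  This is an upper bound: observed lengths
    fall short when depletion is incomplete or seed counts scale
    non-linearly with dilution.
    """
    if base_length < 0:
        raise ValueError("base_length must be >= 0 µm")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return base_length * dilution_factor ** (1.0 / 3.0)


@dataclass(frozen=True)
class AxialRatioResult:
    """Confinement-capped crystal length and axial ratio."""

    length: float
    width: float
    axial_ratio: float
    capped: bool


def axial_ratio_cap(
    intrinsic_length: float,
    width: float,
    droplet_diameter: float,
) -> AxialRatioResult:
    """Cap an elongated crystal at the droplet diameter.

    A needle or parallelepiped cannot elongate beyond the droplet it grows
    in, so ``length' = min(intrinsic_length, droplet_diameter)`` and the
    realized axial ratio is ``length'/width``; ``capped`` records whether
    confinement truncated growth.
    """
    if intrinsic_length <= 0 or width <= 0 or droplet_diameter <= 0:
        raise ValueError("lengths and diameter must be > 0 µm")
    length = min(intrinsic_length, droplet_diameter)
    return AxialRatioResult(length, width, length / width, capped=length < intrinsic_length)


def _slab_center_fraction(tau: float, n_terms: int = 200) -> float:
    """Centre concentration (fraction of bath c₀) of a slab at scaled time τ.

    Slab occupies |x| ≤ L with faces held at c₀ and zero initial interior
    concentration; τ = π² D t / (4 L²).  Standard separation-of-variables
    series:

        c(0,t)/c₀ = 1 − (4/π) Σ_m (−1)^m / (2m+1) · exp(−(2m+1)² τ)
    """
    if tau <= 0:
        return 0.0
    m = np.arange(n_terms)
    terms = (-1.0) ** m / (2 * m + 1) * np.exp(-((2 * m + 1) ** 2) * tau)
    return float(1.0 - 4.0 / math.pi * terms.sum())


def diffusion_time_into_crystal(
    travel: float,
    d_eff: float,
    center_fraction: float = 0.5,
) -> float:
    """Time (ms) for substrate to reach the centre of a crystal slab.

    Models the crystal as a slab of half-thickness ``travel`` µm with faces
    held at the bath substrate concentration and an initially substrate-free
    interior, effective diffusivity ``d_eff`` µm² s⁻¹.  Returns the time at
    which the centre concentration first reaches ``center_fraction`` of the
    bath value, from the Fourier-series solution.  ``t ∝ travel²/d_eff``:
    halving crystal size quarters the triggering delay, which is why
    micrometre crystals reach the sub-millisecond mixing regime.
    """
    if travel <= 0:
        raise ValueError("travel must be > 0 µm")
    if d_eff <= 0:
        raise ValueError("d_eff must be > 0 µm²/s")
    if not 0 < center_fraction < 1:
        raise ValueError("center_fraction must be in (0, 1)")
    # Solve for scaled time τ, then unscale: t = 4 L² τ / (π² D).
    f = lambda tau: _slab_center_fraction(tau) - center_fraction
    tau = brentq(f, 1e-12, 50.0, xtol=1e-14, rtol=1e-13)
    t_seconds = 4.0 * travel**2 * tau / (math.pi**2 * d_eff)
    return s_to_ms(t_seconds)


def diffusivity_from_time(
    travel: float,
    time_ms: float,
    center_fraction: float = 0.5,
) -> float:
    """Effective diffusivity (µm² s⁻¹) implied by an observed centre-arrival
    time — the inverse of :func:`diffusion_time_into_crystal` (t ∝ L²/D is
    invertible in closed form once the series gives τ)."""
    if time_ms <= 0:
        raise ValueError("time_ms must be > 0")
    if travel <= 0:
        raise ValueError("travel must be > 0 µm")
    if not 0 < center_fraction < 1:
        raise ValueError("center_fraction must be in (0, 1)")
    f = lambda tau: _slab_center_fraction(tau) - center_fraction
    tau = brentq(f, 1e-12, 50.0, xtol=1e-14, rtol=1e-13)
    return 4.0 * travel**2 * tau / (math.pi**2 * ms_to_s(time_ms))


def linear_length_fit(
    diameters: "np.ndarray | list[float]",
    lengths: "np.ndarray | list[float]",
) -> tuple[float, float]:
    """Least-squares line ``length ≈ slope·diameter + intercept`` (µm, µm).

    Descriptive utility for the observed linear scaling of crystal length
    with droplet diameter under single-seed occupancy; no coefficients are
    assumed or fixed by the package.
    """
    x = np.asarray(diameters, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired (diameter, length) observations")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
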