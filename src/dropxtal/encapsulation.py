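"""Poisson encapsulation statistics and droplet geometry.

Random (stochastic) loading of crystals or seeds into monodisperse droplets
is modelled as a Poisson process: if the suspension carries ``density``
objects per nanolitre and each droplet has volume ``V`` picolitres, the mean
occupancy is ``λ = density · V / 1000`` and the number of objects per droplet
is Poisson(λ).  Droplets are treated as spheres, so a volume maps to the
sphere-equivalent diameter ``d = (6V/π)^(1/3)`` and the surface-area-to-volume
ratio is ``6/d``.  Droplet generation frequency follows from conservation of
the dispersed phase, ``f = Q_aqueous / V``.

Units follow :mod:`dropxtal.units`: volumes pl, diameters µm, densities
nl⁻¹, flows nl s⁻¹, frequencies kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .units import UM3_PER_PL, PL_PER_NL

__all__ = [
    "DropletSpec",
    "OccupancySpec",
    "FlowConditions",
    "LambdaEstimate",
    "diameter_from_volume",
    "volume_from_diameter",
    "surface_to_volume",
    "lambda_from_density",
    "density_from_lambda",
    "poisson_pmf",
    "single_occupancy_fraction",
    "generation_frequency",
    "fit_lambda",
    "occupancy_histogram",
    "fit_density_loss",
]


def diameter_from_volume(volume: float) -> float:
    """Sphere-equivalent diameter (µm) of a droplet of ``volume`` picolitres.

    ``d = (6 V / π)^(1/3)`` with ``V`` expressed in µm³ (1 pl = 1000 µm³).

    Raises
    ------
    ValueError
        If ``volume`` is negative.
    """
    if volume < 0:
        raise ValueError(f"volume must be >= 0 pl, got {volume}")
    return (6.0 * volume * UM3_PER_PL / math.pi) ** (1.0 / 3.0)


def volume_from_diameter(diameter: float) -> float:
    """Volume (pl) of a sphere of ``diameter`` micrometres; inverse of
    :func:`diameter_from_volume`."""
    if diameter < 0:
        raise ValueError(f"diameter must be >= 0 µm, got {diameter}")
    return math.pi * diameter**3 / 6.0 / UM3_PER_PL


def surface_to_volume(diameter: float) -> float:
    """Surface-area-to-volume ratio (µm⁻¹) of a sphere: ``6/d``."""
    if diameter <= 0:
        raise ValueError(f"diameter must be > 0 µm, got {diameter}")
    return 6.0 / diameter


def lambda_from_density(density: float, volume: float) -> float:
    """Mean objects per droplet: ``λ = density [nl⁻¹] × volume [pl] / 1000``."""
    if density < 0:
        raise ValueError(f"density must be >= 0 nl⁻¹, got {density}")
    if volume < 0:
        raise ValueError(f"volume must be >= 0 pl, got {volume}")
    return density * volume / PL_PER_NL


def density_from_lambda(lam: float, volume: float) -> float:
    """Object density (nl⁻¹) implied by mean occupancy ``lam`` in ``volume`` pl."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0 pl, got {volume}")
    return lam * PL_PER_NL / volume


def poisson_pmf(lam: float, k: int) -> float:
    """Poisson probability ``P(K = k) = e^(−λ) λ^k / k!``.

    ``k`` must be a non-negative integer (floats with integral value are
    accepted).
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if isinstance(k, float) and not k.is_integer():
        raise ValueError(f"k must be an integer, got {k}")
    k = int(k)
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return float(stats.poisson.pmf(k, lam))


def single_occupancy_fraction(lam: float) -> float:
    """Fraction of *occupied* droplets holding exactly one object.

    ``P(K = 1 | K ≥ 1) = λ e^(−λ) / (1 − e^(−λ))``, which tends to 1 as
    λ → 0⁺ (the dilute, uniformity-favouring regime) and decreases strictly
    with λ.

    Raises
    ------
    ValueError
        If ``lam <= 0``.  The λ → 0⁺ limit is exactly 1 but λ = 0 itself has
        no occupied droplets, so it is rejected rather than silently mapped
        to the limit.
    """
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    # expm1 keeps the ratio accurate for tiny λ
    return lam * math.exp(-lam) / (-math.expm1(-lam))


def generation_frequency(aqueous_flow: float, volume: float) -> float:
    """Droplet generation frequency (kHz) from aqueous flow and droplet volume.

    ``f = Q / V`` with ``Q`` in nl s⁻¹ and ``V`` in pl gives f in kHz
    directly (nl/pl = 1000, Hz→kHz = 1/1000).
    """
    if aqueous_flow <= 0:
        raise ValueError(f"aqueous_flow must be > 0 nl/s, got {aqueous_flow}")
    if volume <= 0:
        raise ValueError(f"volume must be > 0 pl, got {volume}")
    return aqueous_flow / volume


@dataclass(frozen=True)
class DropletSpec:
    """A monodisperse droplet population.

    Parameters
    ----------
    volume:
        Droplet volume in picolitres.
    size_cv:
        Diameter coefficient of variation (fraction; microfluidic
        generation typically achieves < 0.04).
    generation_frequency:
        Optional production rate in kHz.
    velocity:
        Optional transport velocity in mm s⁻¹.
    """

    volume: float
    size_cv: float = 0.0
    generation_frequency: float | None = None
    velocity: float | None = None

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0 pl")
        if self.size_cv < 0:
            raise ValueError("size_cv must be >= 0")

    @property
    def diameter(self) -> float:
        """Sphere-equivalent diameter in µm."""
        return diameter_from_volume(self.volume)

    @property
    def surface_to_volume(self) -> float:
        """SA:V ratio 6/d in µm⁻¹."""
        return surface_to_volume(self.diameter)

    @classmethod
    def from_diameter(cls, diameter: float, **kwargs) -> "DropletSpec":
        return cls(volume=volume_from_diameter(diameter), **kwargs)


@dataclass(frozen=True)
class FlowConditions:
    """Carrier and dispersed phase flow rates (nl s⁻¹)."""

    aqueous_flow: float
    oil_flow: float

    def __post_init__(self) -> None:
        if self.aqueous_flow < 0 or self.oil_flow < 0:
            raise ValueError("flows must be >= 0 nl/s")

    @property
    def oil_aqueous_ratio(self) -> float:
        if self.aqueous_flow == 0:
            raise ValueError("aqueous flow is zero; ratio undefined")
        return self.oil_flow / self.aqueous_flow


@dataclass(frozen=True)
class LambdaEstimate:
    """Point estimate and confidence interval for mean occupancy λ."""

    lam: float
    ci_low: float
    ci_high: float
    n: int
    confidence: float = 0.95
    method: str = "garwood"

    def __contains__(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _counts_to_observations(
    counts: Mapping[int, int] | Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Expand a ``{k: n_droplets}`` histogram (or accept raw per-droplet
    counts) into a flat array of per-droplet occupancies."""
    if isinstance(counts, Mapping):
        obs: list[int] = []
        for k, n in counts.items():
            if int(n) != n or n < 0:
                raise ValueError("histogram counts must be non-negative integers")
            if int(k) != k or k < 0:
                raise ValueError("occupancies must be non-negative integers")
            obs.extend([int(k)] * int(n))
        return np.asarray(obs, dtype=int)
    arr = np.asarray(counts)
    if arr.ndim != 1:
        raise ValueError("counts must be a 1-D sequence or a histogram mapping")
    if arr.size and (np.any(arr < 0) or np.any(arr != np.floor(arr))):
        raise ValueError("occupancies must be non-negative integers")
    return arr.astype(int)


def fit_lambda(
    counts: Mapping[int, int] | Sequence[int] | np.ndarray,
    confidence: float = 0.95,
    method: str = "garwood",
    n_boot: int = 2000,
    seed: int | None = None,
) -> LambdaEstimate:
    """Estimate mean occupancy λ from per-droplet crystal counts.

    The point estimate is the sample mean (the Poisson maximum-likelihood
    estimator).  The default confidence interval is the exact (Garwood)
    Poisson-mean interval based on the total count ``T``:
    ``[χ²(α/2; 2T)/2, χ²(1−α/2; 2T+2)/2] / n``, which behaves sensibly in
    the small-count regimes (λ ≤ 0.1) this workflow lives in; a percentile
    bootstrap is available with ``method="bootstrap"``.

    Parameters
    ----------
    counts:
        Either a histogram mapping ``{crystals_per_droplet: n_droplets}`` or
        a flat sequence of per-droplet counts.
    """
    obs = _counts_to_observations(counts)
    n = obs.size
    if n == 0:
        raise ValueError("need at least one observed droplet")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    lam_hat = float(obs.mean())
    alpha = 1.0 - confidence
    if method == "garwood":
        total = int(obs.sum())
        lo = 0.0 if total == 0 else float(stats.chi2.ppf(alpha / 2, 2 * total)) / 2 / n
        hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * total + 2)) / 2 / n
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        means = obs[idx].mean(axis=1)
        lo, hi = (float(q) for q in np.quantile(means, [alpha / 2, 1 - alpha / 2]))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return LambdaEstimate(lam_hat, lo, hi, n, confidence, method)


def occupancy_histogram(observations: Sequence[int] | np.ndarray) -> dict[int, int]:
    """Collapse per-droplet counts into a ``{k: n_droplets}`` histogram."""
    obs = _counts_to_observations(observations)
    ks, ns = np.unique(obs, return_counts=True)
    return {int(k): int(n) for k, n in zip(ks, ns)}


@dataclass(frozen=True)
class OccupancySpec:
    """Mean occupancy λ with its underlying object density.

    Either field may be derived from the other given a droplet volume; when
    both are supplied they must be unit-consistent.
    """

    lam: float
    density: float | None = None
    volume: float | None = None
    counts: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.density is not None and self.density < 0:
            raise ValueError("density must be >= 0 nl⁻¹")
        if self.density is not None and self.volume is not None:
            implied = lambda_from_density(self.density, self.volume)
            if not math.isclose(implied, self.lam, rel_tol=1e-6, abs_tol=1e-12):
                raise ValueError(
                    f"inconsistent spec: density×volume gives λ={implied:.6g}, "
                    f"stated λ={self.lam:.6g}"
                )
        if self.counts is not None:
            _counts_to_observations(self.counts)

    @classmethod
    def from_density(cls, density: float, volume: float) -> "OccupancySpec":
        return cls(lam=lambda_from_density(density, volume), density=density, volume=volume)

    def pmf(self, k: int) -> float:
        return poisson_pmf(self.lam, k)

    @property
    def occupied_fraction(self) -> float:
        """P(K ≥ 1) = 1 − e^(−λ)."""
        return float(-math.expm1(-self.lam))

    @property
    def single_occupancy_fraction(self) -> float:
        return single_occupancy_fraction(self.lam)


def fit_density_loss(
    surface_to_volume_ratios: Sequence[float],
    densities: Sequence[float],
) -> tuple[float, float]:
    """Least-squares line ``density ≈ slope·(SA:V) + intercept``.

    Miniaturized droplets show reduced crystal density that correlates with
    their larger surface-area-to-volume ratio.  This is a descriptive fit
    only — correlation with the interfacial area is not a mechanistic claim.

    Returns
    -------
    (slope, intercept):
        slope in crystals nl⁻¹ µm, intercept in crystals nl⁻¹.
    """
    x = np.asarray(surface_to_volume_ratios, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 paired (SA:V, density) observations")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
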