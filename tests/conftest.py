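"""Shared fixtures.

The mixing simulations and the large synthetic-field round trips are the
expensive parts of the suite, and several tests (unit, property and
acceptance) interrogate the same runs, so they are computed once per
session here.
"""

from __future__ import annotations

import numpy as np
import pytest

from dropxtal.droplet_imaging import analyze_field
from dropxtal.mixing import MixingSimConfig, run_mixing_sim
from dropxtal.synthetic_data import (
    CrystalLengthModel,
    ImagingConfig,
    gen_droplet_field,
)

GRID = 64  # cells across the droplet diameter for all shipped sim configs


@pytest.fixture(scope="session")
def mixing_suite():
    """The shipped set of mixing simulations, keyed by scenario.

    * ``phi_0.1 / phi_0.3 / phi_0.5`` — dye volume-fraction sweep at the
      highest transport velocity (300 mm/s, 39 pl droplets).  The φ=0.5 run
      doubles as the homogenization/long-time run (t_max long enough for
      CV to fall under 1e-3) and as the 300 mm/s point of the velocity
      sweep.
    * ``u_60 / u_150`` — velocity sweep points with the correspondingly
      larger droplets produced at lower shear (126 and 93 pl).
    * ``gen_100 / fus_100`` — generation vs fusion initial condition at
      matched volume, velocity and φ (126 pl, 100 mm/s, φ=0.5).
    """
    runs = {}
    runs["phi_0.5"] = run_mixing_sim(
        MixingSimConfig(droplet_volume=39, velocity=300, dye_volume_fraction=0.5,
                        grid_n=GRID, t_max=32.0, n_outputs=300, store_fields=False)
    )
    for phi in (0.1, 0.3):
        runs[f"phi_{phi}"] = run_mixing_sim(
            MixingSimConfig(droplet_volume=39, velocity=300, dye_volume_fraction=phi,
                            grid_n=GRID, t_max=12.0, n_outputs=150, store_fields=False)
        )
    runs["u_60"] = run_mixing_sim(
        MixingSimConfig(droplet_volume=126, velocity=60, grid_n=GRID,
                        t_max=45.0, n_outputs=200, store_fields=False)
    )
    runs["u_150"] = run_mixing_sim(
        MixingSimConfig(droplet_volume=93, velocity=150, grid_n=GRID,
                        t_max=30.0, n_outputs=200, store_fields=False)
    )
    for mode, key in (("generation", "gen_100"), ("fusion", "fus_100")):
        runs[key] = run_mixing_sim(
            MixingSimConfig(droplet_volume=126, velocity=100, init_mode=mode,
                            grid_n=GRID, t_max=45.0, n_outputs=200,
                            store_fields=False)
        )
    return runs


@pytest.fixture(scope="session")
def recovery_fields():
    """Synthetic droplet fields for end-to-end λ / length-CV recovery.

    Conditions: 500 droplets, 12 µm mean diameter at 3 % size CV, Poisson
    occupancy λ=0.1, rod lengths 3 µm ± 15 %, imaged at 0.25 µm/px (an
    oil-immersion-objective sampling).  Seeds fixed at 1, 2, 3.
    """
    out = []
    for seed in (1, 2, 3):
        imaging = ImagingConfig(pixel_size=0.25, image_size=(2048, 2048), seed=seed)
        image, truth = gen_droplet_field(
            n=500, mean_diameter=12.0, size_cv=0.03, lam=0.1,
            length_model=CrystalLengthModel(mean_length=3.0, cv=0.15),
            imaging=imaging,
        )
        droplets, crystals, summary = analyze_field(image, imaging.pixel_size)
        out.append(dict(seed=seed, truth=truth, droplets=droplets,
                        crystals=crystals, summary=summary))
    return out


@pytest.fixture(scope="session")
def small_field():
    """A modest noise-free field reused by several measurement tests."""
    imaging = ImagingConfig(pixel_size=0.5, image_size=(1024, 1024), seed=11)
    image, truth = gen_droplet_field(
        n=100, mean_diameter=12.0, size_cv=0.03, lam=0.15,
        length_model=CrystalLengthModel(mean_length=3.0, cv=0.15),
        imaging=imaging,
    )
    return image, truth, imaging


def diffusion_only_oracle(config: MixingSimConfig, times_ms: np.ndarray) -> np.ndarray:
    """Independent pure-diffusion solver on the same disk geometry.

    Explicit finite differences built from shifted-array sums with
    mask-weighted neighbour openness, run at a 4x finer time step than the
    package solver uses; returns the CV at the requested times.
    """
    n = config.grid_n
    ntot = n + 2
    diam = config.diameter
    h = diam / n
    idx = (np.arange(ntot) - (ntot - 1) / 2.0) * h
    xx, yy = np.meshgrid(idx, idx)
    fluid = xx**2 + yy**2 < (diam / 2.0) ** 2
    # half-disk initial condition (dye on the low-x side)
    c = np.where((xx < 0) & fluid, 1.0, 0.0)
    D = config.diffusivity
    dt = 0.25 * 0.24 * h * h / D
    f = fluid.astype(float)
    out = []
    t = 0.0
    for target_ms in times_ms:
        target = target_ms * 1e-3
        while t < target - 1e-15:
            step = min(dt, target - t)
            # neighbour sums weighted by whether the neighbour is fluid
            flux = np.zeros_like(c)
            for ax, sh in ((0, 1), (0, -1), (1, 1), (1, -1)):
                nb_c = np.roll(c, sh, axis=ax)
                nb_f = np.roll(f, sh, axis=ax)
                flux += nb_f * (nb_c - c)
            c = c + step * D / h**2 * flux * f
            t += step
        vals = c[fluid]
        out.append(vals.std() / vals.mean())
    return np.array(out)
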