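"""Synthetic microscopy with known ground truth.

The analysis modules are validated against images whose every droplet and
crystal is known exactly.  The generator emulates the statistical structure
the measurements assume:

* monodisperse droplet fields — diameters drawn from a normal with a small
  CV (microfluidic generation achieves < 4 %), placed without overlap;
* Poisson crystal occupancy — per-droplet counts ~ Poisson(λ);
* rod-shaped crystals — oriented rectangles (square-prism silhouettes) with
  configurable length distribution, anti-aliased edges, orientation uniform
  on [0°, 180°);
* mixing sequences — a dye concentration field mapped affinely to darkening
  intensity, plus optional Gaussian noise.

It deliberately omits optical realism (no PSF, no depth of field, no
polydispersity failure modes): passing tests demonstrate that the measurement
code recovers known truth, not that it is robust to every imaging artefact.

Images are 16-bit grayscale, single channel; truth tables use 0-based pixel
coordinates, x right / y down.  A single integer seed drives one
`numpy.random.Generator` stream, so identical configs give bit-identical
output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixing import CvTrace, mixing_time

__all__ = [
    "ImagingConfig",
    "CrystalLengthModel",
    "DropletFieldTruth",
    "MixingSequenceTruth",
    "gen_droplet_field",
    "gen_mixing_frames",
    "gen_cv_trace",
]

MAX_U16 = 65535


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters for synthetic micrographs.

    ``pixel_size`` is µm per pixel; intensities are 16-bit counts.  The same
    ``seed`` always reproduces the same image bit for bit.
    """

    pixel_size: float = 0.5
    image_size: tuple[int, int] = (1024, 1024)  # (height, width) px
    background_level: int = 8000
    droplet_interior_level: int = 20000
    rim_level: int = 2000
    crystal_level: int = 6000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 µm/px")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size too small")


@dataclass(frozen=True)
class CrystalLengthModel:
    """Distribution of rendered crystal lengths.

    Lengths are normal(mean_length, cv·mean_length), truncated at
    ``min_length``; widths follow the habit aspect ratio (length:width).
    """

    mean_length: float = 3.0  # µm
    cv: float = 0.15
    aspect: float = 2.7
    min_length: float = 0.5  # µm

    def __post_init__(self) -> None:
        if self.mean_length <= 0 or self.min_length <= 0:
            raise ValueError("lengths must be > 0 µm")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.aspect < 1:
            raise ValueError("aspect must be >= 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        lengths = rng.normal(self.mean_length, self.cv * self.mean_length, size=n)
        return np.maximum(lengths, self.min_length)


@dataclass
class DropletFieldTruth:
    """Ground truth for one synthetic droplet-field image.

    ``droplets``: droplet_id, center_x_px, center_y_px, diameter_um,
    crystal_count.  ``crystals``: droplet_id, crystal_id, center_x_px,
    center_y_px, length_um, width_um, orientation_deg.
    """

    droplets: pd.DataFrame
    crystals: pd.DataFrame
    pixel_size: float

    @property
    def lam_realized(self) -> float:
        """Realized mean crystals per droplet in this field."""
        return float(self.droplets["crystal_count"].mean())

    def occupancy_histogram(self) -> dict[int, int]:
        counts = self.droplets["crystal_count"].value_counts().sort_index()
        return {int(k): int(v) for k, v in counts.items()}


def _rect_coverage(
    xx: np.ndarray,
    yy: np.ndarray,
    cx: float,
    cy: float,
    length_px: float,
    width_px: float,
    orientation_deg: float,
    aa: float = 1.0,
) -> np.ndarray:
    """Anti-aliased coverage (0..1) of an oriented rectangle on a pixel grid."""
    th = math.radians(orientation_deg)
    dx, dy = xx - cx, yy - cy
    # image y axis points down; orientation measured from +x toward +y keeps
    # angles consistent between truth and measurement
    ax = dx * math.cos(th) + dy * math.sin(th)
    ay = -dx * math.sin(th) + dy * math.cos(th)
    d = np.maximum(np.abs(ax) - length_px / 2.0, np.abs(ay) - width_px / 2.0)
    return np.clip(0.5 - d / aa, 0.0, 1.0)


def gen_droplet_field(
    n: int,
    mean_diameter: float,
    size_cv: float,
    lam: float,
    length_model: CrystalLengthModel | None = None,
    imaging: ImagingConfig | None = None,
    rim_width_um: float | None = None,
    max_tries_per_droplet: int = 2000,
) -> tuple[np.ndarray, DropletFieldTruth]:
    """Render a droplet field with Poisson-occupied rod crystals.

    Droplets (bright interior, dark rim) are placed by rejection sampling
    without overlap; per-droplet crystal counts are Poisson(λ); crystals are
    dark rods confined inside their droplet.  Returns the 16-bit image and
    the exact truth table.

    Raises
    ------
    RuntimeError
        If the field is too crowded to place ``n`` droplets within the retry
        budget.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_diameter <= 0:
        raise ValueError("mean_diameter must be > 0 µm")
    if size_cv < 0 or lam < 0:
        raise ValueError("size_cv and lam must be >= 0")
    length_model = length_model or CrystalLengthModel()
    imaging = imaging or ImagingConfig()
    rng = np.random.default_rng(imaging.seed)
    h_px, w_px = imaging.image_size
    px = imaging.pixel_size
    rim_um = rim_width_um if rim_width_um is not None else max(2.0 * px, 0.06 * mean_diameter)

    diameters = rng.normal(mean_diameter, size_cv * mean_diameter, size=n)
    diameters = np.maximum(diameters, 0.2 * mean_diameter)

    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for i in range(n):
        r_px = (diameters[i] / 2.0 + rim_um) / px
        ok = False
        for _ in range(max_tries_per_droplet):
            cx = rng.uniform(r_px + 1, w_px - r_px - 2)
            cy = rng.uniform(r_px + 1, h_px - r_px - 2)
            if all(
                (cx - ox) ** 2 + (cy - oy) ** 2 > (r_px + orr + 2) ** 2
                for (ox, oy), orr in zip(centers, placed_r)
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place droplet {i + 1}/{n} without overlap; "
                "field too crowded (reduce n or droplet size)"
            )
        centers.append((cx, cy))
        placed_r.append(r_px)

    crystal_counts = rng.poisson(lam, size=n)

    img = np.full((h_px, w_px), float(imaging.background_level))
    yy_full, xx_full = np.mgrid[0:h_px, 0:w_px].astype(float)

    crystal_rows: list[dict] = []
    for i, ((cx, cy), diam) in enumerate(zip(centers, diameters)):
        r_in_px = diam / 2.0 / px
        r_out_px = r_in_px + rim_um / px
        lo_y = max(0, int(cy - r_out_px) - 2)
        hi_y = min(h_px, int(cy + r_out_px) + 3)
        lo_x = max(0, int(cx - r_out_px) - 2)
        hi_x = min(w_px, int(cx + r_out_px) + 3)
        yy = yy_full[lo_y:hi_y, lo_x:hi_x]
        xx = xx_full[lo_y:hi_y, lo_x:hi_x]
        rr = np.hypot(xx - cx, yy - cy)
        patch = img[lo_y:hi_y, lo_x:hi_x]
        # dark rim annulus then bright interior, both with ~1 px soft edges
        rim_cov = np.clip(r_out_px + 0.5 - rr, 0, 1) * np.clip(rr - (r_in_px - 0.5), 0, 1)
        patch += (imaging.rim_level - imaging.background_level) * rim_cov
        int_cov = np.clip(r_in_px + 0.5 - rr, 0, 1)
        patch += (imaging.droplet_interior_level - patch) * int_cov

        k = int(crystal_counts[i])
        lengths = length_model.sample(k, rng)
        placed_rods: list[tuple[float, float, float]] = []  # (x, y, half-diag px)
        for j in range(k):
            length_um = float(min(lengths[j], diam))  # confinement cap
            width_um = length_um / length_model.aspect
            orient = float(rng.uniform(0.0, 180.0))
            # keep the rod fully inside the droplet, and avoid touching
            # sibling rods where geometry allows (bounded retries; dense
            # multi-crystal droplets may still overlap, as real ones do)
            margin = min(length_um / 2.0 / px + 1, r_in_px)
            half_diag = math.hypot(length_um, width_um) / 2.0 / px
            kx = ky = cx
            for _ in range(50):
                rho = math.sqrt(rng.uniform()) * max(r_in_px - margin, 0.0)
                ang = rng.uniform(0, 2 * math.pi)
                kx, ky = cx + rho * math.cos(ang), cy + rho * math.sin(ang)
                if all(
                    math.hypot(kx - ox, ky - oy) > half_diag + od + 1
                    for ox, oy, od in placed_rods
                ):
                    break
            placed_rods.append((kx, ky, half_diag))
            cov = _rect_coverage(xx, yy, kx, ky, length_um / px, width_um / px, orient)
            patch += (imaging.crystal_level - patch) * cov
            crystal_rows.append(
                dict(
                    droplet_id=i,
                    crystal_id=len(crystal_rows),
                    center_x_px=kx,
                    center_y_px=ky,
                    length_um=length_um,
                    width_um=width_um,
                    orientation_deg=orient,
                )
            )
        img[lo_y:hi_y, lo_x:hi_x] = patch

    if imaging.noise_sd > 0:
        img = img + rng.normal(0.0, imaging.noise_sd, size=img.shape)
    img16 = np.clip(np.round(img), 0, MAX_U16).astype(np.uint16)

    droplets = pd.DataFrame(
        dict(
            droplet_id=np.arange(n),
            center_x_px=[c[0] for c in centers],
            center_y_px=[c[1] for c in centers],
            diameter_um=diameters,
            crystal_count=crystal_counts,
        )
    )
    crystals = pd.DataFrame(
        crystal_rows,
        columns=[
            "droplet_id",
            "crystal_id",
            "center_x_px",
            "center_y_px",
            "length_um",
            "width_um",
            "orientation_deg",
        ],
    )
    return img16, DropletFieldTruth(droplets, crystals, imaging.pixel_size)


@dataclass
class MixingSequenceTruth:
    """Ground truth for a rendered mixing sequence.

    ``cv`` holds the dye-concentration CV of each noise-free frame;
    ``mixing_time_ms`` is its first interpolated crossing of ``threshold``.
    ``dye_free_level``/``dye_full_level`` give the affine intensity map so
    analyzers can invert intensity back to concentration.
    """

    frame_interval_ms: float
    cv: np.ndarray
    threshold: float
    mixing_time_ms: float
    dye_free_level: float
    dye_full_level: float
    fluid_mask: np.ndarray


def gen_mixing_frames(
    fields: np.ndarray,
    fluid_mask: np.ndarray,
    frame_interval_ms: float,
    imaging: ImagingConfig | None = None,
    threshold: float = 0.05,
    dye_free_level: int | None = None,
    dye_full_level: int | None = None,
) -> tuple[np.ndarray, MixingSequenceTruth]:
    """Render a concentration-field series as a 16-bit image stack.

    Intensity is an affine map of concentration with the dye darkening the
    image: ``I = free − (free − full)·c`` for c ∈ [0, 1].  Pixels outside the
    droplet mask take the background level.  Gaussian noise (``noise_sd``)
    is added on top; the truth CV series is computed on the noise-free
    concentration fields.
    """
    fields = np.asarray(fields, dtype=float)
    if fields.ndim != 3 or fields.shape[0] == 0:
        raise ValueError("fields must be a non-empty (n, H, W) series")
    if frame_interval_ms <= 0:
        raise ValueError("frame_interval_ms must be > 0")
    imaging = imaging or ImagingConfig()
    fluid_mask = np.asarray(fluid_mask, dtype=bool)
    if fluid_mask.shape != fields.shape[1:]:
        raise ValueError("fluid_mask shape must match field frames")
    free = float(dye_free_level if dye_free_level is not None else imaging.droplet_interior_level)
    full = float(dye_full_level if dye_full_level is not None else imaging.crystal_level)
    if not free > full >= 0:
        raise ValueError("need dye_free_level > dye_full_level >= 0 (dye darkens)")

    rng = np.random.default_rng(imaging.seed)
    c = np.where(fluid_mask[None, :, :], np.nan_to_num(fields, nan=0.0), 0.0)
    cmax = float(c.max())
    if cmax > 0:
        c = c / cmax
    stack = np.full(fields.shape, float(imaging.background_level))
    stack[:, fluid_mask] = free - (free - full) * c[:, fluid_mask]
    if imaging.noise_sd > 0:
        stack = stack + rng.normal(0.0, imaging.noise_sd, size=stack.shape)
    stack16 = np.clip(np.round(stack), 0, MAX_U16).astype(np.uint16)

    cvs = np.empty(fields.shape[0])
    for i in range(fields.shape[0]):
        vals = c[i][fluid_mask]
        mean = vals.mean()
        cvs[i] = vals.std() / mean if mean > 0 else 0.0
    times = np.arange(fields.shape[0]) * frame_interval_ms
    trace = CvTrace(times, cvs, threshold=threshold)
    truth = MixingSequenceTruth(
        frame_interval_ms=frame_interval_ms,
        cv=cvs,
        threshold=threshold,
        mixing_time_ms=mixing_time(trace),
        dye_free_level=free,
        dye_full_level=full,
        fluid_mask=fluid_mask,
    )
    return stack16, truth


def gen_cv_trace(
    cv0: float,
    tau: float,
    frame_interval: float,
    n_frames: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    threshold: float = 0.05,
) -> tuple[CvTrace, float]:
    """Exponential-homogenization CV fixture: ``CV(t) = cv0·e^(−t/τ)`` + noise.

    Returns the noisy trace and the analytic crossing time
    ``τ·ln(cv0/threshold)`` (0 if the trace starts at or below threshold) —
    the known truth for analyzer unit tests.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0 ms")
    if cv0 < 0 or noise_sd < 0:
        raise ValueError("cv0 and noise_sd must be >= 0")
    if n_frames < 1 or frame_interval <= 0:
        raise ValueError("need n_frames >= 1 and frame_interval > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) * frame_interval
    cv = cv0 * np.exp(-t / tau)
    if noise_sd > 0:
        cv = np.maximum(cv + rng.normal(0.0, noise_sd, size=n_frames), 0.0)
    true_crossing = 0.0 if cv0 <= threshold else tau * math.log(cv0 / threshold)
    return CvTrace(t, cv, threshold=threshold), true_crossing
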