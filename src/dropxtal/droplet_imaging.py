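"""Droplet and crystal measurement from grayscale micrographs.

Re-implements, as an unsupervised parameter-driven pipeline, the
measurements a supervised image-analysis workflow would deliver: droplet
detection and sizing, in-droplet crystal segmentation and length
measurement, occupancy counting, and population summaries (droplet diameter
mean/CV, crystal length mean/CV, occupancy histogram and λ̂ with its
confidence interval).

Detection strategy (all parameters explicit, deterministic for fixed
inputs): global Otsu threshold → hole filling (crystals are darker than the
droplet interior) → distance-transform watershed to split touching droplets
→ circularity filter.  Crystals are segmented within each droplet mask by
contrast against the interior and measured along their principal axes.
Coordinates are 0-based pixels (x right, y down); all lengths are reported
in µm via the pixel size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from .encapsulation import LambdaEstimate, fit_lambda, occupancy_histogram

__all__ = [
    "DetectionParams",
    "CrystalParams",
    "LabeledDroplet",
    "CrystalMeasurement",
    "PopulationSummary",
    "detect_droplets",
    "measure_crystals",
    "summarize_population",
    "analyze_field",
]


@dataclass(frozen=True)
class DetectionParams:
    """Droplet-detection knobs.

    ``min_circularity`` uses 4πA/P² with the Crofton perimeter;
    ``exclude_edge`` drops droplets touching the image border (their
    diameters would be truncated).
    """

    min_circularity: float = 0.8
    min_diameter_um: float = 2.0
    exclude_edge: bool = True
    watershed_min_distance_px: int = 5


@dataclass(frozen=True)
class CrystalParams:
    """Crystal-segmentation knobs.

    A pixel belongs to a crystal when it is darker than the droplet interior
    median by at least ``min_contrast_frac`` of the interior median (and by
    more than the noise floor).  ``min_area_px`` suppresses speckle.
    """

    min_area_px: int = 4
    min_contrast_frac: float = 0.25
    erode_droplet_px: int = 1


@dataclass(frozen=True)
class LabeledDroplet:
    """One detected droplet: id, centroid (px), diameter (µm) and its mask."""

    droplet_id: int
    center_x_px: float
    center_y_px: float
    diameter_um: float
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray = field(repr=False)  # boolean, bbox-local
    circularity: float = float("nan")

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass(frozen=True)
class CrystalMeasurement:
    """One segmented crystal: principal-axis length/width (µm), orientation."""

    droplet_id: int
    length_um: float
    width_um: float
    orientation_deg: float
    center_x_px: float
    center_y_px: float
    area_px: int


def detect_droplets(
    image: np.ndarray,
    pixel_size: float,
    params: DetectionParams | None = None,
) -> list[LabeledDroplet]:
    """Detect droplets in a single-channel image.

    Returns one :class:`LabeledDroplet` per accepted detection (possibly
    empty — a blank image is not an error).  Deterministic for fixed inputs.
    """
    params = params or DetectionParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be single-channel (2-D)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0 µm/px")
    if img.max() == img.min():
        return []
    thr = threshold_otsu(img)
    fg = img > thr
    fg = ndi.binary_fill_holes(fg)
    min_area = math.pi * (params.min_diameter_um / pixel_size / 2.0) ** 2
    fg = _remove_small(fg, max(4, int(0.25 * min_area)))
    if not fg.any():
        return []

    # split touching droplets on the distance transform
    dist = ndi.distance_transform_edt(fg)
    min_dist = max(params.watershed_min_distance_px,
                   int(0.25 * params.min_diameter_um / pixel_size))
    peaks = peak_local_max(dist, min_distance=min_dist, labels=fg,
                           exclude_border=False)
    markers = np.zeros(fg.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = label(fg)
    else:
        labels = watershed(-dist, markers, mask=fg)

    droplets: list[LabeledDroplet] = []
    h, w = img.shape
    for region in regionprops(labels):
        if region.area < min_area:
            continue
        perim = region.perimeter_crofton
        circ = 4.0 * math.pi * region.area / perim**2 if perim > 0 else 0.0
        if circ < params.min_circularity:
            continue
        r0, c0, r1, c1 = region.bbox
        if params.exclude_edge and (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
            continue
        cy, cx = region.centroid
        diam_um = region.equivalent_diameter_area * pixel_size
        droplets.append(
            LabeledDroplet(
                droplet_id=len(droplets),
                center_x_px=float(cx),
                center_y_px=float(cy),
                diameter_um=float(diam_um),
                bbox=region.bbox,
                mask=region.image.copy(),
                circularity=float(circ),
            )
        )
    return droplets


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    lbl, n = ndi.label(mask)
    if n == 0:
        return mask
    sizes = ndi.sum_labels(mask, lbl, index=np.arange(1, n + 1))
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes >= min_area
    return keep[lbl]


def _principal_axis_extents(coords: np.ndarray) -> tuple[float, float, float]:
    """Length/width of a pixel blob along its principal axes, plus the
    orientation (deg, from +x toward +y i.e. clockwise on screen).

    Extents are pixel-centre spans: with soft (anti-aliased) object edges a
    mid-contrast threshold lands on the physical boundary, so the span of
    included pixel centres approximates the true extent directly.
    """
    ys, xs = coords[:, 0].astype(float), coords[:, 1].astype(float)
    xs_c, ys_c = xs - xs.mean(), ys - ys.mean()
    cov = np.cov(np.vstack([xs_c, ys_c])) if xs.size > 1 else np.eye(2)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    theta = math.atan2(major[1], major[0]) % math.pi
    along = xs_c * math.cos(theta) + ys_c * math.sin(theta)
    across = -xs_c * math.sin(theta) + ys_c * math.cos(theta)
    length = max(float(along.max() - along.min()), 1.0)
    width = max(float(across.max() - across.min()), 1.0)
    if width > length:
        length, width = width, length
        theta = (theta + math.pi / 2.0) % math.pi
    return length, width, math.degrees(theta)


def measure_crystals(
    image: np.ndarray,
    droplet: LabeledDroplet,
    pixel_size: float,
    params: CrystalParams | None = None,
) -> list[CrystalMeasurement]:
    """Segment and measure crystals inside one droplet mask.

    Crystals appear dark against the bright droplet interior; each connected
    dark region of at least ``min_area_px`` pixels is measured along its
    principal axes (length = major extent, width = minor extent).  Objects
    outside the droplet mask are ignored by construction.
    """
    params = params or CrystalParams()
    img = np.asarray(image, dtype=float)
    r0, c0, r1, c1 = droplet.bbox
    patch = img[r0:r1, c0:c1]
    mask = droplet.mask
    if params.erode_droplet_px > 0:
        mask = ndi.binary_erosion(mask, iterations=params.erode_droplet_px)
    vals = patch[mask]
    if vals.size == 0:
        return []
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med))) * 1.4826
    cut = med - max(params.min_contrast_frac * med, 4.0 * mad)
    dark = (patch < cut) & mask
    dark = _remove_small(dark, params.min_area_px)
    lbl, nlab = ndi.label(dark)
    out: list[CrystalMeasurement] = []
    for i in range(1, nlab + 1):
        coords = np.argwhere(lbl == i)
        length_px, width_px, orient = _principal_axis_extents(coords)
        cy, cx = coords.mean(axis=0)
        out.append(
            CrystalMeasurement(
                droplet_id=droplet.droplet_id,
                length_um=length_px * pixel_size,
                width_um=width_px * pixel_size,
                orientation_deg=orient,
                center_x_px=float(cx + c0),
                center_y_px=float(cy + r0),
                area_px=int(coords.shape[0]),
            )
        )
    return out


@dataclass(frozen=True)
class PopulationSummary:
    """Population-level measurement summary.

    ``length_cv`` is ``None`` (explicitly undefined, not 0) when fewer than
    two crystals were measured.
    """

    n_droplets: int
    droplet_mean_diameter_um: float
    droplet_diameter_cv: float | None
    occupancy: dict[int, int]
    lam: LambdaEstimate
    n_crystals: int
    crystal_mean_length_um: float | None
    crystal_length_cv: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    n_droplets=self.n_droplets,
                    droplet_mean_diameter_um=self.droplet_mean_diameter_um,
                    droplet_diameter_cv=self.droplet_diameter_cv,
                    lam_hat=self.lam.lam,
                    lam_ci_low=self.lam.ci_low,
                    lam_ci_high=self.lam.ci_high,
                    n_crystals=self.n_crystals,
                    crystal_mean_length_um=self.crystal_mean_length_um,
                    crystal_length_cv=self.crystal_length_cv,
                )
            ]
        )


def summarize_population(
    droplets: list[LabeledDroplet],
    crystals: list[CrystalMeasurement],
) -> PopulationSummary:
    """Aggregate detections into the population summary.

    λ̂ delegates to :func:`dropxtal.encapsulation.fit_lambda` on the
    occupancy histogram; CVs are sample SD / mean.
    """
    if not droplets:
        raise ValueError("need at least one droplet")
    diam = np.array([d.diameter_um for d in droplets])
    per_droplet = {d.droplet_id: 0 for d in droplets}
    for c in crystals:
        if c.droplet_id not in per_droplet:
            raise ValueError(f"crystal references unknown droplet {c.droplet_id}")
        per_droplet[c.droplet_id] += 1
    occ_obs = np.array(list(per_droplet.values()))
    lam = fit_lambda(occ_obs)
    lengths = np.array([c.length_um for c in crystals])
    mean_len = float(lengths.mean()) if lengths.size else None
    len_cv = (
        float(lengths.std(ddof=1) / lengths.mean()) if lengths.size >= 2 else None
    )
    diam_cv = float(diam.std(ddof=1) / diam.mean()) if diam.size >= 2 else None
    return PopulationSummary(
        n_droplets=len(droplets),
        droplet_mean_diameter_um=float(diam.mean()),
        droplet_diameter_cv=diam_cv,
        occupancy=occupancy_histogram(occ_obs),
        lam=lam,
        n_crystals=int(lengths.size),
        crystal_mean_length_um=mean_len,
        crystal_length_cv=len_cv,
    )


def analyze_field(
    image: np.ndarray,
    pixel_size: float,
    detection: DetectionParams | None = None,
    crystal: CrystalParams | None = None,
) -> tuple[list[LabeledDroplet], list[CrystalMeasurement], PopulationSummary]:
    """Full measurement chain: detect droplets, measure crystals, summarize."""
    droplets = detect_droplets(image, pixel_size, detection)
    if not droplets:
        raise ValueError("no droplets detected")
    crystals: list[CrystalMeasurement] = []
    for d in droplets:
        crystals.extend(measure_crystals(image, d, pixel_size, crystal))
    return droplets, crystals, summarize_population(droplets, crystals)
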