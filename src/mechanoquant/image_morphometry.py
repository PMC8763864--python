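"""Morphometry of fluorescence images: blob segmentation, cell-level
intensity statistics, fiber-orientation coherency, Pearson colocalization,
line scans and the bead-count inclusion filter.

Blob segmentation follows a deliberately simple, fully deterministic
pipeline (large-scale Gaussian background subtraction, Otsu or fixed
threshold restricted to the cell mask, 8-connected labelling, physical
area filter) so that counts and areas are reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "BlobStats",
    "CoherencyResult",
    "ColocResult",
    "SegmentationParams",
    "segment_blobs",
    "cell_area",
    "mean_cell_fluorescence",
    "coherency",
    "pearson_coloc",
    "line_scan",
    "bead_filter",
]


@dataclass
class SegmentationParams:
    """Knobs of the blob-segmentation pipeline.

    ``background_sigma`` (px) sets the scale of the Gaussian background
    estimate that is subtracted before thresholding; ``threshold`` is
    either ``"otsu"`` or a fixed intensity; the area limits are in um^2
    (defaults suit focal adhesions).
    """

    background_sigma: float = 20.0
    threshold: str | float = "otsu"
    min_area_um2: float = 0.25
    max_area_um2: float = 20.0


@dataclass
class BlobStats:
    count: int
    areas_um2: np.ndarray
    mean_area_um2: float
    label_image: np.ndarray
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        self.areas_um2 = np.asarray(self.areas_um2, float)
        if self.count != self.areas_um2.size:
            raise ValueError("count must equal the number of object areas")


@dataclass
class CoherencyResult:
    coherency: float
    sigma_px: float
    rho_px: float
    n_mask_pixels: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.coherency <= 1 + 1e-12):
            raise ValueError("coherency must be in [0, 1]")
        self.coherency = float(np.clip(self.coherency, 0.0, 1.0))


@dataclass
class ColocResult:
    pearson_r: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.pearson_r <= 1 + 1e-12):
            raise ValueError("Pearson r must be in [-1, 1]")
        self.pearson_r = float(np.clip(self.pearson_r, -1.0, 1.0))


def segment_blobs(image: np.ndarray, cell_mask: np.ndarray,
                  pixel_size_um: float,
                  params: SegmentationParams | None = None) -> BlobStats:
    """Segment bright blob-like objects inside a cell mask.

    Pipeline: subtract a Gaussian background estimate at
    ``params.background_sigma``; threshold the residual within the mask
    (Otsu by default); label 8-connected components; keep objects whose
    physical area lies in ``[min_area_um2, max_area_um2]``.  Zero objects
    is a valid result, not an error.
    """
    params = params or SegmentationParams()
    image = np.asarray(image, float)
    mask = np.asarray(cell_mask) > 0
    if image.shape != mask.shape:
        raise ValueError("image and cell mask must have the same shape")
    if not mask.any():
        raise ValueError("empty cell mask")
    if params.min_area_um2 >= params.max_area_um2:
        raise ValueError("min area must be below max area")

    bg = ndimage.gaussian_filter(image, params.background_sigma)
    resid = image - bg
    vals = resid[mask]
    if params.threshold == "otsu":
        if np.ptp(vals) == 0:
            thresh = np.inf            # featureless: no objects
        else:
            thresh = threshold_otsu(vals)
    else:
        thresh = float(params.threshold)
    binary = (resid > thresh) & mask
    lab = label(binary, connectivity=2)
    px_area = pixel_size_um**2
    keep = np.zeros(lab.max() + 1, bool)
    areas = []
    for region in regionprops(lab):
        a = region.area * px_area
        if params.min_area_um2 <= a <= params.max_area_um2:
            keep[region.label] = True
            areas.append(a)
    lab_filtered = np.where(keep[lab], lab, 0)
    areas = np.asarray(areas, float)
    return BlobStats(count=int(areas.size), areas_um2=areas,
                     mean_area_um2=float(areas.mean()) if areas.size else 0.0,
                     label_image=lab_filtered, params=params)


def cell_area(mask: np.ndarray, pixel_size_um: float) -> float:
    """Mask area in um^2: pixel count times squared pixel size."""
    m = np.asarray(mask) > 0
    if not m.any():
        import warnings
        warnings.warn("empty mask: cell area is 0", stacklevel=2)
        return 0.0
    return float(m.sum()) * pixel_size_um**2


def mean_cell_fluorescence(image: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean intensity over masked pixels."""
    image = np.asarray(image, float)
    m = np.asarray(mask) > 0
    if image.shape != m.shape:
        raise ValueError("image and mask must have the same shape")
    if not m.any():
        raise ValueError("empty mask: mean fluorescence undefined")
    return float(image[m].mean())


def coherency(image: np.ndarray, mask: np.ndarray | None = None,
              sigma: float = 1.0, rho: float = 4.0) -> CoherencyResult:
    """Orientation coherency of a fiber texture from the structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma``; their outer
    products are smoothed at the integration scale ``rho`` and averaged
    over the mask to a single 2x2 tensor J.  Coherency is
    ``(l1 - l2) / (l1 + l2)`` of its eigenvalues: 1 for perfectly aligned
    fibers, 0 for an isotropic texture, and 0 by convention for a constant
    image (degenerate tensor).
    """
    if sigma <= 0 or rho <= 0:
        raise ValueError("sigma and rho must be > 0")
    image = np.asarray(image, float)
    if mask is None:
        mask = np.ones(image.shape, bool)
    m = np.asarray(mask) > 0
    min_pixels = int((2 * rho + 1) ** 2)
    if m.sum() < min_pixels:
        raise ValueError(
            f"mask ({int(m.sum())} px) smaller than the {min_pixels}-px "
            f"integration window at rho = {rho}")
    gx = ndimage.gaussian_filter(image, sigma, order=(0, 1))
    gy = ndimage.gaussian_filter(image, sigma, order=(1, 0))
    jxx = ndimage.gaussian_filter(gx * gx, rho)
    jxy = ndimage.gaussian_filter(gx * gy, rho)
    jyy = ndimage.gaussian_filter(gy * gy, rho)
    a, b, c = jxx[m].mean(), jxy[m].mean(), jyy[m].mean()
    trace = a + c
    if trace <= 0:
        return CoherencyResult(0.0, sigma, rho, int(m.sum()))
    diff = np.sqrt((a - c) ** 2 + 4 * b**2)       # l1 - l2 of a 2x2 symmetric
    return CoherencyResult(float(diff / trace), sigma, rho, int(m.sum()))


def pearson_coloc(channel1: np.ndarray, channel2: np.ndarray,
                  mask: np.ndarray | None = None,
                  exclusion_mask: np.ndarray | None = None) -> ColocResult:
    """Pearson correlation of two channels over masked pixels.

    ``exclusion_mask`` removes pixels (e.g. bright magnetic beads) from the
    computation.  Zero variance in either channel is an explicit error:
    the coefficient is undefined there, and silently returning NaN would
    poison downstream group statistics.
    """
    c1 = np.asarray(channel1, float)
    c2 = np.asarray(channel2, float)
    if c1.shape != c2.shape:
        raise ValueError("channels must have the same shape")
    m = np.ones(c1.shape, bool) if mask is None else np.asarray(mask) > 0
    if exclusion_mask is not None:
        m = m & ~(np.asarray(exclusion_mask) > 0)
    if m.sum() < 2:
        raise ValueError("need at least 2 masked pixels")
    x, y = c1[m], c2[m]
    x = x - x.mean()
    y = y - y.mean()
    vx, vy = float(x @ x), float(y @ y)
    if vx == 0 or vy == 0:
        raise ValueError("zero variance within mask: Pearson r undefined")
    return ColocResult(pearson_r=float((x @ y) / np.sqrt(vx * vy)),
                       n_pixels=int(m.sum()))


def line_scan(images, p0, p1, width: int = 1) -> np.ndarray:
    """Intensity profile along a segment, averaged across a perpendicular
    band of ``width`` pixels.

    ``images`` may be one 2-D image or a sequence/stack of channels.
    Samples are taken at 1-px steps from ``p0`` to ``p1`` (x, y pixel
    coordinates) with bilinear interpolation.  Returns ``(n_channels,
    n_steps)`` (squeezed to 1-D for a single channel).
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("zero-length line")
    stack = np.asarray(images, float)
    if stack.ndim == 2:
        stack = stack[None]
    h, w = stack.shape[1:]
    for p in (p0, p1):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise ValueError(f"endpoint {tuple(p)} outside image")
    n_steps = int(np.floor(length)) + 1
    ts = np.linspace(0, 1, n_steps)
    direction = (p1 - p0) / length
    normal = np.array([-direction[1], direction[0]])
    offsets = np.arange(width) - (width - 1) / 2
    profiles = np.zeros((stack.shape[0], n_steps))
    for off in offsets:
        pts = p0 + ts[:, None] * (p1 - p0) + off * normal
        coords = np.vstack([pts[:, 1], pts[:, 0]])   # (row, col)
        for c in range(stack.shape[0]):
            profiles[c] += ndimage.map_coordinates(stack[c], coords, order=1,
                                                   mode="nearest")
    profiles /= width
    return profiles[0] if profiles.shape[0] == 1 else profiles


def bead_filter(bead_counts, min_beads: int = 1, max_beads: int = 4) -> np.ndarray:
    """Inclusion flags for mechanically stimulated cells.

    A cell enters the analysis only if its bound-bead count is between
    ``min_beads`` and ``max_beads`` inclusive (default 1-4).
    """
    counts = np.asarray(bead_counts)
    if counts.size and (np.any(counts < 0)
                        or not np.issubdtype(counts.dtype, np.integer)):
        counts = counts.astype(float)
        if np.any(counts < 0) or np.any(counts != np.round(counts)):
            raise ValueError("bead counts must be non-negative integers")
        counts = counts.astype(int)
    return (counts >= min_beads) & (counts <= max_beads)
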