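"""Seeded synthetic data with ground truth for every analysis stage.

Each generator draws all randomness from a single ``numpy`` Generator seeded
per call, renders the physical forward model of the corresponding analysis
(Gaussian point-spread pillars with drift, Hertzian approach curves in raw
photodiode units, elliptical fluorescent blobs, oriented fiber textures,
two-factor group tables, qPCR Ct tables) and returns the data together with
a truth record that can be serialised to a JSON sidecar and round-tripped.

The scenes are deliberately idealised: additive Gaussian noise in camera
units or force units, no Poisson shot noise, no optical aberrations.  That
is sufficient to exercise and bound the estimators; see the methods note
for what these scenes do and do not establish about real microscopy data.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .afm_indentation import ForceCurve, hertz_force

__all__ = [
    "PillarSceneTruth",
    "CurveTruth",
    "BlobSceneTruth",
    "make_pillar_scene",
    "gen_pillar_timelapse",
    "gen_force_curve",
    "gen_hard_surface_curve",
    "make_blob_scene",
    "gen_blob_image",
    "gen_fiber_image",
    "gen_group_table",
    "gen_ct_table",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# serialisation helpers
# --------------------------------------------------------------------------

def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


class _TruthRecord:
    """Mixin: dataclass truth record with a versioned JSON sidecar."""

    _array_fields: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = {"schema_version": SCHEMA_VERSION,
             "truth_type": type(self).__name__}
        d.update(_to_jsonable(dataclasses.asdict(self)))
        return d

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict):
        d = dict(d)
        d.pop("schema_version", None)
        d.pop("truth_type", None)
        for name in cls._array_fields:
            if d.get(name) is not None:
                d[name] = np.asarray(d[name])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | os.PathLike):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def equals(self, other) -> bool:
        if type(self) is not type(other):
            return False
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
                if not np.allclose(np.asarray(a, float), np.asarray(b, float),
                                   rtol=0, atol=0, equal_nan=True):
                    return False
            elif a != b:
                return False
        return True


# --------------------------------------------------------------------------
# micropillar time-lapses
# --------------------------------------------------------------------------

@dataclass
class PillarSceneTruth(_TruthRecord):
    """Ground truth for one simulated pillar time-lapse.

    Positions are (x, y) pixels, origin at the top-left pixel centre,
    x rightward and y downward.  ``displacements`` holds the true
    cell-generated deflection of every pillar in every frame (zero for
    reference pillars); ``drift`` is the rigid stage translation added on
    top, zero at frame 0.
    """

    lattice_origin: np.ndarray          # (2,) px
    lattice_vectors: np.ndarray         # (2, 2) px, rows are basis vectors
    rest_positions: np.ndarray          # (n_pillars, 2) px
    displacements: np.ndarray           # (n_frames, n_pillars, 2) px
    drift: np.ndarray                   # (n_frames, 2) px
    reference_flags: np.ndarray         # (n_pillars,) bool
    psf_sigma: float                    # px
    peak_intensity: float               # ADU above background
    background: float                   # ADU
    noise_sd: float                     # ADU
    pixel_size_um: float                # um / px
    n_frames: int
    seed: int
    frame_interval_s: float = 2.0       # 0.5 Hz cadence
    shape: tuple[int, int] = (0, 0)     # (rows, cols) of rendered frames

    _array_fields = ("lattice_origin", "lattice_vectors", "rest_positions",
                     "displacements", "drift", "reference_flags")

    def __post_init__(self) -> None:
        self.lattice_origin = np.asarray(self.lattice_origin, float)
        self.lattice_vectors = np.asarray(self.lattice_vectors, float)
        self.rest_positions = np.asarray(self.rest_positions, float)
        self.displacements = np.asarray(self.displacements, float)
        self.drift = np.asarray(self.drift, float)
        self.reference_flags = np.asarray(self.reference_flags, bool)
        self.shape = tuple(int(v) for v in self.shape)
        if self.psf_sigma <= 0:
            raise ValueError("psf sigma must be > 0")
        if abs(np.linalg.det(self.lattice_vectors)) < 1e-9:
            raise ValueError("lattice vectors must be linearly independent")
        if not np.allclose(self.drift[0], 0.0):
            raise ValueError("drift at frame 0 must be (0, 0)")
        if np.any(self.displacements[:, self.reference_flags, :] != 0.0):
            raise ValueError("reference (cell-free) pillars must not move")

    @property
    def n_pillars(self) -> int:
        return self.rest_positions.shape[0]

    def true_positions(self, frame: int) -> np.ndarray:
        """Rendered (x, y) centres at ``frame``: rest + displacement + drift."""
        return self.rest_positions + self.displacements[frame] + self.drift[frame]


def make_pillar_scene(
    n_rows: int = 10,
    n_cols: int = 10,
    spacing_px: float = 12.0,
    psf_sigma: float = 1.5,
    peak_intensity: float = 5000.0,
    background: float = 400.0,
    snr: float = 25.0,
    pixel_size_um: float = 0.16,
    n_frames: int = 100,
    drift_per_frame_px: tuple[float, float] = (0.0, 0.0),
    max_displacement_px: float = 2.5,
    moving_fraction: float = 0.5,
    hexagonal: bool = False,
    seed: int = 0,
) -> PillarSceneTruth:
    """Build a pillar-scene truth with a programmed traction episode.

    Interior pillars (the "under the cell" set) deflect towards a random
    per-pillar direction following a build-and-partial-release profile
    (smooth rise to a unique peak at ~70% of the movie, then relaxation to
    70% of peak), with per-pillar peak magnitude in [0.5, 1] x
    ``max_displacement_px``; the outermost lattice ring is flagged as
    cell-free reference pillars and never moves.  ``snr`` is peak
    intensity over noise standard deviation; ``snr=inf`` gives a
    noise-free scene.  Drift is linear in time.
    """
    rng = np.random.default_rng(seed)
    margin = 4 * spacing_px / 2 + 6 * psf_sigma
    a1 = np.array([spacing_px, 0.0])
    a2 = np.array([spacing_px / 2, spacing_px * np.sqrt(3) / 2]) if hexagonal \
        else np.array([0.0, spacing_px])
    origin = np.array([margin, margin])
    ij = np.array([(i, j) for j in range(n_rows) for i in range(n_cols)], float)
    rest = origin + ij @ np.vstack([a1, a2])

    # Outermost ring = reference (cell-free); interior pillars may move.
    on_edge = ((ij[:, 0] == 0) | (ij[:, 0] == n_cols - 1)
               | (ij[:, 1] == 0) | (ij[:, 1] == n_rows - 1))
    interior = np.flatnonzero(~on_edge)
    n_moving = int(round(moving_fraction * interior.size))
    moving = rng.choice(interior, size=n_moving, replace=False)

    t = np.arange(n_frames, dtype=float)
    disp = np.zeros((n_frames, rest.shape[0], 2))
    if n_frames > 1 and max_displacement_px > 0:
        # build to a unique peak at ~70% of the movie, relax to 70% of peak
        t_peak = 0.7 * (n_frames - 1)
        rise = 0.5 * (1 - np.cos(np.pi * np.clip(t / t_peak, 0.0, 1.0)))
        release = np.where(
            t > t_peak,
            1.0 - 0.3 * (t - t_peak) / max(1.0, (n_frames - 1) - t_peak),
            1.0)
        profile = rise * release
        for p in moving:
            mag = max_displacement_px * rng.uniform(0.5, 1.0)
            ang = rng.uniform(0, 2 * np.pi)
            disp[:, p, 0] = mag * profile * np.cos(ang)
            disp[:, p, 1] = mag * profile * np.sin(ang)

    drift = np.outer(t, np.asarray(drift_per_frame_px, float))
    noise_sd = 0.0 if np.isinf(snr) else peak_intensity / snr

    extent = origin + np.array([n_cols - 1, n_rows - 1], float) @ np.vstack([a1, a2])
    shape = (int(np.ceil(extent[1] + margin)), int(np.ceil(extent[0] + margin)))
    return PillarSceneTruth(
        lattice_origin=origin, lattice_vectors=np.vstack([a1, a2]),
        rest_positions=rest, displacements=disp, drift=drift,
        reference_flags=on_edge, psf_sigma=psf_sigma,
        peak_intensity=peak_intensity, background=background,
        noise_sd=noise_sd, pixel_size_um=pixel_size_um, n_frames=n_frames,
        seed=seed, shape=shape)


def _render_spots(shape: tuple[int, int], centers: np.ndarray, sigma: float,
                  amplitude: float, out: np.ndarray | None = None) -> np.ndarray:
    """Add isotropic Gaussian spots to an image (windowed, +-5 sigma)."""
    img = np.zeros(shape, float) if out is None else out
    h, w = shape
    r = int(np.ceil(5 * sigma))
    for cx, cy in centers:
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma**2))
    return img


def gen_pillar_timelapse(
    scene: PillarSceneTruth,
    out_path: str | os.PathLike | None = None,
) -> np.ndarray:
    """Render a pillar scene to an ``(n_frames, H, W)`` uint16 stack.

    Each pillar is an isotropic Gaussian spot of amplitude
    ``peak_intensity`` at rest + displacement + drift, on a constant
    background, with additive Gaussian noise of sd ``noise_sd``.  Refuses
    scenes whose pillar spacing is below 4 PSF sigma (spots unresolvable).
    When ``out_path`` is given the stack is written as a multi-frame TIFF
    with the truth record as a ``<name>.truth.json`` sidecar.
    """
    spacing = min(np.linalg.norm(scene.lattice_vectors[0]),
                  np.linalg.norm(scene.lattice_vectors[1]))
    if spacing < 4 * scene.psf_sigma:
        raise ValueError(
            f"pillar spacing {spacing:.2f} px < 4 x psf sigma "
            f"({4 * scene.psf_sigma:.2f} px): spots unresolvable")
    rng = np.random.default_rng(scene.seed)
    shape = scene.shape if scene.shape != (0, 0) else (
        int(scene.rest_positions[:, 1].max() + 20),
        int(scene.rest_positions[:, 0].max() + 20))
    stack = np.empty((scene.n_frames, *shape), np.uint16)
    for k in range(scene.n_frames):
        frame = np.full(shape, float(scene.background))
        _render_spots(shape, scene.true_positions(k), scene.psf_sigma,
                      scene.peak_intensity, out=frame)
        if scene.noise_sd > 0:
            frame += rng.normal(0.0, scene.noise_sd, shape)
        stack[k] = np.clip(np.rint(frame), 0, 65535).astype(np.uint16)
    if out_path is not None:
        tifffile.imwrite(out_path, stack)
        scene.to_json(str(out_path) + ".truth.json"
                      if not str(out_path).endswith(".tif")
                      else str(out_path)[:-4] + ".truth.json")
    return stack


# --------------------------------------------------------------------------
# AFM approach curves
# --------------------------------------------------------------------------

@dataclass
class CurveTruth(_TruthRecord):
    """Ground truth for one simulated Hertzian approach curve."""

    youngs_modulus_pa: float
    poisson: float = 0.5
    radius_m: float = 17.5e-6
    spring_constant_n_per_m: float = 0.07
    sensitivity_m_per_v: float = 50e-9
    contact_height_m: float = 0.0
    baseline_slope_v_per_m: float = 0.0
    baseline_offset_v: float = 0.0
    noise_sd_n: float = 0.0
    max_force_n: float = 1.5e-9
    pre_contact_range_m: float = 2e-6
    n_samples: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.youngs_modulus_pa <= 0:
            raise ValueError("modulus must be > 0")
        if not (0 <= self.poisson <= 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5]")
        if self.radius_m <= 0:
            raise ValueError("radius must be > 0")


def _solve_contact_deflection(travel: np.ndarray, prefac: float,
                              k: float) -> np.ndarray:
    """Deflection d solving k d = prefac (t - d)^{3/2} for travel t >= 0.

    Newton iteration on d in [0, t]; the map is monotone so a handful of
    iterations converge to machine precision.
    """
    d = np.zeros_like(travel)
    for _ in range(60):
        delta = np.clip(travel - d, 0.0, None)
        g = k * d - prefac * delta**1.5
        dg = k + 1.5 * prefac * np.sqrt(delta)
        step = g / dg
        d = np.clip(d - step, 0.0, travel)
        if np.max(np.abs(step)) < 1e-18:
            break
    return d


def gen_force_curve(truth: CurveTruth) -> ForceCurve:
    """Simulate an approach curve in raw (height, deflection-volts) units.

    Heights run from ``contact_height + pre_contact_range`` down to the
    depth at which the noise-free contact force reaches ``max_force``
    (the set-force turnaround).  Below contact the cantilever deflection
    solves the force balance k d = Hertz((z_c - z) - d); above contact it
    is zero.  A linear optical baseline (slope, offset in volts) is added
    to the whole deflection trace, then Gaussian noise of sd
    ``noise_sd_n`` expressed in force units.
    """
    k = truth.spring_constant_n_per_m
    prefac = (4.0 / 3.0) * truth.youngs_modulus_pa / (1 - truth.poisson**2) \
        * np.sqrt(truth.radius_m)
    delta_max = (truth.max_force_n / prefac) ** (2.0 / 3.0)
    z_start = truth.contact_height_m + truth.pre_contact_range_m
    z_end = truth.contact_height_m - delta_max - truth.max_force_n / k
    if not (z_end < truth.contact_height_m < z_start):
        raise ValueError("contact height outside the sampled height range")
    z = np.linspace(z_start, z_end, truth.n_samples)
    travel = np.clip(truth.contact_height_m - z, 0.0, None)
    d = _solve_contact_deflection(travel, prefac, k)
    volts = d / truth.sensitivity_m_per_v \
        + truth.baseline_slope_v_per_m * (z - z_start) + truth.baseline_offset_v
    if truth.noise_sd_n > 0:
        rng = np.random.default_rng(truth.seed)
        volts = volts + rng.normal(0.0, truth.noise_sd_n / k, z.shape) \
            / truth.sensitivity_m_per_v
    return ForceCurve(height_m=z, deflection_v=volts,
                      segment=np.full(z.shape, "approach", dtype=object),
                      spring_constant_n_per_m=k,
                      metadata={"truth": truth.to_dict()})


def gen_hard_surface_curve(
    sensitivity_m_per_v: float = 50e-9,
    spring_constant_n_per_m: float = 0.07,
    contact_height_m: float = 0.0,
    pre_contact_range_m: float = 1e-6,
    indent_range_m: float = 1e-6,
    n_samples: int = 400,
    noise_sd_v: float = 0.0,
    baseline_offset_v: float = 0.0,
    seed: int = 0,
) -> ForceCurve:
    """Approach curve on a rigid substrate, for sensitivity calibration.

    Past contact every metre of piezo travel becomes deflection, so the
    deflection-voltage slope is exactly -1/sensitivity.
    """
    z = np.linspace(contact_height_m + pre_contact_range_m,
                    contact_height_m - indent_range_m, n_samples)
    d = np.clip(contact_height_m - z, 0.0, None)
    volts = d / sensitivity_m_per_v + baseline_offset_v
    if noise_sd_v > 0:
        rng = np.random.default_rng(seed)
        volts = volts + rng.normal(0.0, noise_sd_v, z.shape)
    return ForceCurve(height_m=z, deflection_v=volts,
                      spring_constant_n_per_m=spring_constant_n_per_m)


# --------------------------------------------------------------------------
# blob scenes (focal adhesions, nucleoli, beads) and colocalization
# --------------------------------------------------------------------------

@dataclass
class BlobSceneTruth(_TruthRecord):
    """Elliptical-Gaussian blob scene inside a cell mask."""

    cell_mask: np.ndarray               # (H, W) int labels; 0 = outside
    centers: np.ndarray                 # (n, 2) px, (x, y)
    sigmas: np.ndarray                  # (n, 2) px, (major, minor)
    angles: np.ndarray                  # (n,) rad
    intensities: np.ndarray             # (n,) ADU
    noise_sd: float                     # ADU
    pixel_size_um: float
    seed: int
    n_blobs: int = 0
    target_correlation: float | None = None
    shared_count: int | None = None
    achieved_correlation: float | None = None

    _array_fields = ("cell_mask", "centers", "sigmas", "angles", "intensities")

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask)
        self.centers = np.asarray(self.centers, float).reshape(-1, 2)
        self.sigmas = np.asarray(self.sigmas, float).reshape(-1, 2)
        self.angles = np.asarray(self.angles, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.n_blobs == 0:
            self.n_blobs = self.centers.shape[0]
        if self.n_blobs != self.centers.shape[0]:
            raise ValueError("recorded blob count disagrees with centres")
        h, w = self.cell_mask.shape
        for cx, cy in self.centers:
            ix, iy = int(round(cx)), int(round(cy))
            if not (0 <= ix < w and 0 <= iy < h) or self.cell_mask[iy, ix] == 0:
                raise ValueError("all blob centres must lie inside the cell mask")


def make_blob_scene(
    shape: tuple[int, int] = (256, 256),
    n_blobs: int = 12,
    sigma_range: tuple[float, float] = (1.5, 3.0),
    axis_ratio_range: tuple[float, float] = (1.5, 2.5),
    intensity_range: tuple[float, float] = (800.0, 2000.0),
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    target_correlation: float | None = None,
    min_separation_factor: float | None = None,
    seed: int = 0,
) -> BlobSceneTruth:
    """Random elliptical blobs inside a central elliptical cell mask.

    For counting scenes blob centres are placed with a minimum pairwise
    separation of ``min_separation_factor`` x the summed major sigmas
    (default 3) so that distinct blobs remain distinct connected
    components after thresholding.  Colocalization scenes (a correlation
    target set) place blobs freely: overlap does not bias a pixel-wise
    correlation.
    """
    if min_separation_factor is None:
        min_separation_factor = 0.0 if target_correlation is not None else 3.0
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2, (w - 1) / 2
    mask = (((xx - cx) / (0.42 * w)) ** 2 + ((yy - cy) / (0.42 * h)) ** 2 <= 1)
    mask = mask.astype(np.int32)

    minor = rng.uniform(*sigma_range, n_blobs)
    major = minor * rng.uniform(*axis_ratio_range, n_blobs)
    # keep blob footprints comfortably inside the mask
    pad = 3 * major.max() if n_blobs else 0
    centers = np.empty((n_blobs, 2))
    placed = 0
    attempts = 0
    while placed < n_blobs:
        attempts += 1
        if attempts > 20000:
            raise ValueError(
                "could not place blobs with the required separation; "
                "reduce n_blobs or blob size")
        cand = rng.uniform([pad, pad], [w - pad, h - pad], size=2)
        if not mask[int(round(cand[1])), int(round(cand[0]))]:
            continue
        if placed and min_separation_factor > 0:
            sep = np.hypot(*(centers[:placed] - cand).T)
            if np.any(sep < min_separation_factor
                      * (major[:placed] + major[placed])):
                continue
        centers[placed] = cand
        placed += 1
    blob_area = np.pi * (3 * major) * (3 * minor)
    if n_blobs and blob_area.max() > mask.sum():
        raise ValueError("requested blob area exceeds the cell mask")
    return BlobSceneTruth(
        cell_mask=mask, centers=centers,
        sigmas=np.column_stack([major, minor]),
        angles=rng.uniform(0, np.pi, n_blobs),
        intensities=rng.uniform(*intensity_range, n_blobs),
        noise_sd=noise_sd, pixel_size_um=pixel_size_um, seed=seed,
        n_blobs=n_blobs, target_correlation=target_correlation)


def _render_blobs(shape, centers, sigmas, angles, intensities) -> np.ndarray:
    img = np.zeros(shape, float)
    h, w = shape
    for (cx, cy), (sa, sb), th, amp in zip(centers, sigmas, angles, intensities):
        r = int(np.ceil(4 * sa))
        x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
        y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        xg, yg = np.meshgrid(xs, ys)
        u = xg * np.cos(th) + yg * np.sin(th)
        v = -xg * np.sin(th) + yg * np.cos(th)
        img[y0:y1, x0:x1] += amp * np.exp(-(u**2 / (2 * sa**2)
                                            + v**2 / (2 * sb**2)))
    return img


def _masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x, y = a[mask > 0], b[mask > 0]
    x = x - x.mean()
    y = y - y.mean()
    return float((x @ y) / np.sqrt((x @ x) * (y @ y)))


def gen_blob_image(scene: BlobSceneTruth,
                   correlation_tolerance: float = 0.02) -> np.ndarray:
    """Render a blob scene to one channel, or two correlated channels.

    Without a correlation target the return is an ``(H, W)`` image.  With a
    target r in [0, 1] the return is ``(2, H, W)``: channel 2 shares the
    first ``k`` blobs of channel 1 and adds independent blobs elsewhere,
    with ``k`` chosen (and, if the discrete grid is too coarse, a blend
    between adjacent k) so that the mask-restricted Pearson correlation of
    the noise-free channels is within ``correlation_tolerance`` of the
    target.  A target of 1.0 returns channel 2 as an affine copy of
    channel 1.  The achieved noise-free correlation and shared count are
    written back into the truth record.
    """
    shape = scene.cell_mask.shape
    ch1 = _render_blobs(shape, scene.centers, scene.sigmas, scene.angles,
                        scene.intensities)
    rng = np.random.default_rng(scene.seed + 1)
    if scene.target_correlation is None:
        if scene.noise_sd > 0:
            ch1 = ch1 + rng.normal(0, scene.noise_sd, shape)
        return ch1

    target = float(scene.target_correlation)
    if target >= 1.0:
        ch2 = 1.3 * ch1 + 50.0
        scene.shared_count = scene.n_blobs
        scene.achieved_correlation = 1.0
    else:
        # independent blob set for channel 2, same statistics
        indep = make_blob_scene(shape=shape, n_blobs=scene.n_blobs,
                                noise_sd=0.0,
                                pixel_size_um=scene.pixel_size_um,
                                min_separation_factor=0.0,
                                seed=scene.seed + 7919)
        per_blob = [_render_blobs(shape, scene.centers[i:i + 1],
                                  scene.sigmas[i:i + 1], scene.angles[i:i + 1],
                                  scene.intensities[i:i + 1])
                    for i in range(scene.n_blobs)]
        indep_per_blob = [_render_blobs(shape, indep.centers[i:i + 1],
                                        indep.sigmas[i:i + 1],
                                        indep.angles[i:i + 1],
                                        indep.intensities[i:i + 1])
                          for i in range(scene.n_blobs)]
        shared_cum = np.cumsum([np.zeros(shape)] + per_blob, axis=0)
        indep_cum = np.cumsum([np.zeros(shape)] + indep_per_blob, axis=0)
        rs = np.array([
            _masked_pearson(ch1, shared_cum[k] + (indep_cum[-1] - indep_cum[k]),
                            scene.cell_mask)
            for k in range(scene.n_blobs + 1)])
        k = int(np.argmin(np.abs(rs - target)))
        ch2 = shared_cum[k] + (indep_cum[-1] - indep_cum[k])
        if abs(rs[k] - target) > correlation_tolerance:
            # blend towards the adjacent shared count to hit the target
            k2 = k + 1 if (k < scene.n_blobs and
                           (rs[k] - target) * (rs[k + 1] - target) <= 0) else k - 1
            alt = shared_cum[k2] + (indep_cum[-1] - indep_cum[k2])
            from scipy.optimize import brentq
            f = lambda w: _masked_pearson(ch1, (1 - w) * ch2 + w * alt,
                                          scene.cell_mask) - target
            wstar = brentq(f, 0.0, 1.0) if f(0.0) * f(1.0) <= 0 else 0.0
            ch2 = (1 - wstar) * ch2 + wstar * alt
        scene.shared_count = k
        scene.achieved_correlation = _masked_pearson(ch1, ch2, scene.cell_mask)
    out = np.stack([ch1, ch2])
    if scene.noise_sd > 0:
        out = out + rng.normal(0, scene.noise_sd, out.shape)
    return out


# --------------------------------------------------------------------------
# fiber textures
# --------------------------------------------------------------------------

def gen_fiber_image(
    orientation_sd: float,
    theta0: float = 0.0,
    n_fibers: int = 200,
    shape: tuple[int, int] = (256, 256),
    length: float = 60.0,
    amplitude: float = 1000.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Straight fiber segments with orientations ~ Normal(theta0, sd).

    ``orientation_sd = inf`` draws orientations uniformly on [0, pi).
    Returns the rendered image and a record with the drawn orientations'
    circular statistics on the axial (period-pi) scale: the resultant
    length R of exp(2 i theta) and circular dispersion 1 - R.
    """
    if orientation_sd < 0:
        raise ValueError("orientation sd must be >= 0")
    rng = np.random.default_rng(seed)
    if np.isinf(orientation_sd):
        thetas = rng.uniform(0, np.pi, n_fibers)
    else:
        thetas = np.mod(rng.normal(theta0, orientation_sd, n_fibers), np.pi)
    h, w = shape
    img = np.zeros(shape, float)
    from skimage.draw import line_aa
    for th in thetas:
        cx = rng.uniform(0.15 * w, 0.85 * w)
        cy = rng.uniform(0.15 * h, 0.85 * h)
        dx, dy = np.cos(th) * length / 2, np.sin(th) * length / 2
        r0, c0 = int(round(cy - dy)), int(round(cx - dx))
        r1, c1 = int(round(cy + dy)), int(round(cx + dx))
        rr, cc, val = line_aa(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[ok], cc[ok]] += amplitude * val[ok]
    resultant = float(np.abs(np.mean(np.exp(2j * thetas))))
    record = {"orientations_rad": thetas, "resultant_length": resultant,
              "circular_dispersion": 1.0 - resultant, "seed": seed,
              "orientation_sd": float(orientation_sd), "theta0": float(theta0)}
    return img, record


# --------------------------------------------------------------------------
# group tables and Ct tables
# --------------------------------------------------------------------------

def gen_group_table(
    means: dict,
    noise_sd: float,
    n_per_group: int,
    seed: int = 0,
    value_name: str = "value",
) -> pd.DataFrame:
    """Tidy two-factor (or one-factor) table with Gaussian within-group noise.

    ``means`` maps a level or a ``(levelA, levelB)`` tuple to the true group
    mean.  Output columns are ``factorA`` (and ``factorB`` for two-factor
    designs) and the measurement column; true means are stored in
    ``df.attrs["true_means"]``.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    keys = list(means)
    if not keys:
        raise ValueError("need at least one group")
    two_factor = isinstance(keys[0], tuple)
    levels_a = sorted({(k[0] if two_factor else k) for k in keys})
    if len(levels_a) < 2 and not two_factor:
        raise ValueError("need >= 2 levels in the factor")
    rng = np.random.default_rng(seed)
    rows = []
    for key in keys:
        mu = means[key]
        draws = mu + rng.normal(0.0, noise_sd, n_per_group)
        for v in draws:
            if two_factor:
                rows.append({"factorA": key[0], "factorB": key[1],
                             value_name: v})
            else:
                rows.append({"factorA": key, value_name: v})
    df = pd.DataFrame(rows)
    df.attrs["true_means"] = {str(k): float(v) for k, v in means.items()}
    df.attrs["noise_sd"] = float(noise_sd)
    df.attrs["seed"] = int(seed)
    return df


def gen_ct_table(
    fold_changes: dict,
    calibrator: str,
    target_gene: str = "EIF6",
    reference_gene: str = "GAPDH",
    base_ct_target: float = 24.0,
    base_ct_reference: float = 18.0,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    n_samples_per_condition: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table realising specified true fold changes vs a calibrator.

    A fold change f for a condition shifts the target-gene Ct by
    -log2(f) relative to the calibrator condition (amplification
    efficiency 2).  Columns: sample, condition, gene, ct.
    """
    if calibrator not in fold_changes:
        raise ValueError("calibrator condition must appear in fold_changes")
    rng = np.random.default_rng(seed)
    rows = []
    for cond, fold in fold_changes.items():
        dct_shift = -np.log2(fold)
        for s in range(n_samples_per_condition):
            sample = f"{cond}_{s + 1}"
            for gene, base in ((target_gene, base_ct_target + dct_shift),
                               (reference_gene, base_ct_reference)):
                for _ in range(n_replicates):
                    rows.append({"sample": sample, "condition": cond,
                                 "gene": gene,
                                 "ct": base + rng.normal(0, replicate_sd)})
    df = pd.DataFrame(rows)
    df.attrs["true_folds"] = {str(k): float(v) for k, v in fold_changes.items()}
    return df
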