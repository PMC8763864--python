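"""Micropillar traction-force microscopy.

Bright-field time-lapses of an elastic micropillar array are reduced to
per-pillar traction forces in four steps: candidate pillar centres are
detected on the first frame, each pillar's point-spread-function centre is
tracked with sub-pixel precision through every frame, rigid stage drift is
estimated from cell-free reference pillars and subtracted, and
displacements relative to the zero-force frame-0 position are multiplied by
the pillar spring stiffness to give force vectors.  The per-pillar maximum
force magnitude over the movie is the peak force; peak forces of the
pillars under the cell are summarised per cell.

Each pillar behaves as an independent linear spring: ``F = k * u`` with
``k`` in nN/um.  The stiffness is substrate calibration data and must be
supplied by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.feature import peak_local_max

__all__ = [
    "PillarTrackSet",
    "DriftTrace",
    "TractionField",
    "detect_pillars",
    "localize_center",
    "track_pillars",
    "estimate_drift",
    "compute_displacements",
    "displacements_to_forces",
]

log = logging.getLogger(__name__)


@dataclass
class PillarTrackSet:
    """Sub-pixel pillar centres for every frame.

    ``positions`` is ``(n_pillars, n_frames, 2)`` in (x, y) pixels with NaN
    marking frames where a pillar could not be localized; ``residuals``
    holds the RMS fit residual per localization and ``ok`` whether the
    Gaussian fit converged (False = centroid fallback or missing).
    """

    pillar_ids: np.ndarray
    positions: np.ndarray
    residuals: np.ndarray
    ok: np.ndarray
    reference_flags: np.ndarray
    pixel_size_um: float = 1.0
    frame_interval_s: float = 2.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        n, t, _ = self.positions.shape
        self.reference_flags = np.asarray(self.reference_flags, bool)
        if self.reference_flags.shape != (n,):
            raise ValueError("one reference flag per pillar required")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.positions[:, :, 0]).mean(axis=1)


@dataclass
class DriftTrace:
    drift_px: np.ndarray                # (n_frames, 2)
    estimator: str
    reference_ids: np.ndarray

    def __post_init__(self) -> None:
        self.drift_px = np.asarray(self.drift_px, float)
        if not np.all(self.drift_px[0] == 0.0):
            raise ValueError("drift at frame 0 must be exactly (0, 0)")


@dataclass
class TractionField:
    """Displacements (um), forces (nN) and per-pillar peak forces."""

    pillar_ids: np.ndarray
    displacements_um: np.ndarray        # (n_pillars, n_frames, 2)
    forces_nn: np.ndarray               # (n_pillars, n_frames, 2)
    stiffness_nn_per_um: float
    peak_forces_nn: np.ndarray          # (n_pillars,)
    cell_summary: dict = field(default_factory=dict)


def detect_pillars(frame: np.ndarray, spacing_hint_px: float,
                   smooth_sigma: float = 1.0,
                   threshold_rel: float = 0.3) -> np.ndarray:
    """Candidate pillar rest positions from one frame.

    Local maxima of the lightly smoothed frame, deduplicated to at most one
    detection per lattice site by enforcing a minimum separation of half
    the spacing hint.  Returns ``(n, 2)`` (x, y) pixel coordinates.
    """
    if spacing_hint_px < 4:
        raise ValueError("spacing hint must be >= 4 px")
    img = ndimage.gaussian_filter(np.asarray(frame, float), smooth_sigma)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo <= 0:
        raise ValueError("blank frame: no intensity contrast, nothing to detect")
    peaks = peak_local_max(img, min_distance=max(1, int(spacing_hint_px / 2)),
                           threshold_abs=lo + threshold_rel * (hi - lo),
                           exclude_border=False)
    if peaks.size == 0:
        raise ValueError(
            "no pillar candidates found; check spacing hint and contrast")
    return peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)


def _gauss2d(params, xg, yg):
    amp, x0, y0, sigma, off = params
    return amp * np.exp(-((xg - x0) ** 2 + (yg - y0) ** 2)
                        / (2 * sigma**2)) + off


def localize_center(frame: np.ndarray, approx_xy, window_px: int,
                    ) -> tuple[float, float, float, bool]:
    """Sub-pixel spot centre by isotropic-Gaussian least squares.

    Fits amplitude, centre, sigma and constant offset over a
    ``window_px``-wide square around ``approx_xy``.  If the fit fails to
    converge or lands on an implausible sigma (outside [0.5, window/2] px)
    the background-subtracted intensity centroid is returned instead and
    flagged.  Returns ``(x, y, rms_residual, gaussian_ok)``.

    Raises if the window is clipped by the image edge.
    """
    frame = np.asarray(frame, float)
    h, w = frame.shape
    half = window_px // 2
    cx, cy = int(round(approx_xy[0])), int(round(approx_xy[1]))
    x0, x1 = cx - half, cx + half + 1
    y0, y1 = cy - half, cy + half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"window around ({cx}, {cy}) clipped by image edge")
    patch = frame[y0:y1, x0:x1]
    yg, xg = np.mgrid[y0:y1, x0:x1]

    off0 = float(patch.min())
    amp0 = float(patch.max()) - off0
    p0 = np.array([amp0, approx_xy[0], approx_xy[1], max(1.0, half / 3), off0])
    ok = True
    try:
        res = least_squares(
            lambda p: (_gauss2d(p, xg, yg) - patch).ravel(), p0,
            method="lm", max_nfev=200)
        amp, xf, yf, sigma, _ = res.x
        rms = float(np.sqrt(np.mean(res.fun**2)))
        if (not res.success or amp <= 0 or not (0.5 <= abs(sigma) <= half)
                or not (x0 <= xf < x1) or not (y0 <= yf < y1)):
            ok = False
    except Exception:  # pragma: no cover - defensive
        ok = False
    if not ok:
        bg = np.percentile(patch, 10)
        wts = np.clip(patch - bg, 0, None)
        tot = wts.sum()
        if tot <= 0:
            return float("nan"), float("nan"), float("nan"), False
        xf = float((wts * xg).sum() / tot)
        yf = float((wts * yg).sum() / tot)
        rms = float(np.sqrt(np.mean((patch - bg - wts.mean()) ** 2)))
        return xf, yf, rms, False
    return float(xf), float(yf), rms, True


def track_pillars(stack: np.ndarray, initial_positions: np.ndarray,
                  spacing_px: float, window_px: int | None = None,
                  reference_flags: np.ndarray | None = None,
                  pixel_size_um: float = 1.0,
                  frame_interval_s: float = 2.0) -> PillarTrackSet:
    """Track every pillar through the stack.

    Each pillar is re-localized per frame in a window centred on its
    previous position (nearest-neighbour association through time).  A
    localization farther than half the lattice spacing from the previous
    position is rejected as a mis-association and the frame marked
    missing.  If two pillars collapse onto the same position the one with
    the lower fit residual keeps it.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, H, W)")
    init = np.asarray(initial_positions, float)
    n, t = init.shape[0], stack.shape[0]
    window_px = window_px or max(7, int(spacing_px) - 2 | 1)
    positions = np.full((n, t, 2), np.nan)
    residuals = np.full((n, t), np.nan)
    ok = np.zeros((n, t), bool)
    max_jump = spacing_px / 2

    prev = init.copy()
    for k in range(t):
        frame = stack[k]
        for i in range(n):
            if np.isnan(prev[i, 0]):
                continue
            try:
                x, y, r, good = localize_center(frame, prev[i], window_px)
            except ValueError:
                continue
            if np.isnan(x) or np.hypot(x - prev[i, 0], y - prev[i, 1]) > max_jump:
                continue
            positions[i, k] = (x, y)
            residuals[i, k] = r
            ok[i, k] = good
        # resolve duplicate assignments: keep the better fit
        found = np.flatnonzero(~np.isnan(positions[:, k, 0]))
        for a_idx in range(found.size):
            for b_idx in range(a_idx + 1, found.size):
                i, j = found[a_idx], found[b_idx]
                if np.isnan(positions[i, k, 0]) or np.isnan(positions[j, k, 0]):
                    continue
                d = np.hypot(*(positions[i, k] - positions[j, k]))
                if d < spacing_px / 4:
                    loser = i if residuals[i, k] > residuals[j, k] else j
                    positions[loser, k] = np.nan
                    ok[loser, k] = False
                    log.warning("frame %d: pillars %d/%d collapsed; "
                                "pillar %d marked missing", k, i, j, loser)
        prev = np.where(np.isnan(positions[:, k]), prev, positions[:, k])
    if reference_flags is None:
        reference_flags = np.zeros(n, bool)
    return PillarTrackSet(pillar_ids=np.arange(n), positions=positions,
                          residuals=residuals, ok=ok,
                          reference_flags=np.asarray(reference_flags, bool),
                          pixel_size_um=pixel_size_um,
                          frame_interval_s=frame_interval_s)


def estimate_drift(tracks: PillarTrackSet) -> DriftTrace:
    """Stage drift as the component-wise median displacement of cell-free
    reference pillars relative to frame 0.  Frame 0 drift is exactly zero.
    """
    refs = np.flatnonzero(tracks.reference_flags)
    if refs.size == 0:
        raise ValueError(
            "no reference pillars flagged; select a cell-free region and "
            "flag its pillars to enable drift correction")
    p = tracks.positions[refs]                     # (r, t, 2)
    complete = ~np.isnan(p[:, :, 0]).any(axis=1)
    if not complete.any():
        raise ValueError("no reference pillar has a complete track")
    p = p[complete]
    drift = np.median(p - p[:, :1, :], axis=0)
    drift[0] = 0.0
    return DriftTrace(drift_px=drift, estimator="median",
                      reference_ids=refs[complete])


def compute_displacements(tracks: PillarTrackSet,
                          drift: DriftTrace | None = None) -> np.ndarray:
    """Drift-corrected displacement of every pillar from its frame-0
    (zero-force) position, in micrometres: ``u_i(t) = (p_i(t) - drift(t)) -
    p_i(0)``.  Frame-0 displacement is exactly zero; missing positions stay
    NaN.
    """
    p = tracks.positions
    d = np.zeros((tracks.n_frames, 2)) if drift is None else drift.drift_px
    if d.shape[0] != tracks.n_frames:
        raise ValueError("drift trace must cover every frame")
    u = (p - d[None, :, :]) - p[:, :1, :]
    u[:, 0, :] = 0.0
    return u * tracks.pixel_size_um


def displacements_to_forces(
    displacements_um: np.ndarray,
    stiffness_nn_per_um: float,
    pillar_ids: np.ndarray | None = None,
    cell_flags: np.ndarray | None = None,
    max_missing_fraction: float = 0.2,
) -> TractionField:
    """Convert displacements to traction forces and summarise peaks.

    Forces are the linear spring law per component; the per-pillar peak is
    the maximum force magnitude over observed frames.  The cell summary
    (mean/sum of peak forces, pillar count) covers pillars flagged as under
    the cell, excluding pillars missing more than ``max_missing_fraction``
    of frames.
    """
    if stiffness_nn_per_um <= 0:
        raise ValueError("pillar stiffness must be > 0")
    u = np.asarray(displacements_um, float)
    n = u.shape[0]
    forces = stiffness_nn_per_um * u
    mag = np.linalg.norm(forces, axis=2)           # (n, t), NaN where missing
    with np.errstate(invalid="ignore"):
        peaks = np.nanmax(mag, axis=1)
    peaks = np.where(np.isnan(peaks), 0.0, peaks)
    if pillar_ids is None:
        pillar_ids = np.arange(n)
    if cell_flags is None:
        cell_flags = np.ones(n, bool)
    cell_flags = np.asarray(cell_flags, bool)
    missing = np.isnan(u[:, :, 0]).mean(axis=1)
    usable = cell_flags & (missing <= max_missing_fraction)
    dropped = int(cell_flags.sum() - usable.sum())
    if dropped:
        log.info("excluding %d pillar(s) missing > %.0f%% of frames from the "
                 "cell summary", dropped, 100 * max_missing_fraction)
    sel = peaks[usable]
    summary = {
        "n_pillars": int(usable.sum()),
        "n_excluded_missing": dropped,
        "mean_peak_force_nN": float(sel.mean()) if sel.size else 0.0,
        "sum_peak_force_nN": float(sel.sum()) if sel.size else 0.0,
        "max_peak_force_nN": float(sel.max()) if sel.size else 0.0,
    }
    return TractionField(pillar_ids=np.asarray(pillar_ids),
                         displacements_um=u, forces_nn=forces,
                         stiffness_nn_per_um=stiffness_nn_per_um,
                         peak_forces_nn=peaks, cell_summary=summary)
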