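"""AFM nanoindentation analysis: sensitivity calibration, force conversion and
Hertz spherical-indenter fitting.

The pipeline mirrors standard force-spectroscopy practice for soft samples
probed with a bead-functionalised cantilever:

1. the photodiode sensitivity (m/V) is calibrated from the contact slope of a
   curve acquired on a rigid substrate;
2. raw (piezo height, deflection voltage) samples are converted to force via
   the cantilever spring constant, a linear pre-contact baseline is removed,
   and height is compliance-corrected to tip--sample separation;
3. the contact point and Young's modulus are estimated jointly by scanning
   candidate contact points and solving the delta^{3/2}-linearised
   least-squares problem in closed form at each one.

Sign conventions: piezo height decreases during approach; deflection is
positive when the cantilever is pushed away from the sample (repulsive
contact).  Tip--sample separation is ``height + deflection`` up to the
(unknown) additive contact offset, so indentation is
``contact_separation - separation``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "HertzFit",
    "calibrate_sensitivity",
    "deflection_to_force",
    "hertz_force",
    "fit_hertz",
]

#: Default Poisson ratio: incompressible-cell limit.
DEFAULT_POISSON = 0.5
#: Default indenter radius (m): half of a 35 um glass bead.
DEFAULT_RADIUS_M = 17.5e-6


@dataclass
class ForceCurve:
    """A force--distance curve in raw or calibrated units.

    Exactly one of ``deflection_v`` (photodiode volts) or ``force_n``
    (newtons) must be supplied.  ``segment`` labels each sample as
    ``"approach"`` or ``"retract"``.
    """

    height_m: np.ndarray
    deflection_v: np.ndarray | None = None
    force_n: np.ndarray | None = None
    segment: np.ndarray | None = None
    sensitivity_m_per_v: float | None = None
    spring_constant_n_per_m: float = 0.07
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.height_m = np.asarray(self.height_m, dtype=float)
        if (self.deflection_v is None) == (self.force_n is None):
            raise ValueError("exactly one of deflection_v / force_n must be set")
        if self.deflection_v is not None:
            self.deflection_v = np.asarray(self.deflection_v, dtype=float)
        if self.force_n is not None:
            self.force_n = np.asarray(self.force_n, dtype=float)
        if self.segment is None:
            self.segment = np.full(self.height_m.shape, "approach", dtype=object)
        else:
            self.segment = np.asarray(self.segment, dtype=object)
        if self.spring_constant_n_per_m <= 0:
            raise ValueError("spring constant must be > 0")
        n = self.height_m.size
        for arr in (self.deflection_v, self.force_n, self.segment):
            if arr is not None and arr.size != n:
                raise ValueError("curve columns must have equal length")

    # ------------------------------------------------------------------ I/O
    def approach(self) -> "ForceCurve":
        """Approach-segment view, sorted in acquisition order (height
        decreasing)."""
        sel = self.segment == "approach"
        order = np.argsort(self.height_m[sel])[::-1]
        idx = np.flatnonzero(sel)[order]
        return ForceCurve(
            height_m=self.height_m[idx],
            deflection_v=None if self.deflection_v is None else self.deflection_v[idx],
            force_n=None if self.force_n is None else self.force_n[idx],
            segment=self.segment[idx],
            sensitivity_m_per_v=self.sensitivity_m_per_v,
            spring_constant_n_per_m=self.spring_constant_n_per_m,
            metadata=dict(self.metadata),
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        if self.deflection_v is not None:
            df = pd.DataFrame(
                {"height_m": self.height_m, "deflection_V": self.deflection_v,
                 "segment": self.segment}
            )
        else:
            df = pd.DataFrame(
                {"height_m": self.height_m, "force_N": self.force_n,
                 "segment": self.segment}
            )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike,
                 spring_constant_n_per_m: float = 0.07) -> "ForceCurve":
        df = pd.read_csv(path)
        required = {"height_m", "segment"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"curve CSV {path} missing column(s): {sorted(missing)}")
        if "deflection_V" in df.columns:
            return cls(height_m=df["height_m"].to_numpy(),
                       deflection_v=df["deflection_V"].to_numpy(),
                       segment=df["segment"].to_numpy(),
                       spring_constant_n_per_m=spring_constant_n_per_m)
        if "force_N" in df.columns:
            return cls(height_m=df["height_m"].to_numpy(),
                       force_n=df["force_N"].to_numpy(),
                       segment=df["segment"].to_numpy(),
                       spring_constant_n_per_m=spring_constant_n_per_m)
        raise ValueError(
            f"curve CSV {path} missing column(s): ['deflection_V' or 'force_N']")


@dataclass
class HertzFit:
    """Result of a Hertz spherical-indenter fit to one approach curve."""

    contact_height_m: float
    youngs_modulus_pa: float
    poisson: float
    radius_m: float
    fit_start_m: float
    fit_end_m: float
    rms_residual_n: float
    converged: bool
    n_fit_samples: int = 0

    def __post_init__(self) -> None:
        if self.rms_residual_n < 0:
            raise ValueError("residual must be >= 0")


def hertz_force(indentation_m, youngs_modulus_pa: float,
                poisson: float = DEFAULT_POISSON,
                radius_m: float = DEFAULT_RADIUS_M):
    """Hertz contact force of a rigid sphere on an elastic half-space.

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2); F(0) = 0.

    Parameters are indentation depth delta (m, scalar or array, >= 0),
    Young's modulus E (Pa), Poisson ratio nu and sphere radius R (m).
    """
    delta = np.asarray(indentation_m, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation must be >= 0")
    if radius_m <= 0:
        raise ValueError("indenter radius must be > 0")
    if not (0 <= poisson < 1):
        raise ValueError("Poisson ratio must be in [0, 1)")
    out = (4.0 / 3.0) * (youngs_modulus_pa / (1.0 - poisson**2)) \
        * np.sqrt(radius_m) * delta**1.5
    return out if out.ndim else float(out)


def _linear_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line y = a*x + b; returns (a, b, r_squared)."""
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(a), float(b), r2


def calibrate_sensitivity(curve: ForceCurve, min_r_squared: float = 0.99) -> float:
    """Photodiode sensitivity (m/V) from a curve on a rigid substrate.

    On an incompressible surface every metre of piezo travel past contact
    becomes one metre of cantilever deflection, so the contact-side slope of
    deflection (V) versus height (m) is -1/sensitivity.  The slope is taken
    by least squares over the steepest contiguous half of the contact
    region (the deepest half, furthest from the contact kink).
    """
    app = curve.approach()
    if app.deflection_v is None:
        raise ValueError("sensitivity calibration needs raw deflection volts")
    v = app.deflection_v
    z = app.height_m
    n = v.size
    if n < 10:
        raise ValueError("too few approach samples for calibration")
    # Baseline from the pre-contact start of the approach.
    n_base = max(3, int(0.3 * n))
    base_sd = float(np.std(v[:n_base]))
    base_mean = float(np.mean(v[:n_base]))
    thresh = base_mean + max(5.0 * base_sd, 1e-12 * max(1.0, abs(base_mean)))
    above = np.flatnonzero(v > thresh)
    if above.size < 6:
        raise ValueError("no contact region found: curve never leaves baseline")
    contact = above[0]
    # Steepest (deepest) contiguous half of the contact region.
    half = contact + (n - contact) // 2
    a, _b, r2 = _linear_fit(z[half:], v[half:])
    if r2 < min_r_squared:
        raise ValueError(
            f"contact segment not linear (R^2 = {r2:.4f} < {min_r_squared})")
    if a == 0:
        raise ValueError("zero contact slope; cannot calibrate")
    return 1.0 / abs(a)


def deflection_to_force(
    curve: ForceCurve,
    sensitivity_m_per_v: float | None = None,
    spring_constant_n_per_m: float | None = None,
    baseline_fraction: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert an approach curve to (separation, force) with baseline removed.

    Deflection d (m) = V * sensitivity; force F = k * d; separation is the
    compliance-corrected tip--sample distance ``height + d`` (arbitrary
    offset; the Hertz fit locates the contact point).  A straight line
    fitted to the first ``baseline_fraction`` of approach samples (the
    pre-contact region) is subtracted from the force to remove photodiode
    offset and optical-interference tilt.  Curves already expressed in
    newtons pass through with baseline subtraction only.

    Returns ``(separation_m, force_n)`` in acquisition order (approach,
    height decreasing).
    """
    app = curve.approach()
    k = spring_constant_n_per_m or app.spring_constant_n_per_m
    if app.force_n is not None:
        d = app.force_n / k
        force = app.force_n.copy()
    else:
        sens = sensitivity_m_per_v or app.sensitivity_m_per_v
        if sens is None or sens <= 0:
            raise ValueError("sensitivity (m/V) must be provided and > 0")
        d = app.deflection_v * sens
        force = k * d
    z = app.height_m
    n_base = max(2, int(baseline_fraction * z.size))
    a, b, _ = _linear_fit(z[:n_base], force[:n_base])
    force = force - (a * z + b)
    separation = z + force / k
    return separation, force


def fit_hertz(
    separation_m: np.ndarray,
    force_n: np.ndarray,
    radius_m: float = DEFAULT_RADIUS_M,
    poisson: float = DEFAULT_POISSON,
    candidate_fraction: tuple[float, float] = (0.02, 0.98),
    max_residual_fraction: float = 0.2,
) -> HertzFit:
    """Joint contact-point / Young's-modulus estimate for one approach curve.

    Every sample in the central ``candidate_fraction`` span of the curve
    (by index, acquisition order) is a candidate contact point; the default
    spans nearly the whole curve because on stiff samples the set-force
    turnaround leaves the true contact close to the end of the sweep.  For candidate c the indentation of
    later samples is delta = s_c - s, the model is linear in E on
    delta^{3/2}, and E follows in closed form; pre-contact samples are
    modelled as zero force.  The candidate minimising the whole-curve RMS
    residual wins.  A best fit whose residual exceeds
    ``max_residual_fraction`` of the maximum force is flagged non-converged
    (the modulus is still reported).
    """
    s = np.asarray(separation_m, dtype=float)
    f = np.asarray(force_n, dtype=float)
    if s.size != f.size:
        raise ValueError("separation and force must have equal length")
    if s.size < 50:
        raise ValueError("need >= 50 approach samples spanning contact")
    # Acquisition order: separation decreasing.
    if s[0] < s[-1]:
        s, f = s[::-1], f[::-1]
    n = s.size
    lo, hi = int(candidate_fraction[0] * n), int(candidate_fraction[1] * n)
    prefac = (4.0 / 3.0) / (1.0 - poisson**2) * np.sqrt(radius_m)

    best = (np.inf, lo, 0.0)  # (rss, candidate index, E)
    # Cumulative sums let the pre-contact residual be O(1) per candidate.
    cum_f2 = np.concatenate([[0.0], np.cumsum(f**2)])
    for c in range(lo, hi):
        delta = s[c] - s[c:]
        x = prefac * np.clip(delta, 0.0, None) ** 1.5
        sxx = float(x @ x)
        if sxx <= 0:
            continue
        e_hat = float(x @ f[c:]) / sxx
        if e_hat <= 0:
            continue
        rss = cum_f2[c] + float(np.sum((f[c:] - e_hat * x) ** 2))
        if rss < best[0]:
            best = (rss, c, e_hat)
    rss, c, e_hat = best
    s_c = None
    if np.isfinite(rss) and e_hat > 0:
        # Continuous refinement: the modulus is steeply sensitive to the
        # contact point on stiff curves (few, shallow post-contact samples),
        # so polish z_c between the neighbouring grid samples.
        from scipy.optimize import minimize_scalar

        def _rss_at(zc: float) -> tuple[float, float]:
            delta = np.clip(zc - s, 0.0, None)
            x = prefac * delta**1.5
            sxx = float(x @ x)
            if sxx <= 0:
                return np.inf, 0.0
            e = float(x @ f) / sxx
            return float(np.sum((f - e * x) ** 2)), e

        lo_s = s[min(c + 1, n - 1)]
        hi_s = s[max(c - 1, 0)]
        if hi_s > lo_s:
            opt = minimize_scalar(lambda zc: _rss_at(zc)[0],
                                  bounds=(lo_s, hi_s), method="bounded",
                                  options={"xatol": 1e-12})
            rss_ref, e_ref = _rss_at(float(opt.x))
            if rss_ref <= rss and e_ref > 0:
                rss, e_hat, s_c = rss_ref, e_ref, float(opt.x)
    if not np.isfinite(rss) or e_hat <= 0:
        # No candidate produced a positive modulus (e.g. flat curve).
        return HertzFit(contact_height_m=float(s[n // 2]),
                        youngs_modulus_pa=float("nan"), poisson=poisson,
                        radius_m=radius_m, fit_start_m=float(s[n // 2]),
                        fit_end_m=float(s[-1]),
                        rms_residual_n=float(np.sqrt(np.mean(f**2))),
                        converged=False, n_fit_samples=0)
    rms = float(np.sqrt(rss / n))
    fmax = float(np.max(np.abs(f)))
    converged = fmax > 0 and rms <= max_residual_fraction * fmax
    zc = float(s[c]) if s_c is None else s_c
    return HertzFit(contact_height_m=zc, youngs_modulus_pa=e_hat,
                    poisson=poisson, radius_m=radius_m,
                    fit_start_m=zc, fit_end_m=float(s[-1]),
                    rms_residual_n=rms, converged=converged,
                    n_fit_samples=int(np.sum(s < zc)))


def fit_curve(curve: ForceCurve,
              radius_m: float = DEFAULT_RADIUS_M,
              poisson: float = DEFAULT_POISSON,
              sensitivity_m_per_v: float | None = None) -> HertzFit:
    """Convenience wrapper: calibrated curve in, HertzFit out."""
    sep, force = deflection_to_force(curve, sensitivity_m_per_v)
    return fit_hertz(sep, force, radius_m=radius_m, poisson=poisson)
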