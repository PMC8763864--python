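"""Minimal plotting: per-pillar peak-force vector map."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["force_vector_map"]


def force_vector_map(rest_positions: np.ndarray, field, out_path: str) -> str:
    """Quiver plot of each pillar's force vector at its peak-force frame."""
    forces = field.forces_nn
    mag = np.linalg.norm(forces, axis=2)
    mag = np.where(np.isnan(mag), -np.inf, mag)
    peak_frame = np.argmax(mag, axis=1)
    vec = forces[np.arange(forces.shape[0]), peak_frame]
    vec = np.where(np.isnan(vec), 0.0, vec)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.quiver(rest_positions[:, 0], rest_positions[:, 1],
              vec[:, 0], vec[:, 1], field.peak_forces_nn,
              angles="xy", cmap="viridis")
    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title("peak traction forces (nN)")
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
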