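"""Schematic topographic rendering of band-power matrices.

These are quick-look maps on the idealized montage (azimuthal projection of
the unit-sphere electrode positions), not anatomically registered plots.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy.interpolate import griddata  # noqa: E402

from .montage import CHANNELS_32, channel_positions

__all__ = ["project_2d", "render_topomaps"]


def project_2d(labels=CHANNELS_32) -> np.ndarray:
    """Azimuthal equidistant projection of electrode positions to the plane
    (nose up)."""
    xyz = channel_positions(labels)
    incl = np.arccos(np.clip(xyz[:, 2], -1, 1))
    az = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 at nose, positive right
    return np.column_stack([incl * np.sin(az), incl * np.cos(az)])


def render_topomaps(
    matrix: np.ndarray,
    levels,
    band_names,
    labels=CHANNELS_32,
    path=None,
    grid_n: int = 64,
):
    """Render a levels x bands grid of interpolated scalp maps.

    ``matrix`` is the (n_levels, n_bands, n_channels) output of
    :func:`fearloop.offline.grand_average_topomap`. Returns the figure;
    saves to ``path`` when given.
    """
    pos = project_2d(labels)
    lim = 1.05 * np.abs(pos).max()
    gx, gy = np.meshgrid(
        np.linspace(-lim, lim, grid_n), np.linspace(-lim, lim, grid_n)
    )
    n_lev, n_band, _ = matrix.shape
    fig, axes = plt.subplots(
        n_lev, n_band, figsize=(2.2 * n_band, 2.0 * n_lev), squeeze=False
    )
    for i in range(n_lev):
        for j in range(n_band):
            ax = axes[i][j]
            vals = matrix[i, j]
            if np.all(np.isnan(vals)):
                ax.set_axis_off()
                continue
            z = griddata(pos, vals, (gx, gy), method="cubic")
            ax.contourf(gx, gy, z, levels=12, cmap="RdBu_r")
            ax.scatter(pos[:, 0], pos[:, 1], s=2, c="k")
            ax.set_xticks([])
            ax.set_yticks([])
            if i == 0:
                ax.set_title(band_names[j], fontsize=9)
            if j == 0:
                ax.set_ylabel(f"level {levels[i]}", fontsize=9)
            ax.set_aspect("equal")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
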