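"""Optional matplotlib rendering of meshes, fields and shape predictions."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import TriMesh
from .phantoms import Phantom

__all__ = ["plot_field", "plot_mask"]


def _tripcolor(ax, mesh: TriMesh, values: np.ndarray, **kw):
    import matplotlib.tri as mtri

    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.triangles)
    return ax.tripcolor(tri, facecolors=np.asarray(values, float), **kw)


def _outline(ax, phantom: Phantom | None):
    import matplotlib.patches as mpatches

    ax.add_patch(mpatches.Circle((0, 0), 1.0, fill=False, lw=1.0, color="k"))
    if phantom is not None:
        for c in phantom.circles:
            ax.add_patch(
                mpatches.Circle(c.center, c.radius, fill=False, lw=1.0, color="w")
            )
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")


def plot_field(
    mesh: TriMesh,
    sigma: np.ndarray,
    path: str | Path | None = None,
    phantom: Phantom | None = None,
    title: str = "",
):
    """Render a per-triangle conductivity field; returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    pc = _tripcolor(ax, mesh, sigma, cmap="viridis")
    fig.colorbar(pc, ax=ax, shrink=0.8)
    _outline(ax, phantom)
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_mask(
    mesh: TriMesh,
    mask: np.ndarray,
    path: str | Path | None = None,
    phantom: Phantom | None = None,
    title: str = "",
):
    """Render a boolean per-triangle anomaly mask over the phantom outline."""
    return plot_field(
        mesh, np.asarray(mask, float), path=path, phantom=phantom, title=title
    )
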