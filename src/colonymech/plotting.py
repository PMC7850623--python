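"""Static plots for runs and shear decompositions (matplotlib)."""

from __future__ import annotations

import numpy as np

from .kinematics import ShearDecomposition, project_xx


def plot_shear_decomposition(
    dec: ShearDecomposition, axis_angle: float = 0.0, ax=None
):
    """Cumulative pure-shear channels vs time along a reference axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    t = dec.cumulative["time"]
    for ch, style in [
        ("total", dict(color="k", lw=2)),
        ("elongation", dict(color="tab:green")),
        ("t1", dict(color="tab:red")),
        ("division", dict(color="tab:blue")),
        ("extrusion", dict(color="tab:purple")),
        ("correlation", dict(color="tab:gray", ls="--")),
    ]:
        vals = [
            project_xx(xx, xy, axis_angle)
            for xx, xy in zip(dec.cumulative[f"{ch}_xx"], dec.cumulative[f"{ch}_xy"])
        ]
        ax.plot(t, vals, label=ch, **style)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.set_xlabel("time")
    ax.set_ylabel("cumulative pure shear (xx)")
    ax.legend(fontsize=8, frameon=False)
    return ax


def plot_colony(vertices: np.ndarray, cells: list, polarity=None, ax=None):
    """Cell polygons (and optionally polarity directors) of one snapshot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    for loop in cells:
        if len(loop) < 3:
            continue
        pts = vertices[loop]
        ax.fill(pts[:, 0], pts[:, 1], ec="k", fc="wheat", lw=0.5, alpha=0.9)
    if polarity is not None:
        angles = getattr(polarity, "angles", polarity)
        centroids = []
        for loop in cells:
            centroids.append(
                vertices[loop].mean(axis=0) if len(loop) >= 3 else [np.nan, np.nan]
            )
        centroids = np.asarray(centroids)
        u = 0.35 * np.cos(angles)
        v = 0.35 * np.sin(angles)
        ax.plot(
            np.stack([centroids[:, 0] - u, centroids[:, 0] + u]),
            np.stack([centroids[:, 1] - v, centroids[:, 1] + v]),
            color="tab:red",
            lw=1,
        )
    ax.set_aspect(1)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax
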