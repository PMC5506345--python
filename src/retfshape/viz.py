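"""Figure helpers: enface maps on triangulated surfaces and column plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .mesh import TriSurface


def plot_enface_map(
    surface: TriSurface,
    values: np.ndarray,
    path,
    title: str = "",
    cmap: str = "viridis",
    units: str = "mm",
    vmin: float | None = None,
    vmax: float | None = None,
) -> None:
    """Enface (x-y) view of a per-vertex field; right-eye orientation with
    nasal to the right, superior up."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    tpc = ax.tripcolor(
        surface.vertices[:, 0],
        surface.vertices[:, 1],
        surface.faces,
        np.asarray(values, dtype=float),
        shading="gouraud",
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    ax.set_aspect("equal")
    ax.set_xlabel("temporal ← x (mm) → nasal")
    ax.set_ylabel("inferior ← y (mm) → superior")
    ax.set_title(title)
    fig.colorbar(tpc, ax=ax, label=units)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_columns(
    values: np.ndarray,
    row_perm: np.ndarray,
    col_perm: np.ndarray,
    col_key: np.ndarray,
    path,
    title: str = "",
    key_label: str = "",
    cmap: str = "viridis",
) -> None:
    """Multi-subject column plot: one column per eye (ordered by the key,
    shown in grayscale below), rows = template points ordered by sector and
    BMO-center distance."""
    v = np.asarray(values, dtype=float)[np.ix_(row_perm, col_perm)]
    key = np.asarray(col_key, dtype=float)[col_perm]
    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(6, 6), height_ratios=[12, 1], sharex=True
    )
    im = ax0.imshow(v, aspect="auto", interpolation="nearest", cmap=cmap)
    ax0.set_ylabel("template points (N → IN, inner → outer)")
    ax0.set_title(title)
    fig.colorbar(im, ax=ax0)
    ax1.imshow(key[None, :], aspect="auto", cmap="gray", interpolation="nearest")
    ax1.set_yticks([])
    ax1.set_xlabel(f"eyes ordered by {key_label}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
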