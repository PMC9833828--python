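"""Synthetic fixtures with known ground truth.

Three generators, all deterministic under a fixed seed and all emitting
ground truth next to the data:

* ellipse grids — rasterized solid ellipses of prescribed aspect ratio, the
  measurement oracle for the gyration-tensor morphometrics (a uniform
  ellipse with semiaxes a >= b has principal radii of gyration a/2 and b/2,
  hence aspect ratio exactly a/b);
* periodic Voronoi masks — confluent label images for measurement and CPM
  initialization;
* model samples — i.i.d. draws of aspect ratio and scaled area from the
  analytic laws, the canonical input for parameter-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import distributions as dist
from .cpm import voronoi_labels

__all__ = ["ellipse_grid_mask", "voronoi_mask", "model_samples"]


def ellipse_grid_mask(
    aspect_ratios,
    semi_major: float = 40.0,
    pad: int = 6,
    n_cols: int | None = None,
    orientations=None,
    seed: int | None = None,
):
    """Grid of rasterized solid ellipses with prescribed aspect ratios.

    Each ellipse sits in its own grid box (background label 0); semi-minor
    axis is ``semi_major / r``.  Rasterization is by pixel-center inclusion.
    Returns ``(label_image, ground_truth)`` where the ground-truth frame has
    the prescribed r, semiaxes and orientation per cell id.

    ``orientations`` may be an array of angles in radians, ``"random"``
    (drawn with ``seed``), or None for axis-aligned ellipses.
    """
    r = np.atleast_1d(np.asarray(aspect_ratios, dtype=float))
    if np.any(r < 1):
        raise ValueError("prescribed aspect ratios must be >= 1")
    if semi_major <= 0:
        raise ValueError("semi_major must be positive")
    n = r.size
    box = int(np.ceil(2 * semi_major)) + 2 * int(pad) + 1
    if 2 * semi_major >= box:
        raise ValueError("ellipses do not fit their grid boxes; increase pad")
    if orientations is None:
        theta = np.zeros(n)
    elif isinstance(orientations, str) and orientations == "random":
        theta = np.random.default_rng(seed).uniform(0, np.pi, n)
    else:
        theta = np.broadcast_to(np.asarray(orientations, dtype=float), (n,)).copy()

    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    img = np.zeros((n_rows * box, n_cols * box), dtype=np.int32)
    yy, xx = np.mgrid[0:box, 0:box]
    cy = cx = (box - 1) / 2.0
    truth = []
    for i in range(n):
        gi, gj = divmod(i, n_cols)
        a, b = semi_major, semi_major / r[i]
        ct, st = np.cos(theta[i]), np.sin(theta[i])
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        tile = img[gi * box:(gi + 1) * box, gj * box:(gj + 1) * box]
        tile[inside] = i + 1
        truth.append(
            {"cell_id": i + 1, "aspect_ratio": r[i], "semi_major": a,
             "semi_minor": b, "orientation": theta[i]}
        )
    return img, pd.DataFrame(truth)


def voronoi_mask(n_seeds: int, size: tuple[int, int], seed: int) -> np.ndarray:
    """Confluent nearest-seed tessellation under the periodic (torus) metric."""
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds")
    rows, cols = int(size[0]), int(size[1])
    rng = np.random.default_rng(seed)
    return voronoi_labels(rows, cols, n_seeds, rng, "square").astype(np.int32)


def model_samples(alpha: float, mu: float, n_cells: int, seed: int) -> pd.DataFrame:
    """Independent per-cell draws of aspect ratio r and scaled area a.

    r follows the analytic aspect-ratio law at ``alpha``; a follows the
    unit-mean Gamma law at ``mu``.  Columns: cell_id, aspect_ratio, area.
    """
    rng = np.random.default_rng(seed)
    r = dist.sample_r(alpha, n_cells, rng)
    a = dist.ScaledAreaDistribution(mu).rvs(n_cells, rng)
    return pd.DataFrame(
        {"cell_id": np.arange(1, n_cells + 1), "aspect_ratio": r, "area": a}
    )
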