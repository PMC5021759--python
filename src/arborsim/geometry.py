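"""Soma-centered geometry: physical distance maps and annulus binning.

All morphometry in this package is binned into concentric shells
("annuli") of width 6.25 um around the soma center.  Annulus 0 contains
the soma; annulus k covers physical distances [k*6.25, (k+1)*6.25).
Nine annuli are carried everywhere, matching the nine morphological
regions of the compartmental models.
"""

from __future__ import annotations

import numpy as np

#: Width of one concentric shell around the soma center, in micrometers.
ANNULUS_WIDTH_UM = 6.25

#: Number of annuli carried in every profile (annulus 0 = soma).
N_ANNULI = 9


class GeometryError(ValueError):
    """Raised when coordinates, grids or masks are geometrically inconsistent."""


def distance_map(shape, center_um, voxel_size):
    """Physical Euclidean distance of every voxel center from a reference point.

    Parameters
    ----------
    shape : tuple of int
        Grid shape, (nz, ny, nx).
    center_um : sequence of float
        Reference point in physical coordinates (z, y, x), micrometers.
    voxel_size : sequence of float
        Voxel edge lengths (dz, dy, dx) in micrometers.

    Returns
    -------
    ndarray of float32, same shape, distances in micrometers.
    """
    center_um = np.asarray(center_um, dtype=float)
    voxel_size = np.asarray(voxel_size, dtype=float)
    if np.any(voxel_size <= 0):
        raise GeometryError("voxel_size must be strictly positive")
    if len(shape) != 3:
        raise GeometryError("expected a 3D grid")
    axes = [
        (np.arange(n, dtype=np.float64) * dv - c) ** 2
        for n, dv, c in zip(shape, voxel_size, center_um)
    ]
    d2 = (
        axes[0][:, None, None]
        + axes[1][None, :, None]
        + axes[2][None, None, :]
    )
    return np.sqrt(d2, dtype=np.float64).astype(np.float32)


def annulus_index(dist_um, width_um=ANNULUS_WIDTH_UM, n_annuli=N_ANNULI, clip=True):
    """Map distances to annulus indices with half-open intervals [k*w, (k+1)*w).

    Distances beyond the outermost annulus are clipped into the last
    annulus when ``clip`` is true (the models carry nine regions; anything
    farther out is attributed to the outermost region).
    """
    k = np.floor(np.asarray(dist_um, dtype=float) / width_um).astype(int)
    if clip:
        k = np.clip(k, 0, n_annuli - 1)
    return k


def voxel_to_um(index_zyx, voxel_size):
    """Physical (z, y, x) position of a voxel center in micrometers."""
    return np.asarray(index_zyx, dtype=float) * np.asarray(voxel_size, dtype=float)


def um_to_voxel(pos_um, voxel_size):
    """Nearest voxel index for a physical (z, y, x) position."""
    return np.round(
        np.asarray(pos_um, dtype=float) / np.asarray(voxel_size, dtype=float)
    ).astype(int)
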