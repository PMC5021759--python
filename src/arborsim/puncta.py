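"""Synaptic-puncta detection, object-based colocalization and measurement.

Punctae (compact presynaptic-marker clusters, one per terminal) are
segmented intensity-independently: a LoG sharpens puncta boundaries,
local maxima of the transform seed a watershed-constrained region
growing over the positive-LoG support, and each resulting 3D mask is
one punctum.  A punctum is assigned to the dye-filled neuron if its
mask shares at least one voxel with the neuron mask.  Intensities are
measured on the raw (pre-filter) image and normalized to the mean over
control-neuron punctae of the same channel and imaging session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.segmentation import watershed

from .geometry import GeometryError
from .segmentation import STRUCT_26, NeuronMask, inverted_log
from .volume import VolumeImage


class NormalizationError(RuntimeError):
    """Raised when intensity normalization has no control punctae to use."""


@dataclass
class PunctaSet:
    """Labeled puncta masks plus a per-punctum measurement table.

    ``labels`` holds one positive integer id per punctum mask (0 =
    background).  ``table`` has one row per punctum; columns are grown
    by the measurement steps: id, channel, n_voxels, z_um/y_um/x_um
    (centroid), then raw_mean, dist_um, colocalized, afu.
    """

    labels: np.ndarray
    table: pd.DataFrame
    voxel_size: tuple
    channel: str = ""
    control_mean: float = np.nan

    def __len__(self):
        return len(self.table)


def _ellipsoid_footprint(r_xy=2, r_z=1):
    """Boolean ellipsoid footprint (2*r_z+1, 2*r_xy+1, 2*r_xy+1)."""
    zz, yy, xx = np.mgrid[-r_z : r_z + 1, -r_xy : r_xy + 1, -r_xy : r_xy + 1]
    return (zz / r_z) ** 2 + (yy / r_xy) ** 2 + (xx / r_xy) ** 2 <= 1.0


def detect_puncta(channel_img: VolumeImage, max_r_xy=2, max_r_z=1, min_size=1,
                  noise_floor_sds=5.0):
    """Detect punctae on one marker channel.

    LoG (radius 1 voxel) -> local maxima within an ellipsoidal
    neighborhood (xy radius ``max_r_xy`` px, z radius ``max_r_z``
    voxel; 500 nm x 500 nm x 1 um at the default acquisition geometry)
    -> maxima seed a watershed over the LoG landscape, which grows each
    seed while preventing merges between nearby seeds.  Growth and
    seeding are restricted to the positive LoG support above a robust
    noise floor (``noise_floor_sds`` MAD-estimated SDs of the
    transform), so a noise-only stack yields no punctae.  Plateau
    maxima are collapsed to their lexicographically first voxel so
    seeding is deterministic.
    """
    log3 = inverted_log(channel_img.voxels, sigma=1.0)
    mad_sd = float(np.median(np.abs(log3 - np.median(log3)))) / 0.6745
    floor = max(0.0, noise_floor_sds * mad_sd)
    fp = _ellipsoid_footprint(max_r_xy, max_r_z)
    maxf = ndi.maximum_filter(log3, footprint=fp, mode="nearest")
    peaks = (log3 >= maxf) & (log3 > floor)
    # collapse plateaus deterministically: first voxel in scan order per plateau
    plat_labels, n_peaks = ndi.label(peaks, structure=STRUCT_26)
    markers = np.zeros(log3.shape, dtype=np.int32)
    if n_peaks:
        first = np.zeros(n_peaks + 1, dtype=np.int64)
        flat = plat_labels.ravel()
        nz = np.flatnonzero(flat)
        # nz is in scan (lexicographic) order; keep the first per label
        seen = np.zeros(n_peaks + 1, dtype=bool)
        for pos in nz:
            lab = flat[pos]
            if not seen[lab]:
                seen[lab] = True
                first[lab] = pos
        coords = np.unravel_index(first[1:], log3.shape)
        markers[coords] = np.arange(1, n_peaks + 1)
    labels = watershed(-log3, markers=markers, mask=log3 > floor,
                       connectivity=np.ones((3, 3, 3)))
    ids = np.arange(1, n_peaks + 1)
    if n_peaks:
        sizes = ndi.sum_labels(labels > 0, labels, index=ids)
        keep = sizes >= min_size
        if not keep.all():
            remove = ids[~keep]
            labels[np.isin(labels, remove)] = 0
            ids = ids[keep]
            sizes = sizes[keep]
    else:
        sizes = np.empty(0)
    vs = np.asarray(channel_img.voxel_size, dtype=float)
    if len(ids):
        cz, cy, cx = zip(*ndi.center_of_mass(labels > 0, labels, index=ids))
        table = pd.DataFrame(
            {
                "id": ids,
                "channel": channel_img.channel,
                "n_voxels": np.asarray(sizes, dtype=int),
                "z_um": np.asarray(cz) * vs[0],
                "y_um": np.asarray(cy) * vs[1],
                "x_um": np.asarray(cx) * vs[2],
            }
        )
    else:
        table = pd.DataFrame(
            columns=["id", "channel", "n_voxels", "z_um", "y_um", "x_um"]
        )
    return PunctaSet(labels=labels, table=table,
                     voxel_size=channel_img.voxel_size, channel=channel_img.channel)


def colocalize(punctae: PunctaSet, neuron: NeuronMask):
    """Flag punctae sharing >= 1 voxel with the neuron mask.

    Idempotent; monotone in the mask (a larger mask can only add flags).
    """
    if punctae.labels.shape != neuron.mask.shape:
        raise GeometryError("puncta labels and neuron mask grids differ")
    on = np.unique(punctae.labels[neuron.mask & (punctae.labels > 0)])
    punctae.table["colocalized"] = punctae.table["id"].isin(on).to_numpy()
    return punctae


def measure(punctae: PunctaSet, raw: VolumeImage, dmap):
    """Mean raw intensity and soma distance per punctum.

    Intensity is redirected to the original unprocessed image; the soma
    distance of a punctum is the mean of the distance map over its mask
    (the mask-average distance from the soma center).
    """
    if raw.voxels.shape != punctae.labels.shape or dmap.shape != punctae.labels.shape:
        raise GeometryError("raw image / distance map grid mismatch")
    ids = punctae.table["id"].to_numpy()
    if len(ids):
        punctae.table["raw_mean"] = ndi.mean(
            raw.voxels.astype(np.float64), punctae.labels, index=ids
        )
        punctae.table["dist_um"] = ndi.mean(
            np.asarray(dmap, dtype=np.float64), punctae.labels, index=ids
        )
    else:
        punctae.table["raw_mean"] = np.empty(0)
        punctae.table["dist_um"] = np.empty(0)
    return punctae


def normalize_intensities(table: pd.DataFrame, control_ids, neuron_col="neuron",
                          session_col="session"):
    """Add an ``afu`` column: raw mean over the session's control mean.

    ``table`` is a concatenated per-punctum table across neurons of one
    or more imaging sessions, with columns ``raw_mean``, ``channel``,
    ``neuron`` and ``session``.  For each (session, channel) cell the
    control mean is the average raw intensity over all punctae belonging
    to control neurons; every punctum's AFU is its raw mean divided by
    that control mean, making the control-group session mean 1 AFU by
    construction.
    """
    control_ids = set(control_ids)
    table = table.copy()
    afu = np.full(len(table), np.nan)
    for (_, _), idx in table.groupby([session_col, "channel"]).groups.items():
        sub = table.loc[idx]
        ctrl = sub[sub[neuron_col].isin(control_ids)]
        if len(ctrl) == 0:
            raise NormalizationError(
                "no control-neuron punctae in session for normalization"
            )
        afu[table.index.get_indexer(idx)] = (
            sub["raw_mean"] / ctrl["raw_mean"].mean()
        ).to_numpy()
    table["afu"] = afu
    return table
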