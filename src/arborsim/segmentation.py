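"""Neuron-fill segmentation, skeletonization, Sholl analysis and the
soma-centered distance map.

The segmentation stream mirrors an intensity-independent LoG workflow:
the dye-fill channel is convolved with a Laplacian of Gaussian, the
transform is thresholded at mode + SD/10 of its maximum-Z projection,
and the largest 26-connected 3D component (soma plus all continuous
dendrites) is retained.  The LoG is applied with the sign convention
that bright structures map to positive values.

Sholl crossings are counted on the 3D skeleton of the mask: a crossing
at radius k*6.25 um is one connected group of skeleton voxels that
straddles the sphere of that radius.  Skeleton length is summed from
the physical step lengths of the skeleton's spanning tree, binned by
the annulus of each step's midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.morphology import skeletonize

from .geometry import (
    ANNULUS_WIDTH_UM,
    N_ANNULI,
    GeometryError,
    annulus_index,
    distance_map,
)
from .thresholds import mode_sd_threshold, renyi_threshold
from .volume import VolumeImage

#: 26-connectivity structuring element for 3D labeling.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Raised when a stream produces an empty result (no neuron / no soma)."""


@dataclass
class NeuronMask:
    """Binary mask of the retained (largest) connected neuron component."""

    mask: np.ndarray
    voxel_size: tuple
    n_components_before: int = 1

    @property
    def volume_um3(self):
        dz, dy, dx = self.voxel_size
        return float(self.mask.sum()) * dz * dy * dx


@dataclass
class SomaReference:
    """Physical soma-center coordinate (z, y, x) in micrometers."""

    center_um: np.ndarray


@dataclass
class ShollResult:
    """Per-annulus skeleton length and Sholl crossings.

    ``length_um[k]`` sums skeleton step lengths whose midpoints fall in
    annulus k; ``crossings[k]`` counts distinct skeleton branches
    intersecting the sphere of radius k*6.25 um (k >= 1; annulus 0 is
    the soma and has no crossing count).
    """

    length_um: np.ndarray
    crossings: np.ndarray
    skeleton: np.ndarray


def inverted_log(stack, sigma):
    """Laplacian-of-Gaussian with bright structures positive.

    ``sigma`` is per-axis in voxels, interpreted from the "radius" of an
    ImageJ-style LoG (radius 1 voxel -> sigma 1 voxel per axis).
    """
    return -ndi.gaussian_laplace(np.asarray(stack, dtype=np.float32), sigma=sigma)


def segment_neuron(gfp: VolumeImage, exclusion_mask=None, sd_fraction=0.1):
    """Segment the dye-filled neuron and keep the largest 3D component.

    Pipeline: LoG (radius 1 voxel) -> max-Z projection of the transform
    -> threshold = mode + ``sd_fraction`` * SD of the projection ->
    binarize the full 3D transform at that threshold -> remove voxels
    under the optional exclusion mask -> retain the largest 26-connected
    component.

    Raises
    ------
    SegmentationError
        If no foreground survives the threshold.
    GeometryError
        If the exclusion mask shape mismatches.
    """
    log3 = inverted_log(gfp.voxels, sigma=1.0)
    proj = log3.max(axis=0)
    thr = mode_sd_threshold(proj, sd_fraction=sd_fraction)
    fg = log3 > thr
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != fg.shape:
            raise GeometryError("exclusion mask shape mismatch")
        fg &= ~exclusion_mask
    labels, n = ndi.label(fg, structure=STRUCT_26)
    if n == 0:
        raise SegmentationError("no neuron found: empty foreground after threshold")
    sizes = ndi.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    kept = labels == keep
    # the LoG is ~zero inside large uniform blobs (flat plateau), which
    # hollows out the soma; close those cavities
    kept = ndi.binary_fill_holes(kept)
    return NeuronMask(mask=kept, voxel_size=gfp.voxel_size,
                      n_components_before=int(n))


def locate_soma_center(gfp: VolumeImage, saturation=0.004, heavy_sigma_xy=10.0,
                       heavy_sigma_z=1.0, alpha=2.0, refine_mask=None,
                       refine_radius_um=8.0):
    """Locate the soma center via the heavy-LoG / Renyi-entropy stream.

    Chain: saturate ``saturation`` of the intensity range (split between
    tails) and rescale to 8-bit -> heavy LoG (xy radius 10 px, z radius
    1 voxel) -> max-Z projection -> Renyi-entropy threshold on the
    256-bin histogram -> largest 2D component -> center of mass of that
    object.  Mass is the z-summed saturated intensity over the object's
    footprint: the soma spans many z planes while dendrites occupy one
    or two, so the z-projection mass concentrates at the soma.  The z
    coordinate, which a projection cannot provide, is the
    intensity-weighted mean z over the footprint columns.

    When ``refine_mask`` (a :class:`NeuronMask` or boolean grid) is
    given, the projection estimate seeds an iterated local 3D center of
    mass over mask voxels within ``refine_radius_um``, sharpening the
    reference point to sub-voxel accuracy on the fill object.
    """
    raw = np.asarray(gfp.voxels, dtype=np.float64)
    lo, hi = np.percentile(raw, [100 * saturation / 2, 100 * (1 - saturation / 2)])
    if hi <= lo:
        raise SegmentationError("no soma: image has no dynamic range")
    sat8 = np.clip((raw - lo) / (hi - lo) * 255.0, 0, 255)
    heavy = inverted_log(sat8, sigma=(heavy_sigma_z, heavy_sigma_xy, heavy_sigma_xy))
    proj = heavy.max(axis=0)
    # Rescale the projection to 8-bit for the entropy threshold.
    pmin, pmax = proj.min(), proj.max()
    if pmax <= pmin:
        raise SegmentationError("no soma: flat heavy-LoG projection")
    p8 = np.clip((proj - pmin) / (pmax - pmin) * 255.0, 0, 255).astype(np.uint8)
    hist = np.bincount(p8.ravel(), minlength=256)
    t = renyi_threshold(hist, alpha=alpha)
    bw = p8 > t
    labels, n = ndi.label(bw)
    if n == 0:
        raise SegmentationError("no soma: empty threshold result")
    zsum = sat8.sum(axis=0)  # z-projected mass per column
    # most massive object: integrated fluorescence, not footprint area
    masses = ndi.sum_labels(zsum, labels, index=np.arange(1, n + 1))
    comp = labels == (int(np.argmax(masses)) + 1)
    yy, xx = np.nonzero(comp)
    w = zsum[yy, xx]
    wsum = w.sum()
    cy = float((yy * w).sum() / wsum)
    cx = float((xx * w).sum() / wsum)
    # z: intensity-weighted over the footprint columns
    col = sat8[:, yy, xx]
    zw = col.sum(axis=1)
    cz = float((np.arange(raw.shape[0]) * zw).sum() / zw.sum())
    dz, dy, dx = gfp.voxel_size
    center = np.array([cz * dz, cy * dy, cx * dx])
    if refine_mask is not None:
        m = refine_mask.mask if isinstance(refine_mask, NeuronMask) else refine_mask
        coords = np.argwhere(m) * np.asarray(gfp.voxel_size)
        for _ in range(5):
            sel = np.linalg.norm(coords - center, axis=1) < refine_radius_um
            if not sel.any():
                break
            center = coords[sel].mean(axis=0)
    return SomaReference(center_um=center)


def distance_transform(soma: SomaReference, shape, voxel_size):
    """Physical Euclidean distance of every voxel from the soma center."""
    center = np.asarray(soma.center_um, dtype=float)
    extent = (np.asarray(shape) - 1) * np.asarray(voxel_size, dtype=float)
    if np.any(center < 0) or np.any(center > extent):
        raise GeometryError("soma center lies outside the grid")
    return distance_map(shape, center, voxel_size)


# ---------------------------------------------------------------------------
# Skeleton + Sholl

def _half_offsets():
    """The 13 'positive' 26-neighborhood offsets (each undirected pair once)."""
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) > (0, 0, 0) or (
                    dz == 0 and ((dy, dx) > (0, 0) or (dy == 0 and dx > 0))
                ):
                    if (dz, dy, dx) != (0, 0, 0):
                        offs.append((dz, dy, dx))
    # keep exactly one of each +/- pair
    uniq = []
    seen = set()
    for o in offs:
        if tuple(-c for c in o) not in seen:
            seen.add(o)
            uniq.append(o)
    return np.array(uniq, dtype=int)


OFFSETS_HALF = _half_offsets()
assert len(OFFSETS_HALF) == 13


def _skeleton_edges(skel, voxel_size):
    """Undirected 26-adjacency edges between skeleton voxels.

    Returns (ids volume, coords (n,3), edges (m,2) int, lengths (m,) um).
    """
    coords = np.argwhere(skel)
    ids = -np.ones(skel.shape, dtype=np.int64)
    ids[tuple(coords.T)] = np.arange(len(coords))
    voxel_size = np.asarray(voxel_size, dtype=float)
    e_a, e_b, e_len = [], [], []
    for off in OFFSETS_HALF:
        nbr = coords + off
        ok = np.all((nbr >= 0) & (nbr < skel.shape), axis=1)
        if not ok.any():
            continue
        a = ids[tuple(coords[ok].T)]
        b = ids[tuple(nbr[ok].T)]
        hit = b >= 0
        if not hit.any():
            continue
        e_a.append(a[hit])
        e_b.append(b[hit])
        e_len.append(np.full(hit.sum(), np.linalg.norm(off * voxel_size)))
    if not e_a:
        return ids, coords, np.empty((0, 2), int), np.empty(0)
    return (
        ids,
        coords,
        np.stack([np.concatenate(e_a), np.concatenate(e_b)], axis=1),
        np.concatenate(e_len),
    )


def skeletonize_and_sholl(neuron: NeuronMask, soma: SomaReference,
                          shell_width_um=ANNULUS_WIDTH_UM, n_annuli=N_ANNULI):
    """3D medial-axis thinning followed by annulus-binned length and crossings.

    Length per annulus sums the physical lengths of the skeleton's
    minimum-spanning-tree steps (anisotropy-aware 26-connectivity),
    assigned by the midpoint distance of each step.  Crossings at radius
    k*shell_width are counted as 26-connected clusters of skeleton
    voxels lying inside the sphere with at least one skeleton neighbor
    on or outside it.
    """
    mask = neuron.mask
    center = np.asarray(soma.center_um, dtype=float)
    vs = np.asarray(neuron.voxel_size, dtype=float)
    cvox = np.round(center / vs).astype(int)
    cvox = np.clip(cvox, 0, np.asarray(mask.shape) - 1)
    if not mask[tuple(cvox)]:
        # a center of mass can fall just outside an irregular object;
        # accept it if the mask is within a couple of micrometers
        mc = np.argwhere(mask)
        d = np.linalg.norm((mc - cvox) * vs, axis=1)
        if d.min() > 3.0:
            raise GeometryError("soma center does not lie inside the neuron mask")

    skel = skeletonize(mask)
    if not skel.any():  # degenerate tiny mask; treat the center voxel as skeleton
        skel = np.zeros_like(mask)
        skel[tuple(cvox)] = True

    ids, coords, edges, lengths = _skeleton_edges(skel, vs)
    dists = np.linalg.norm(coords * vs - center, axis=1)

    length_um = np.zeros(n_annuli)
    crossings = np.zeros(n_annuli, dtype=int)
    if len(edges):
        # spanning tree removes redundant diagonal/orthogonal duplicate steps
        n = len(coords)
        g = coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
        mst = minimum_spanning_tree(g).tocoo()
        mid = 0.5 * (dists[mst.row] + dists[mst.col])
        k = annulus_index(mid, shell_width_um, n_annuli)
        np.add.at(length_um, k, mst.data)
        # a crossing = one tree step straddling the sphere; each skeleton
        # branch path contributes its own step even when branches touch
        da, db = dists[mst.row], dists[mst.col]
        for k in range(1, n_annuli):
            r = k * shell_width_um
            crossings[k] = int(((da < r) != (db < r)).sum())
    return ShollResult(length_um=length_um, crossings=crossings, skeleton=skel)
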