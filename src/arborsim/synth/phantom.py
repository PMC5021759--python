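"""Phantom fluorescence stacks with voxel-level ground truth.

The phantom emulates the acquisition geometry of the fixed-cell imaging
this pipeline targets (0.25 um xy pixels, 1 um z step, 16-bit, three
channels: cell fill plus excitatory and inhibitory presynaptic
markers).  A neuron is a spherical soma plus a radial branch tree of
constant-radius tubes (0.5 um) blurred by a Gaussian PSF (sigma 1 px in
xy, 0.5 voxel in z); punctae are 3D Gaussians whose integrated
intensity is proportional to a specified normalized-intensity value.
Noise is additive Gaussian on a constant 16-bit offset, the simplest
model under which mode+SD thresholding is well defined.

Branch trees are synthesized to hit a per-annulus Sholl-crossing
profile exactly, with short tangential twigs (which add length but
never cross an annulus boundary) making dendrite length controllable
independently of crossings.  Ground truth (per-annulus path length,
crossings, puncta records, the rendered tube voxel set) is computed
from the polyline geometry, not from the rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from ..geometry import ANNULUS_WIDTH_UM, N_ANNULI, GeometryError, annulus_index
from ..volume import DEFAULT_VOXEL_SIZE, VolumeImage

TUBE_RADIUS_UM = 0.5
PSF_SIGMA_VOX = (0.5, 1.0, 1.0)  # (z, y, x)


@dataclass
class PhantomSpec:
    """Full description of one phantom field of view.

    ``branches`` are polylines in physical (z, y, x) um coordinates;
    ``puncta`` is a frame with columns z_um, y_um, x_um, channel
    ("VGlut1" | "VGAT"), afu (normalized intensity driving rendered
    brightness) and on_neuron.
    """

    shape: tuple
    soma_center_um: np.ndarray
    soma_radius_um: float = 5.0
    branches: list = field(default_factory=list)
    puncta: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["z_um", "y_um", "x_um", "channel", "afu", "on_neuron"]
        )
    )
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    noise_sd: float = 20.0
    offset: float = 100.0
    fill_amplitude: float = 4000.0
    puncta_gain: float = 3000.0
    seed: int = 0

    def validate(self):
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel_size must be strictly positive")
        extent = (np.asarray(self.shape) - 1) * np.asarray(self.voxel_size)
        for br in self.branches:
            br = np.asarray(br, dtype=float)
            if np.any(br < 0) or np.any(br > extent):
                raise GeometryError("branch path exits the volume")
        if self.offset + self.fill_amplitude > 65535:
            raise GeometryError("rendered intensities exceed 16-bit range")
        return self


@dataclass
class GroundTruth:
    """Geometric truth accompanying a rendered phantom."""

    length_um: np.ndarray          # per annulus, from polyline geometry
    crossings: np.ndarray          # per annulus (index k: sphere k*6.25)
    tube_voxels: np.ndarray        # bool, rendered neuron support (pre-blur)
    puncta: pd.DataFrame           # truth records incl. dist_um

    @property
    def total_length_um(self):
        return float(self.length_um[1:].sum())


# ---------------------------------------------------------------------------
# branch-tree synthesis


def _unit(v):
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _radial_dir(p, center):
    return _unit(np.asarray(p) - np.asarray(center))


def _extend_to_radius(p, direction, center, r_target, step=0.5, z_span=3.0):
    """March from ``p`` along ``direction`` (with its z drift clamped to
    +/- ``z_span`` of the center plane) until 3D radius >= r_target.
    Returns the polyline points appended (excluding ``p``)."""
    pts = []
    p = np.asarray(p, dtype=float).copy()
    d = _unit(np.asarray(direction, dtype=float))
    guard = 0
    while np.linalg.norm(p - center) < r_target:
        p = p + d * step
        if abs(p[0] - center[0]) > z_span:
            d = d.copy()
            d[0] = -0.2 * np.sign(p[0] - center[0])
            d = _unit(d)
        pts.append(p.copy())
        guard += 1
        if guard > 10000:
            raise GeometryError("branch extension failed to reach target radius")
    return pts


def _rotate_xy(d, angle):
    """Rotate a direction about the z axis (arrays are (z, y, x))."""
    c, s = np.cos(angle), np.sin(angle)
    z, y, x = d
    return np.array([z, c * y - s * x, s * y + c * x])


def sample_branch_tree(rng, crossings_target, soma_center_um, soma_radius_um,
                       twig_budget_um=None, jitter_deg=12.0, z_span=3.0):
    """Synthesize radial branch polylines matching a crossings profile.

    ``crossings_target[k]`` (k >= 1) branches must cross the sphere of
    radius k*6.25 um.  Branches start on the soma surface, march
    outward with small azimuthal jitter, bifurcate when the next
    annulus needs more paths and terminate just inside a boundary when
    it needs fewer.  ``twig_budget_um[k]`` of tangential twig length is
    added inside annulus k without crossing its boundaries.
    """
    W = ANNULUS_WIDTH_UM
    center = np.asarray(soma_center_um, dtype=float)
    target = np.asarray(crossings_target, dtype=int)
    eps = 2.0  # stop/spawn margin inside a boundary, um; bifurcating this
    # far before a sphere lets sibling tubes separate beyond the PSF
    # before they cross it, so each child is resolvable as its own crossing
    branches = []

    n1 = int(target[1]) if len(target) > 1 else 0
    if n1 == 0:
        tips = []
    else:
        az0 = rng.uniform(0, 2 * np.pi)
        tips = []
        for j in range(n1):
            az = az0 + 2 * np.pi * j / n1 + rng.normal(0, 0.15)
            d = np.array([rng.normal(0, 0.08), np.cos(az), np.sin(az)])
            p = center + _unit(d) * soma_radius_um
            tips.append({"pts": [p.copy()], "dir": _unit(d)})

    for k in range(1, N_ANNULI):
        n_k = int(target[k])
        if n_k == 0:
            for t in tips:
                branches.append(np.asarray(t["pts"]))
            tips = []
            if target[k:].sum() > 0:
                raise GeometryError("orphan annulus: crossings after a gap")
            break
        # adjust path count entering annulus k
        while len(tips) > n_k:
            t = tips.pop(int(rng.integers(len(tips))))
            branches.append(np.asarray(t["pts"]))
        while 0 < len(tips) < n_k:
            src = tips[int(rng.integers(len(tips)))]
            ang = np.deg2rad(40 + 25 * rng.random()) * rng.choice([-1, 1])
            # the child keeps its divergence through the annulus it is
            # born in, so siblings separate beyond the PSF before and
            # while crossing the sphere
            tips.append(
                {"pts": [np.asarray(src["pts"][-1]).copy()],
                 "dir": _unit(_rotate_xy(src["dir"], ang)),
                 "offset": ang}
            )
        if not tips:
            if target[k:].sum() > 0:
                raise GeometryError("orphan annulus: no parent paths available")
            break
        r_exit = (k + 1) * W - eps
        for t in tips:
            ang = t.pop("offset", None)
            if ang is None:
                ang = np.deg2rad(rng.normal(0, jitter_deg))
            d = _unit(_rotate_xy(_radial_dir(t["pts"][-1], center), ang))
            d[0] += rng.normal(0, 0.05)
            d = _unit(d)
            t["dir"] = d
            t["pts"].extend(
                _extend_to_radius(t["pts"][-1], d, center, r_exit, z_span=z_span)
            )
    for t in tips:
        branches.append(np.asarray(t["pts"]))

    if twig_budget_um is not None:
        branches = add_twigs(rng, branches, center, twig_budget_um)
    return branches


def add_twigs(rng, branches, soma_center_um, twig_budget_um):
    """Append short tangential twigs to an existing tree.

    Twigs add dendrite length inside one annulus without ever crossing
    an annulus boundary, decoupling total length from Sholl crossings.
    ``twig_budget_um[k]`` um of twig length is placed in annulus k.
    """
    W = ANNULUS_WIDTH_UM
    center = np.asarray(soma_center_um, dtype=float)
    out = [np.asarray(b, dtype=float) for b in branches]
    eps = 0.4
    for k in range(1, N_ANNULI):
        budget = float(twig_budget_um[k])
        tries = 0
        while budget > 0.75 and tries < 400:
            tries += 1
            host = out[int(rng.integers(len(out)))]
            radii = np.linalg.norm(host - center, axis=1)
            ok = (radii > k * W + 1.0) & (radii < (k + 1) * W - 1.5)
            idx = np.flatnonzero(ok)
            if len(idx) == 0:
                continue
            p = host[int(rng.choice(idx))]
            radial = _radial_dir(p, center)
            tang = _unit(np.cross(radial, np.array([1.0, 0.0, 0.0])))
            if np.linalg.norm(tang) == 0:
                continue
            tang = _unit(_rotate_xy(tang, np.pi * rng.integers(2)))
            length = min(budget, 2.0 + 2.5 * rng.random())
            npts = max(2, int(length / 0.5))
            ts = np.linspace(0, length, npts + 1)[1:]
            twig = p[None, :] + ts[:, None] * tang[None, :]
            tr = np.linalg.norm(twig - center, axis=1)
            if tr.min() <= k * W + eps or tr.max() >= (k + 1) * W - eps:
                continue
            out.append(np.vstack([p[None, :], twig]))
            budget -= length
    return out


# ---------------------------------------------------------------------------
# geometric ground truth


def branch_truth(branches, soma_center_um, resolution_um=0.1):
    """Per-annulus path length and sphere crossings from polylines."""
    W = ANNULUS_WIDTH_UM
    center = np.asarray(soma_center_um, dtype=float)
    length = np.zeros(N_ANNULI)
    crossings = np.zeros(N_ANNULI, dtype=int)
    for br in branches:
        br = np.asarray(br, dtype=float)
        if len(br) < 2:
            continue
        # resample finely for length binning
        seg = np.diff(br, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        for a, b, L in zip(br[:-1], br[1:], seglen):
            if L == 0:
                continue
            n = max(1, int(np.ceil(L / resolution_um)))
            ts = (np.arange(n) + 0.5) / n
            mids = a[None, :] + ts[:, None] * (b - a)[None, :]
            k = annulus_index(np.linalg.norm(mids - center, axis=1))
            np.add.at(length, k, L / n)
        radii = np.linalg.norm(br - center, axis=1)
        rmin, rmax = radii.min(), radii.max()
        for k in range(1, N_ANNULI):
            if rmin < k * W <= rmax:
                crossings[k] += 1
    return length, crossings


# ---------------------------------------------------------------------------
# rendering


def _stamp_tube(shape, voxel_size, points_um, radius_um=TUBE_RADIUS_UM):
    """Mark tube voxels along sampled path points (disc in xy, 1 slice in z)."""
    vs = np.asarray(voxel_size, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    if len(points_um) == 0:
        return mask
    r_px = int(np.ceil(radius_um / vs[2]))
    offs = [
        (0, dy, dx)
        for dy in range(-r_px, r_px + 1)
        for dx in range(-r_px, r_px + 1)
        if (dy * vs[1]) ** 2 + (dx * vs[2]) ** 2 <= radius_um**2 + 1e-9
    ]
    offs = np.asarray(offs, dtype=int)
    vox = np.round(np.asarray(points_um) / vs).astype(int)
    all_idx = (vox[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = np.all((all_idx >= 0) & (all_idx < np.asarray(shape)), axis=1)
    all_idx = all_idx[ok]
    mask[all_idx[:, 0], all_idx[:, 1], all_idx[:, 2]] = True
    return mask


def _soma_mask(shape, voxel_size, center_um, radius_um):
    vs = np.asarray(voxel_size, dtype=float)
    zz = (np.arange(shape[0]) * vs[0] - center_um[0]) ** 2
    yy = (np.arange(shape[1]) * vs[1] - center_um[1]) ** 2
    xx = (np.arange(shape[2]) * vs[2] - center_um[2]) ** 2
    d2 = zz[:, None, None] + yy[None, :, None] + xx[None, None, :]
    return d2 <= radius_um**2


def _sample_paths(branches, resolution_um=0.125):
    pts = []
    for br in branches:
        br = np.asarray(br, dtype=float)
        if len(br) == 1:
            pts.append(br)
            continue
        seg = np.diff(br, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        for a, b, L in zip(br[:-1], br[1:], seglen):
            n = max(1, int(np.ceil(L / resolution_um)))
            ts = np.linspace(0, 1, n + 1)[:-1]
            pts.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    return np.concatenate(pts, axis=0) if pts else np.empty((0, 3))


def generate_neuron_phantom(spec: PhantomSpec):
    """Render a phantom into (GFP, VGlut1, VGAT) stacks plus ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape, vs = tuple(spec.shape), spec.voxel_size

    tube = _stamp_tube(shape, vs, _sample_paths(spec.branches))
    tube |= _soma_mask(shape, vs, spec.soma_center_um, spec.soma_radius_um)

    gfp = ndi.gaussian_filter(tube.astype(np.float32), sigma=PSF_SIGMA_VOX)
    gfp = gfp * spec.fill_amplitude + spec.offset

    puncta = spec.puncta.reset_index(drop=True).copy()
    chans = {}
    for cname in ("VGlut1", "VGAT"):
        img = np.zeros(shape, dtype=np.float32)
        sub = puncta[puncta["channel"] == cname]
        for _, row in sub.iterrows():
            pos = np.array([row["z_um"], row["y_um"], row["x_um"]])
            vox = np.round(pos / np.asarray(vs)).astype(int)
            if np.any(vox < 0) or np.any(vox >= shape):
                raise GeometryError("punctum outside the volume")
            img[tuple(vox)] += float(row["afu"]) * spec.puncta_gain
        # gaussian_filter preserves the integral, so integrated intensity
        # stays proportional to the specified normalized intensity
        img = ndi.gaussian_filter(img, sigma=PSF_SIGMA_VOX)
        chans[cname] = img + spec.offset

    length, crossings = branch_truth(spec.branches, spec.soma_center_um)
    # soma interior contributes fill but no dendrite length

    if len(puncta):
        center = np.asarray(spec.soma_center_um, dtype=float)
        pos = puncta[["z_um", "y_um", "x_um"]].to_numpy(float)
        puncta["dist_um"] = np.linalg.norm(pos - center, axis=1)
        # verify the on-neuron invariant against the rendered support
        vox = np.round(pos / np.asarray(vs)).astype(int)
        on_rendered = tube[vox[:, 0], vox[:, 1], vox[:, 2]]
        puncta["on_rendered_neuron"] = on_rendered

    def finish(img):
        noisy = img + rng.normal(0.0, spec.noise_sd, size=shape)
        return np.clip(noisy, 0, 65535).astype(np.uint16)

    vols = {
        "GFP": VolumeImage(finish(gfp), vs, "GFP"),
        "VGlut1": VolumeImage(finish(chans["VGlut1"]), vs, "VGlut1"),
        "VGAT": VolumeImage(finish(chans["VGAT"]), vs, "VGAT"),
    }
    truth = GroundTruth(
        length_um=length, crossings=crossings, tube_voxels=tube, puncta=puncta
    )
    return vols, truth


# ---------------------------------------------------------------------------
# puncta placement helpers


def place_puncta_on_branches(rng, branches, n_per_channel, afu_sampler,
                             channels=("VGlut1", "VGAT")):
    """Scatter on-neuron punctae uniformly along path length.

    ``n_per_channel`` maps channel -> count; ``afu_sampler(rng, channel,
    size)`` draws normalized intensities.
    """
    pts = _sample_paths(branches, resolution_um=0.25)
    rows = []
    for ch in channels:
        n = int(n_per_channel.get(ch, 0))
        if n == 0 or len(pts) == 0:
            continue
        picks = pts[rng.integers(len(pts), size=n)]
        afu = afu_sampler(rng, ch, n)
        for p, a in zip(picks, afu):
            rows.append(
                {"z_um": p[0], "y_um": p[1], "x_um": p[2], "channel": ch,
                 "afu": float(a), "on_neuron": True}
            )
    return pd.DataFrame(rows)


def place_off_neuron_puncta(rng, spec_shape, voxel_size, tube_voxels, n,
                            channel="VGlut1", afu=1.0, min_gap_um=1.5):
    """Scatter punctae guaranteed to be clear of the rendered neuron."""
    vs = np.asarray(voxel_size, dtype=float)
    grow = ndi.binary_dilation(
        tube_voxels, iterations=int(np.ceil(min_gap_um / vs.min()))
    )
    rows = []
    guard = 0
    while len(rows) < n and guard < 10000:
        guard += 1
        vox = np.array([rng.integers(2, s - 2) for s in spec_shape])
        if grow[tuple(vox)]:
            continue
        p = vox * vs
        rows.append(
            {"z_um": p[0], "y_um": p[1], "x_um": p[2], "channel": channel,
             "afu": float(afu), "on_neuron": False}
        )
    return pd.DataFrame(rows)
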