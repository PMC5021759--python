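"""3D volume container and TIFF I/O.

Arrays are ordered (z, y, x); voxel sizes are (dz, dy, dx) in
micrometers.  The acquisition geometry this package assumes throughout
is 0.25 um xy pixels with a 1 um z step, 16-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .geometry import GeometryError

#: Default acquisition geometry (dz, dy, dx) in micrometers.
DEFAULT_VOXEL_SIZE = (1.0, 0.25, 0.25)


@dataclass
class VolumeImage:
    """A single-channel 3D image stack with physical voxel size.

    Attributes
    ----------
    voxels : ndarray (nz, ny, nx)
    voxel_size : (dz, dy, dx) in micrometers
    channel : free-form tag, e.g. "GFP", "VGlut1", "VGAT"
    """

    voxels: np.ndarray
    voxel_size: tuple = DEFAULT_VOXEL_SIZE
    channel: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise GeometryError("VolumeImage requires a non-empty 3D grid")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel_size must be strictly positive")

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume_um3(self):
        dz, dy, dx = self.voxel_size
        return dz * dy * dx


def write_tiff(path, image: VolumeImage):
    """Write a stack as a multi-page TIFF (one page per z-plane)."""
    tifffile.imwrite(
        str(path),
        image.voxels,
        metadata={
            "voxel_size_um": list(image.voxel_size),
            "channel": image.channel,
        },
    )


def read_tiff(path, voxel_size=DEFAULT_VOXEL_SIZE, channel=""):
    """Read a multi-page TIFF back into a :class:`VolumeImage`.

    The voxel size is taken from the argument; TIFF metadata written by
    :func:`write_tiff` is advisory only.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return VolumeImage(voxels=data, voxel_size=tuple(voxel_size), channel=channel)
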