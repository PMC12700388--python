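"""Saliency-map construction from a binary segmentation.

A binary mask is not differentiable, but its skeleton voxels are the ones
deepest inside the structure.  The Euclidean distance transform encodes that
depth (each foreground voxel carries its distance to the nearest background
voxel), and Gaussian smoothing turns it into a smooth scalar field whose
ridges coincide with the segmentation skeleton.  Probability maps produced by
a segmentation network can be used directly in place of this construction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .volume_io import BinaryVolume, ScalarVolume

__all__ = ["saliency_from_segmentation"]


def saliency_from_segmentation(seg: BinaryVolume, sigma: float = 2.0) -> ScalarVolume:
    """Distance transform of ``seg`` followed by isotropic Gaussian smoothing.

    Parameters
    ----------
    seg:
        Binary segmentation; foreground = 1.
    sigma:
        Standard deviation of the Gaussian, in voxels.  Must be positive.
        Reflective boundary handling avoids artificial ridges at the faces.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    if not seg.data.any():
        warnings.warn("segmentation has no foreground; saliency is all zero", stacklevel=2)
        return ScalarVolume(np.zeros(seg.shape, dtype=np.float32), seg.voxel_size)
    if seg.data.all():
        # degenerate all-foreground volume: treat the faces as background so
        # the distance transform is defined (it then grows from the borders)
        padded = np.pad(seg.data, 1)
        dt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    else:
        dt = ndimage.distance_transform_edt(seg.data)
    sal = ndimage.gaussian_filter(dt, sigma=sigma, mode="reflect")
    return ScalarVolume(sal.astype(np.float32), seg.voxel_size)
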