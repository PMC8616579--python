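"""Candidate generation: anisotropic blur, per-plane maxima, farthest-first
pruning, and exclusion of dark (vessel / soma) regions.

Candidate synapses are local maxima of the volume after Gaussian blurring
with standard deviation 5 px in XY and 1 px in z.  Maxima are found per
z-plane with a strict 8-neighbour comparison; one physical synapse then
appears as a short stack of per-plane candidates that the merge stage joins.
Candidates closer than 3 px within a plane are deduplicated by a greedy
farthest-first traversal, and candidates falling in regions whose blurred
z-score is below -1 (blood vessels, cell bodies) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CandidatePeak, ImageVolume


@dataclass
class ExclusionMask:
    """Boolean grid of excluded voxels (True = excluded)."""

    mask: np.ndarray
    z_threshold: float

    def __contains__(self, zyx: tuple[int, int, int]) -> bool:
        return bool(self.mask[zyx])


def blur_volume(vol: ImageVolume, sigma_xy: float = 5.0, sigma_z: float = 1.0) -> ImageVolume:
    """Separable Gaussian blur, sigma (z, y, x) = (sigma_z, sigma_xy, sigma_xy).

    Borders are handled by reflection; the kernel is normalised, so a
    constant field maps to itself.
    """
    if sigma_xy <= 0 or sigma_z <= 0:
        raise ValueError("blur sigmas must be positive")
    blurred = ndimage.gaussian_filter(
        vol.voxels.astype(np.float64), sigma=(sigma_z, sigma_xy, sigma_xy), mode="reflect"
    )
    return ImageVolume(blurred, vol.voxel_size, vol.channel)


def find_local_maxima(blurred: ImageVolume) -> list[CandidatePeak]:
    """Per-plane 2D local maxima of the blurred volume.

    A voxel is a maximum if it is strictly greater than its 8 in-plane
    neighbours; pixels within 1 px of the XY edge never qualify.  Results
    are sorted by decreasing blurred value, ties broken by (z, y, x).
    """
    data = blurred.voxels
    footprint = np.ones((1, 3, 3), dtype=bool)
    footprint[0, 1, 1] = False
    neighbour_max = ndimage.maximum_filter(data, footprint=footprint, mode="constant", cval=-np.inf)
    is_max = data > neighbour_max
    is_max[:, :1, :] = False
    is_max[:, -1:, :] = False
    is_max[:, :, :1] = False
    is_max[:, :, -1:] = False
    zs, ys, xs = np.nonzero(is_max)
    vals = data[zs, ys, xs]
    order = np.lexsort((xs, ys, zs, -vals))
    return [
        CandidatePeak(int(zs[i]), int(ys[i]), int(xs[i]), float(vals[i]))
        for i in order
    ]


def farthest_first_prune(
    peaks: list[CandidatePeak], min_dist: float = 3.0
) -> list[CandidatePeak]:
    """Deduplicate nearby candidates by a greedy farthest-first traversal.

    Pruning is per z-plane with in-plane Euclidean distance.  The traversal
    starts at the highest-valued peak; at each step the unselected peak whose
    minimum distance to the selected set is largest is added (ties broken by
    input order, i.e. higher blurred value first), and the traversal stops
    once that largest minimum distance drops below ``min_dist``.
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    by_plane: dict[int, list[CandidatePeak]] = {}
    for p in peaks:
        by_plane.setdefault(p.z, []).append(p)

    kept: list[CandidatePeak] = []
    for z in sorted(by_plane):
        plane_peaks = by_plane[z]
        pts = np.array([[p.y, p.x] for p in plane_peaks], dtype=np.float64)
        n = len(plane_peaks)
        if n == 1:
            kept.append(plane_peaks[0])
            continue
        selected = np.zeros(n, dtype=bool)
        selected[0] = True  # peaks arrive sorted by decreasing value
        min_d = np.linalg.norm(pts - pts[0], axis=1)
        min_d[0] = -np.inf
        while True:
            idx = int(np.argmax(min_d))
            if min_d[idx] < min_dist:
                break
            selected[idx] = True
            d = np.linalg.norm(pts - pts[idx], axis=1)
            np.minimum(min_d, d, out=min_d)
            min_d[idx] = -np.inf
        kept.extend(p for p, s in zip(plane_peaks, selected) if s)

    kept.sort(key=lambda p: (-p.blurred_value, p.z, p.y, p.x))
    return kept


def build_exclusion_mask(blurred: ImageVolume, z_threshold: float = -1.0) -> ExclusionMask:
    """Mask voxels whose volume-wide z-score falls below ``z_threshold``.

    A zero-variance volume excludes nothing.
    """
    data = blurred.voxels
    std = float(data.std())
    if std == 0:
        return ExclusionMask(np.zeros(data.shape, dtype=bool), z_threshold)
    zscore = (data - data.mean()) / std
    return ExclusionMask(zscore < z_threshold, z_threshold)


def filter_excluded(peaks: list[CandidatePeak], mask: ExclusionMask) -> list[CandidatePeak]:
    """Drop candidates whose voxel lies in the exclusion mask."""
    return [p for p in peaks if not mask.mask[p.z, p.y, p.x]]
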