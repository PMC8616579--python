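"""Domain types and coordinate conventions.

All voxel grids are indexed ``(z, y, x)``, 0-based; plane 0 is the first
TIFF page.  Physical positions are ``index * voxel_size`` with voxel sizes
``(dz, dy, dx)`` in micrometres.  Intensities are kept on their native
scale — no normalisation at I/O time — so that SNR values and intensity
sums are reproducible from raw data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: default in vivo voxel geometry: 0.096 um pixels in XY, 1 um z-steps
DEFAULT_VOXEL_SIZE = (1.0, 0.096, 0.096)


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel dimensions.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative finite intensities on their native scale.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in micrometres.
    channel : str
        Free-text channel label (e.g. ``"SEP-GluA1"``).
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    channel: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("volume must be 3D with at least one z-plane")
        if len(self.voxel_size) != 3 or any(s <= 0 for s in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dz, dy, dx)")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class CandidatePeak:
    """A per-plane local maximum of the blurred volume."""

    z: int
    y: int
    x: int
    blurred_value: float


@dataclass(frozen=True)
class EllipseTemplate:
    """One member of the elliptical matched-template family.

    ``fg_offsets``/``bg_offsets`` are in-plane integer ``(dy, dx)`` offsets
    relative to the candidate centre; the background is a ring of width 3 px
    surrounding the ellipse.  ``roundness`` is the major/minor semi-axis
    ratio (1 = circle); ``area_target_px`` the requested area before
    rasterisation and ``area_px`` the rasterised foreground pixel count.
    """

    area_target_px: float
    roundness: float
    angle: float
    fg_offsets: tuple[tuple[int, int], ...]
    bg_offsets: tuple[tuple[int, int], ...]

    @property
    def area_px(self) -> int:
        return len(self.fg_offsets)


@dataclass
class TemplateFit:
    """Winning template at a candidate, with the slice-averaged SNRs."""

    peak: CandidatePeak
    template: EllipseTemplate
    snr1: float
    snr3: float = float("nan")
    snr7: float = float("nan")


@dataclass
class Detection2D:
    """An accepted/rejected single-plane detection."""

    fit: TemplateFit
    footprint: frozenset[tuple[int, int]]
    accepted: bool
    reject_reasons: list[str] = field(default_factory=list)

    @property
    def z(self) -> int:
        return self.fit.peak.z


@dataclass
class Synapse3D:
    """A merged 3D synapse: per-plane footprints joined across adjacent z."""

    id: int
    voxels: frozenset[tuple[int, int, int]]
    centroid: tuple[float, float, float]
    total_intensity: float

    @property
    def z_span(self) -> int:
        zs = {v[0] for v in self.voxels}
        return max(zs) - min(zs) + 1

    @property
    def n_planes(self) -> int:
        return len({v[0] for v in self.voxels})

    @property
    def max_plane_area_px(self) -> int:
        counts: dict[int, int] = {}
        for z, _, _ in self.voxels:
            counts[z] = counts.get(z, 0) + 1
        return max(counts.values())


@dataclass
class AnnotationSet:
    """Labelled voxel footprints from any source (auto / human / truth)."""

    synapses: dict[int, frozenset[tuple[int, int, int]]]
    source: str = "automatic"
    shape: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        self.synapses = {
            int(k): frozenset(tuple(map(int, v)) for v in vox)
            for k, vox in self.synapses.items()
            if len(vox) > 0
        }
        if self.shape is not None:
            for label, vox in self.synapses.items():
                for v in vox:
                    if any(c < 0 or c >= s for c, s in zip(v, self.shape)):
                        raise ValueError(
                            f"synapse {label} voxel {v} outside grid {self.shape}"
                        )

    def __len__(self) -> int:
        return len(self.synapses)


@dataclass
class DetectionConfig:
    """Every numeric threshold of the detection rule system.

    Defaults are the published operating point: 5 x 5 x 1 px Gaussian blur,
    3-px farthest-first pruning, a 65 x 65 template window (radius 32) with a
    3-px background ring, foreground areas 20-150 px, roundness 1-2.5 over 4
    steps, 12 angles over [0, 2 pi), exclusion at blurred z-score < -1, an
    SNR null threshold at the 90th percentile of 300 random locations, the
    3-plane SNR retention fraction 2/3, and a 2-6 plane z-span validity rule.
    """

    sigma_xy: float = 5.0
    sigma_z: float = 1.0
    min_candidate_dist: float = 3.0
    area_min_px: int = 20
    area_max_px: int = 150
    roundness_min: float = 1.0
    roundness_max: float = 2.5
    n_areas: int = 12
    n_roundness: int = 4
    n_angles: int = 12
    window_radius: int = 32
    bg_width: float = 3.0
    exclusion_z: float = -1.0
    n_null_locations: int = 300
    null_percentile: float = 90.0
    # where the null locations are drawn from: "snapped" (default) draws
    # uniformly random voxels and snaps each to the locally brightest
    # blurred position, giving a spatially uniform sample of local maxima
    # that stays noise-dominated at any synapse density; "candidates"
    # scores random members of the candidate population; "uniform" scores
    # the raw random voxels themselves
    null_locations: str = "snapped"
    snr3_min_fraction: float = 2.0 / 3.0
    z_span_min: int = 2
    z_span_max: int = 6
    min_overlap_px: int = 1
    # which image the SNR is measured on ("raw" default; "blurred" available)
    snr_image: str = "raw"
    # std in the SNR denominator: "window" = the 65x65 defining window
    # (noise-normalised at all contrasts), "region" = fg+bg of the template,
    # "bg" = background ring only
    snr_std_region: str = "window"
    # 3-plane rule: "fraction" (snr3 >= 2/3 snr1) or "increase" (snr3 >= snr1)
    snr3_rule: str = "fraction"
    # wide-average rule compares snr7 against "snr3" (default) or "snr1";
    # see docs: for a PSF-limited punctum snr7 ~= snr1 on the peak plane, so
    # the snr1 baseline cannot separate puncta from artifacts
    snr7_baseline: str = "snr3"
    # half-width of the wide slice-average window (3 -> seven planes z+-3)
    wide_halfwidth: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.area_min_px <= self.area_max_px):
            raise ValueError("area bounds must satisfy 0 < min <= max")
        if not (1.0 <= self.roundness_min <= self.roundness_max):
            raise ValueError("roundness bounds must satisfy 1 <= min <= max")
        if self.z_span_min > self.z_span_max:
            raise ValueError("z-span bounds out of order")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("blur sigmas must be positive")
        if self.snr_image not in ("raw", "blurred"):
            raise ValueError("snr_image must be 'raw' or 'blurred'")
        if self.snr_std_region not in ("region", "window", "bg"):
            raise ValueError("snr_std_region must be 'region', 'window' or 'bg'")
        if self.snr3_rule not in ("fraction", "increase"):
            raise ValueError("snr3_rule must be 'fraction' or 'increase'")
        if self.snr7_baseline not in ("snr1", "snr3"):
            raise ValueError("snr7_baseline must be 'snr1' or 'snr3'")
        if self.null_locations not in ("snapped", "candidates", "uniform"):
            raise ValueError("null_locations must be 'snapped', 'candidates' or 'uniform'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})
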