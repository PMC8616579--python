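"""Synthetic ground-truth volumes emulating in vivo two-photon imaging of
fluorescent synaptic puncta.

Each punctum is an intrinsically single-plane elliptical disc (XY area
0.125-1.25 um^2, roundness 1-2.5) that becomes a 3D blob through the
microscope PSF, modelled as a separable Gaussian with FWHM 0.55 / 0.57 /
2.50 um in X / Y / Z.  At the default 1 um z-step the axial sigma is about
1.06 px, which spreads a disc over roughly three planes — matching the
2-6-plane validity rule without tuning.  The background carries a constant
offset, Gaussian read noise, optional Poisson shot noise, and dark
ellipsoidal "vessel" regions that exercise the exclusion mask.  Ground
truth footprints are the post-PSF half-maximum isocontours of each
punctum's own signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import DEFAULT_VOXEL_SIZE, AnnotationSet, ImageVolume

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class PsfModel:
    """Gaussian PSF parameterised by per-axis FWHM in micrometres."""

    fwhm_x: float = 0.55
    fwhm_y: float = 0.57
    fwhm_z: float = 2.50

    def __post_init__(self):
        if min(self.fwhm_x, self.fwhm_y, self.fwhm_z) <= 0:
            raise ValueError("FWHM values must be positive")


def psf_sigmas(
    psf: PsfModel, voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
) -> tuple[float, float, float]:
    """Per-axis Gaussian sigmas in voxel units, (sigma_z, sigma_y, sigma_x).

    sigma = FWHM / (2 sqrt(2 ln 2)) / voxel_size per axis.
    """
    dz, dy, dx = voxel_size
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel sizes must be positive")
    return (
        psf.fwhm_z / (_FWHM_TO_SIGMA * dz),
        psf.fwhm_y / (_FWHM_TO_SIGMA * dy),
        psf.fwhm_x / (_FWHM_TO_SIGMA * dx),
    )


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic volumes.

    Amplitudes are log-normal around ``amp_median`` (arbitrary fluorescence
    units); the default contrast ``amp_median / sigma_read = 10`` is a
    clearly resolvable punctum.  ``min_sep_um`` is enforced on the
    XY-projected centre distance so planted puncta never overlap in XY.
    """

    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    psf: PsfModel = field(default_factory=PsfModel)
    area_um2_range: tuple[float, float] = (0.125, 1.25)
    roundness_range: tuple[float, float] = (1.0, 2.5)
    amp_median: float = 80.0
    amp_sigma_log: float = 0.3
    background: float = 100.0
    sigma_read: float = 8.0
    poisson_noise: bool = False
    min_sep_um: float = 1.5
    n_vessels: int = 2
    vessel_radius_px: tuple[float, float] = (8.0, 16.0)
    vessel_floor: float = 0.02
    vessel_clearance_px: float = 8.0
    margin_px: int = 16
    z_margin: int = 2
    max_placement_attempts: int = 20_000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psf"] = asdict(self.psf)
        return d


@dataclass(frozen=True)
class SynapseRecord:
    """Per-punctum ground-truth parameters.

    ``amplitude`` is the punctum's post-PSF peak intensity above background
    (the observed peak contrast); the painted disc height is scaled by the
    punctum's own PSF attenuation so that the rendered blob peaks at this
    value.
    """

    label: int
    z: int
    y: float
    x: float
    area_um2: float
    roundness: float
    angle: float
    amplitude: float


@dataclass
class GroundTruthVolume:
    volume: ImageVolume
    truth: AnnotationSet
    records: list[SynapseRecord]
    params: GeneratorParams
    seed: int


def _disc_mask(shape_yx, cy, cx, area_px, roundness, angle):
    """Boolean raster of one rotated elliptical disc on a 2D grid."""
    b = np.sqrt(area_px / (np.pi * roundness))
    a = roundness * b
    yy, xx = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
    dy = yy - cy
    dx = xx - cx
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _punctum_blob(rec: SynapseRecord, shape, params: GeneratorParams):
    """Unit-height post-PSF blob of one punctum on a crop, with its origin.

    Returns ``(crop, (z0, y0, x0), peak)`` where ``crop`` is the blurred
    image of the punctum's disc painted at height 1 and ``peak`` is its
    maximum (the punctum's PSF attenuation factor).
    """
    _, dy, dx = params.voxel_size
    sigmas = psf_sigmas(params.psf, params.voxel_size)
    pad_z = int(np.ceil(4 * sigmas[0])) + 2
    pad_xy = int(np.ceil(4 * max(sigmas[1:]))) + 14
    z0 = max(0, rec.z - pad_z)
    z1 = min(shape[0], rec.z + pad_z + 1)
    y0 = max(0, int(rec.y) - pad_xy)
    y1 = min(shape[1], int(rec.y) + pad_xy + 1)
    x0 = max(0, int(rec.x) - pad_xy)
    x1 = min(shape[2], int(rec.x) + pad_xy + 1)
    crop = np.zeros((z1 - z0, y1 - y0, x1 - x0), dtype=np.float64)
    area_px = rec.area_um2 / (dy * dx)
    disc = _disc_mask(crop.shape[1:], rec.y - y0, rec.x - x0, area_px, rec.roundness, rec.angle)
    crop[rec.z - z0][disc] = 1.0
    blurred = ndimage.gaussian_filter(crop, sigma=sigmas, mode="constant")
    return blurred, (z0, y0, x0), float(blurred.max())


def _truth_footprint(rec: SynapseRecord, shape, params: GeneratorParams):
    """Per-plane half-maximum footprint of one punctum's own image.

    A plane carries the punctum when its in-plane peak reaches half the 3D
    peak; on each such plane the footprint is the half-maximum contour of
    that plane's own profile.  This mirrors how a per-plane segmentation
    sees the punctum: the image's XY profile shape is the same on every
    plane (only dimmer away from focus), so the per-plane footprint is the
    well-conditioned notion of ground-truth extent for voxel-overlap
    evaluation.
    """
    blurred, (z0, y0, x0), peak = _punctum_blob(rec, shape, params)
    voxels = []
    for dz in range(blurred.shape[0]):
        plane = blurred[dz]
        pmax = plane.max()
        if pmax >= 0.5 * peak:
            ys, xs = np.nonzero(plane >= 0.5 * pmax)
            voxels.extend(zip([dz + z0] * len(ys), (ys + y0).tolist(), (xs + x0).tolist()))
    return frozenset(voxels)


def _place_vessels(shape, params: GeneratorParams, rng) -> np.ndarray:
    """Dark ellipsoidal blobs standing in for blood vessels / somata."""
    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    for _ in range(params.n_vessels):
        cz = rng.uniform(0, shape[0] - 1)
        cy = rng.uniform(0, shape[1] - 1)
        cx = rng.uniform(0, shape[2] - 1)
        rz = rng.uniform(1.0, max(1.5, shape[0] / 4))
        ry = rng.uniform(*params.vessel_radius_px)
        rx = rng.uniform(*params.vessel_radius_px)
        mask |= ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask


def _sample_centers(shape, n, params: GeneratorParams, vessel_mask, rng):
    """Rejection-sample punctum centres with a minimum XY-projected spacing."""
    _, dy, dx = params.voxel_size
    min_sep_px = params.min_sep_um / dx
    m = params.margin_px
    zm = params.z_margin
    if shape[1] <= 2 * m or shape[2] <= 2 * m or shape[0] <= 2 * zm:
        raise ValueError(f"volume {shape} too small for margins ({zm}, {m}, {m})")
    # per-plane XY clearance from vessels so puncta are not dimmed by them
    vessel_dist = np.stack(
        [ndimage.distance_transform_edt(~vessel_mask[z]) for z in range(shape[0])]
    )
    centers: list[tuple[int, float, float]] = []
    attempts = 0
    while len(centers) < n:
        attempts += 1
        if attempts > params.max_placement_attempts:
            raise RuntimeError(
                f"placed only {len(centers)}/{n} puncta after {attempts} attempts; "
                "volume too small for the requested density at min_sep_um="
                f"{params.min_sep_um}"
            )
        z = int(rng.integers(zm, shape[0] - zm))
        y = rng.uniform(m, shape[1] - 1 - m)
        x = rng.uniform(m, shape[2] - 1 - m)
        if vessel_dist[z, int(round(y)), int(round(x))] <= params.vessel_clearance_px:
            continue
        if any((y - cy) ** 2 + (x - cx) ** 2 < min_sep_px**2 for _, cy, cx in centers):
            continue
        centers.append((z, y, x))
    return centers


def generate_volume(
    shape: tuple[int, int, int] = (20, 256, 256),
    n_synapses: int = 40,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> GroundTruthVolume:
    """Generate one synthetic volume with known per-punctum ground truth.

    Deterministic: the same ``(shape, n_synapses, params, seed)`` reproduces
    the volume bit-exactly.  Structure (vessels, centres, shapes,
    amplitudes) and noise draw from independent streams spawned from the
    seed so that longitudinal sessions can redraw noise alone.
    """
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    struct_ss, noise_ss = ss.spawn(2)
    rng_struct = np.random.default_rng(struct_ss)
    rng_noise = np.random.default_rng(noise_ss)

    vessel_mask = _place_vessels(shape, params, rng_struct)
    centers = _sample_centers(shape, n_synapses, params, vessel_mask, rng_struct)
    records = []
    for i, (z, y, x) in enumerate(centers, start=1):
        area = rng_struct.uniform(*params.area_um2_range)
        roundness = rng_struct.uniform(*params.roundness_range)
        angle = rng_struct.uniform(0.0, np.pi)
        amplitude = params.amp_median * np.exp(params.amp_sigma_log * rng_struct.standard_normal())
        records.append(SynapseRecord(i, z, y, x, area, roundness, angle, amplitude))

    volume = _assemble(records, shape, params, vessel_mask, rng_noise)
    truth = AnnotationSet(
        {r.label: _truth_footprint(r, shape, params) for r in records},
        source="ground_truth",
        shape=shape,
    )
    return GroundTruthVolume(volume, truth, records, params, seed)


def _assemble(records, shape, params: GeneratorParams, vessel_mask, rng_noise) -> ImageVolume:
    # vessels attenuate the scene before the PSF acts: dark structures are
    # imaged through the same optics, so their edges are PSF-smooth
    attenuation = np.where(vessel_mask, params.vessel_floor, 1.0)
    _, dy, dx = params.voxel_size
    clean = np.zeros(shape, dtype=np.float64)
    for r in records:
        # paint so that the post-PSF blob peaks at r.amplitude: the drawn
        # amplitude is the punctum's observed peak contrast over background
        _, _, peak = _punctum_blob(r, shape, params)
        area_px = r.area_um2 / (dy * dx)
        disc = _disc_mask(shape[1:], r.y, r.x, area_px, r.roundness, r.angle)
        clean[r.z][disc] += r.amplitude / peak
    clean = (clean + params.background) * attenuation
    sigmas = psf_sigmas(params.psf, params.voxel_size)
    clean = ndimage.gaussian_filter(clean, sigma=sigmas, mode="nearest")
    if params.poisson_noise:
        clean = rng_noise.poisson(np.clip(clean, 0, None)).astype(np.float64)
    noisy = clean + rng_noise.normal(0.0, params.sigma_read, size=shape)
    return ImageVolume(np.clip(noisy, 0.0, None), params.voxel_size, "synthetic")


def generate_longitudinal(
    base: GroundTruthVolume,
    n_sessions: int = 2,
    potentiation_factor: float = 1.0,
    potentiated_fraction: float = 0.0,
    shift: tuple[int, int, int] = (0, 0, 0),
    seed: int = 0,
    stimulus_after: int = 0,
) -> list[GroundTruthVolume]:
    """Replicate a volume across imaging sessions.

    Sessions share punctum positions and shapes and redraw noise only.
    Sessions with index > ``stimulus_after`` multiply the amplitudes of a
    randomly chosen ``potentiated_fraction`` of puncta by
    ``potentiation_factor``; an optional global integer shift is applied to
    every session after the first (truth footprints move with it).
    """
    if not (0.0 <= potentiated_fraction <= 1.0):
        raise ValueError("potentiated_fraction must lie in [0, 1]")
    if potentiation_factor <= 0:
        raise ValueError("potentiation_factor must be positive")
    params = base.params
    shape = base.volume.shape
    ss = np.random.SeedSequence(seed)
    pick_ss, *noise_ss = ss.spawn(n_sessions + 1)
    rng_pick = np.random.default_rng(pick_ss)
    n_pot = int(round(potentiated_fraction * len(base.records)))
    pot_labels = set(
        rng_pick.choice([r.label for r in base.records], size=n_pot, replace=False).tolist()
    ) if n_pot else set()

    # regenerate the vessel layout exactly as generate_volume drew it
    struct_ss, _ = np.random.SeedSequence(base.seed).spawn(2)
    vessel_mask = _place_vessels(shape, params, np.random.default_rng(struct_ss))

    sessions = []
    for i in range(n_sessions):
        potentiated = i > stimulus_after
        records = [
            SynapseRecord(
                r.label, r.z, r.y, r.x, r.area_um2, r.roundness, r.angle,
                r.amplitude * (potentiation_factor if potentiated and r.label in pot_labels else 1.0),
            )
            for r in base.records
        ]
        vol = _assemble(records, shape, params, vessel_mask, np.random.default_rng(noise_ss[i]))
        truth_sets = {r.label: _truth_footprint(r, shape, params) for r in records}
        if i > 0 and shift != (0, 0, 0):
            from .quantify import apply_translation

            vol = apply_translation(vol, shift)
            shifted = {}
            for lab, vox in truth_sets.items():
                moved = frozenset(
                    (z + shift[0], y + shift[1], x + shift[2])
                    for z, y, x in vox
                    if 0 <= z + shift[0] < shape[0]
                    and 0 <= y + shift[1] < shape[1]
                    and 0 <= x + shift[2] < shape[2]
                )
                if moved:
                    shifted[lab] = moved
            truth_sets = shifted
        truth = AnnotationSet(truth_sets, source="ground_truth", shape=shape)
        sessions.append(GroundTruthVolume(vol, truth, records, params, seed))
    return sessions


def simulate_frap_trace(
    y0: float,
    plateau: float,
    k: float,
    timepoints,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a normalized FRAP recovery trace.

    Post-bleach points follow the one-phase decay
    ``Y(t) = (y0 - plateau) exp(-k t) + plateau``; baseline points (t < 0)
    sit at the normalized pre-bleach level of 1.  Gaussian noise of standard
    deviation ``noise_sigma`` is added to every point.
    """
    t = np.asarray(timepoints, dtype=float)
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    if np.any(np.diff(t) < 0):
        raise ValueError("timepoints must be ascending")
    y = np.where(t < 0, 1.0, (y0 - plateau) * np.exp(-k * np.clip(t, 0, None)) + plateau)
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, noise_sigma, size=t.shape) if noise_sigma > 0 else y
    return pd.DataFrame({"t_min": t, "value": y})
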