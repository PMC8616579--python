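"""Per-synapse and per-session measurements, baseline normalisation,
translation alignment, and the Mann-Whitney distribution-shift statistic
used for longitudinal plasticity quantification.

Longitudinal statistics are population-level: each imaging session is
detected independently, per-synapse summed intensities are normalised to
the pooled-baseline mean, and each session's intensity distribution is
compared against the pooled baseline with a two-sided Mann-Whitney U test.
Synapse identity is not tracked across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
from scipy.stats import rankdata

from .core import DetectionConfig, ImageVolume, Synapse3D

#: enumeration budget for the exact Mann-Whitney null distribution
_EXACT_MAX_COMBINATIONS = 200_000


@dataclass
class SessionStats:
    """Population summary of one imaging session."""

    session_id: int | str
    intensity_values: list[float]
    mean_area_px: float = float("nan")
    n_detected: int | None = None

    @property
    def n_synapses(self) -> int:
        return len(self.intensity_values)

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity_values)) if self.intensity_values else float("nan")


def synapse_intensity(vol: ImageVolume, synapse: Synapse3D) -> float:
    """Sum of raw voxel intensities over the merged 3D footprint."""
    arr = np.array(sorted(synapse.voxels))
    if arr.size == 0:
        return 0.0
    if (arr < 0).any() or (arr >= np.array(vol.shape)).any():
        raise IndexError("synapse voxel outside the volume")
    return float(vol.voxels[arr[:, 0], arr[:, 1], arr[:, 2]].sum())


def synapse_max_area(
    synapse: Synapse3D, voxel_size: tuple[float, float, float] | None = None
) -> float | tuple[float, float]:
    """Maximum single-plane area in px (and um^2 when a voxel size is given)."""
    if not synapse.voxels:
        raise ValueError("empty synapse")
    area_px = synapse.max_plane_area_px
    if voxel_size is None:
        return float(area_px)
    _, dy, dx = voxel_size
    return float(area_px), float(area_px * dy * dx)


def normalize_to_baseline(
    sessions: list[SessionStats],
    baseline_ids: list,
    method: str = "mean",
) -> list[SessionStats]:
    """Divide every per-synapse intensity by the pooled-baseline mean
    (or median with ``method='median'``); baseline sessions then have
    normalised mean (median) ~= 1."""
    baseline_ids = set(baseline_ids)
    pooled = [
        v for s in sessions if s.session_id in baseline_ids for v in s.intensity_values
    ]
    if not pooled:
        raise ValueError("no baseline intensities to normalise against")
    denom = float(np.mean(pooled)) if method == "mean" else float(np.median(pooled))
    if denom == 0:
        raise ValueError("baseline mean intensity is zero")
    return [
        SessionStats(
            s.session_id,
            [v / denom for v in s.intensity_values],
            s.mean_area_px,
            s.n_detected,
        )
        for s in sessions
    ]


def _exact_two_sided_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    The permutation distribution of U is symmetric about n_a*n_b/2 even
    under ties, so the two-sided p is P(|U - mu| >= |u_obs - mu|).
    """
    N = len(ranks)
    n_b = N - n_a
    mu = n_a * n_b / 2.0
    offset = n_a * (n_a + 1) / 2.0
    dev = abs(u_obs - mu) - 1e-9
    n_extreme = 0
    total = 0
    for idx in combinations(range(N), n_a):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev:
            n_extreme += 1
        total += 1
    return n_extreme / total


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Returns ``(U_a, p)`` where ``U_a`` is the statistic of the first sample
    (``U_a + U_b = n_a * n_b``).  The p-value is exact (full enumeration of
    the permutation null) when the smaller sample has at most 8 values and
    the enumeration is tractable, and a tie-corrected normal approximation
    with continuity correction otherwise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0)

    if min(n_a, n_b) <= 8 and comb(n_a + n_b, n_a) <= _EXACT_MAX_COMBINATIONS:
        return u_a, float(min(1.0, _exact_two_sided_p(ranks, n_a, u_a)))

    N = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (N * (N - 1)))
    var = n_a * n_b / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return u_a, 1.0
    dev = abs(u_a - mu)
    z = max(0.0, dev - 0.5) / sqrt(var)
    p = 2.0 * 0.5 * (1.0 - erf(z / sqrt(2.0)))
    return u_a, float(min(1.0, p))


def align_translation(
    ref: ImageVolume,
    moving: ImageVolume,
    max_shift: tuple[int, int, int] = (2, 10, 10),
) -> tuple[int, int, int]:
    """Integer (dz, dy, dx) shift maximising zero-mean cross-correlation.

    The returned shift is the one to apply to ``moving`` (via
    :func:`apply_translation`) to align it onto ``ref``; ties are broken
    towards the smallest shift magnitude, then lexicographically.
    """
    if ref.shape != moving.shape:
        raise ValueError("volumes must share a shape for translation alignment")
    if any(m >= s for m, s in zip(max_shift, ref.shape)):
        raise ValueError("max_shift exceeds the volume extent")
    # zero-padding by max_shift per axis makes the circular FFT correlation
    # exact for all lags within +-max_shift while keeping memory ~ volume
    r = (ref.voxels - ref.voxels.mean()).astype(np.float32)
    m = (moving.voxels - moving.voxels.mean()).astype(np.float32)
    padded = tuple(s + 2 * ms for s, ms in zip(ref.shape, max_shift))
    axes = (0, 1, 2)
    fr = np.fft.rfftn(r, s=padded, axes=axes)
    fm = np.fft.rfftn(m, s=padded, axes=axes)
    cc = np.fft.irfftn(fr * np.conj(fm), s=padded, axes=axes)
    shifts = []
    for dz in range(-max_shift[0], max_shift[0] + 1):
        for dy in range(-max_shift[1], max_shift[1] + 1):
            for dx in range(-max_shift[2], max_shift[2] + 1):
                shifts.append((dz, dy, dx))
    shifts.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2 + s[2] ** 2, s))
    vals = np.array([cc[tuple(np.mod(s, padded))] for s in shifts])
    best = float(vals.max())
    tol = 1e-6 * max(1.0, abs(best))
    for s, v in zip(shifts, vals):
        if v >= best - tol:
            return s
    return shifts[int(np.argmax(vals))]


def apply_translation(vol: ImageVolume, shift: tuple[int, int, int]) -> ImageVolume:
    """Shift a volume by integer (dz, dy, dx), zero-filling exposed voxels."""
    out = np.zeros_like(vol.voxels)
    src = []
    dst = []
    for s, n in zip(shift, vol.shape):
        s = int(s)
        if abs(s) >= n:
            return ImageVolume(out, vol.voxel_size, vol.channel)
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = vol.voxels[tuple(src)]
    return ImageVolume(out, vol.voxel_size, vol.channel)


def session_stats_from_synapses(
    session_id, vol: ImageVolume, synapses: list[Synapse3D]
) -> SessionStats:
    intensities = [synapse_intensity(vol, s) for s in synapses]
    areas = [s.max_plane_area_px for s in synapses]
    return SessionStats(
        session_id,
        intensities,
        float(np.mean(areas)) if areas else float("nan"),
        n_detected=len(synapses),
    )


def longitudinal_report(
    session_volumes: list[ImageVolume],
    config: DetectionConfig | None = None,
    baseline_ids: list | None = None,
    max_shift: tuple[int, int, int] = (2, 10, 10),
    family=None,
) -> tuple[list[SessionStats], dict]:
    """Detect and quantify a longitudinal series of sessions.

    Each session is translation-aligned to the first, detected with
    :func:`synaptodetect.pipeline.detect_pipeline`, summarised, normalised
    to the pooled baseline (sessions listed in ``baseline_ids``; default
    the first session), and compared to the pooled baseline with a
    two-sided Mann-Whitney U test.
    """
    from .pipeline import detect_pipeline
    from .templates import build_template_family

    if len(session_volumes) < 2:
        raise ValueError("need at least two sessions")
    config = config or DetectionConfig()
    baseline_ids = baseline_ids if baseline_ids is not None else [0]
    if family is None:
        family = build_template_family(config)

    stats: list[SessionStats] = []
    shifts: dict[int, tuple[int, int, int]] = {}
    for i, vol in enumerate(session_volumes):
        if i == 0:
            aligned = vol
            shifts[i] = (0, 0, 0)
        else:
            shift = align_translation(session_volumes[0], vol, max_shift)
            shifts[i] = shift
            aligned = apply_translation(vol, shift)
        synapses, _ = detect_pipeline(aligned, config, family=family)
        stats.append(session_stats_from_synapses(i, aligned, synapses))

    normalized = normalize_to_baseline(stats, baseline_ids)
    pooled = [
        v for s in normalized if s.session_id in set(baseline_ids) for v in s.intensity_values
    ]
    p_values: dict[int, float] = {}
    for s in normalized:
        if s.intensity_values and pooled:
            _, p = mann_whitney_u(s.intensity_values, pooled)
        else:
            p = float("nan")
        p_values[s.session_id] = p
    report = {"shifts": shifts, "p_values": p_values, "baseline_ids": list(baseline_ids)}
    return normalized, report
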