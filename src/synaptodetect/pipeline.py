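"""Acceptance rules and 3D merging: the five-condition rule engine, the
null-SNR threshold, z-plane merging, and the full detection pipeline.

A per-plane candidate is accepted as a synapse only if all five conditions
hold: (1) its best template has 20-150 px area; (2) roundness between 1 and
2.5; (3) single-plane SNR above the 90th percentile of 300 random null
locations; (4) SNR retained to at least 2/3 when averaging with the two
adjacent slices (synapses span more than one slice, noise does not); and
(5) SNR not increased by widening the average to seven adjacent slices
(artifacts span many more slices than synapses; the SNR of a punctum peaks
at its own axial scale, so widening past the 3-slice average must not
help — the comparison baseline is configurable, ``snr3`` by default).  Accepted detections overlapping in XY on
adjacent z-planes are merged into 3D synapses, and only synapses spanning
2-6 consecutive planes are kept.
"""

from __future__ import annotations

import numpy as np

from .core import CandidatePeak, Detection2D, DetectionConfig, ImageVolume, Synapse3D, TemplateFit
from .detect import (
    ExclusionMask,
    blur_volume,
    build_exclusion_mask,
    farthest_first_prune,
    filter_excluded,
    find_local_maxima,
)
from .templates import (
    EllipseTemplate,
    TemplateFamilyScorer,
    build_template_family,
    extract_window,
    extract_windows,
    template_snr,
)

RULE_SIZE = "size"
RULE_ROUNDNESS = "roundness"
RULE_SNR_NULL = "snr-null"
RULE_SLICE3 = "slice-average-3"
RULE_SLICE7 = "slice-average-7"


def _averaged_plane(voxels: np.ndarray, z: int, halfwidth: int) -> np.ndarray:
    """Pixelwise mean of planes z-halfwidth ... z+halfwidth, truncated at ends."""
    lo = max(0, z - halfwidth)
    hi = min(voxels.shape[0], z + halfwidth + 1)
    return voxels[lo:hi].mean(axis=0)


def slice_average_snrs(
    vol: ImageVolume, fit: TemplateFit, config: DetectionConfig | None = None
) -> tuple[float, float, float]:
    """SNR of the winning template on the plane, the 3-plane mean and the
    7-plane mean (windows truncated at stack ends).  Also fills the fit's
    ``snr3``/``snr7`` fields."""
    config = config or DetectionConfig()
    p = fit.peak
    w1 = extract_window(vol.voxels[p.z], p.y, p.x, config.window_radius)
    w3 = extract_window(_averaged_plane(vol.voxels, p.z, 1), p.y, p.x, config.window_radius)
    w7 = extract_window(
        _averaged_plane(vol.voxels, p.z, config.wide_halfwidth), p.y, p.x, config.window_radius
    )
    snr1 = template_snr(w1, fit.template, config.snr_std_region)
    snr3 = template_snr(w3, fit.template, config.snr_std_region)
    snr7 = template_snr(w7, fit.template, config.snr_std_region)
    fit.snr1, fit.snr3, fit.snr7 = snr1, snr3, snr7
    return snr1, snr3, snr7


def snr_null_threshold(
    vol: ImageVolume,
    family: list[EllipseTemplate],
    mask: ExclusionMask,
    n: int = 300,
    pct: float = 90.0,
    seed: int = 0,
    config: DetectionConfig | None = None,
    scorer: TemplateFamilyScorer | None = None,
    candidates: list[CandidatePeak] | None = None,
    blurred: ImageVolume | None = None,
) -> float:
    """The pct-th percentile of best-template SNRs at n random locations.

    Three sampling schemes: with ``candidates`` given, the n locations are
    drawn uniformly without replacement from the candidate population; with
    ``blurred`` given, uniformly random voxels are snapped to the brightest
    blurred position within ``2 * sigma_xy`` in-plane, yielding a spatially
    uniform sample of local maxima (null SNRs are then exchangeable with
    candidate SNRs under the no-synapse hypothesis at any synapse density);
    otherwise the raw random voxels are scored, and fewer than n valid
    voxels is an error.  Locations avoid the exclusion mask and the 1-px XY
    border.  Deterministic given the seed; percentiles interpolate linearly.
    """
    config = config or DetectionConfig()
    if scorer is None:
        scorer = TemplateFamilyScorer(family, config.window_radius, config.snr_std_region)
    rng = np.random.default_rng(seed)
    if candidates is not None:
        if not candidates:
            raise ValueError("no candidate locations to draw the null sample from")
        idx = np.arange(len(candidates))
        if len(candidates) > n:
            idx = rng.choice(idx, size=n, replace=False)
        zs = np.array([candidates[i].z for i in idx])
        ys = np.array([candidates[i].y for i in idx])
        xs = np.array([candidates[i].x for i in idx])
    else:
        valid = ~mask.mask.copy()
        valid[:, :1, :] = False
        valid[:, -1:, :] = False
        valid[:, :, :1] = False
        valid[:, :, -1:] = False
        flat = np.flatnonzero(valid)
        if len(flat) < n:
            raise ValueError(f"only {len(flat)} valid null locations, need {n}")
        chosen = rng.choice(flat, size=n, replace=False)
        zs, ys, xs = np.unravel_index(chosen, mask.mask.shape)
        if blurred is not None:
            # snap each location to the locally brightest blurred position
            r = max(1, int(np.ceil(2 * config.sigma_xy)))
            ny, nx = blurred.voxels.shape[1:]
            sy, sx = [], []
            for z, y, x in zip(zs, ys, xs):
                y0, y1 = max(1, y - r), min(ny - 1, y + r + 1)
                x0, x1 = max(1, x - r), min(nx - 1, x + r + 1)
                patch = blurred.voxels[z, y0:y1, x0:x1]
                iy, ix = np.unravel_index(np.argmax(patch), patch.shape)
                sy.append(y0 + iy)
                sx.append(x0 + ix)
            ys, xs = np.array(sy), np.array(sx)
    snrs = np.empty(len(zs), dtype=np.float64)
    for z in np.unique(zs):
        sel = zs == z
        windows = extract_windows(vol.voxels[z], ys[sel], xs[sel], config.window_radius)
        _, best = scorer.best(windows)
        snrs[sel] = best
    return float(np.percentile(snrs, pct))


def apply_acceptance_rules(
    fit: TemplateFit, threshold: float, config: DetectionConfig | None = None
) -> Detection2D:
    """Evaluate the five acceptance conditions on one template fit.

    ``reject_reasons`` lists every failed rule; the detection is accepted
    iff the list is empty.
    """
    config = config or DetectionConfig()
    reasons: list[str] = []
    t = fit.template
    if not (config.area_min_px <= t.area_px <= config.area_max_px):
        reasons.append(RULE_SIZE)
    if not (config.roundness_min <= t.roundness <= config.roundness_max):
        reasons.append(RULE_ROUNDNESS)
    if not fit.snr1 > threshold:
        reasons.append(RULE_SNR_NULL)
    if config.snr3_rule == "increase":
        ok3 = fit.snr3 >= fit.snr1
    else:
        ok3 = fit.snr3 >= config.snr3_min_fraction * fit.snr1
    if not ok3:
        reasons.append(RULE_SLICE3)
    wide_base = fit.snr3 if config.snr7_baseline == "snr3" else fit.snr1
    if not fit.snr7 <= wide_base:
        reasons.append(RULE_SLICE7)
    footprint = frozenset(
        (fit.peak.y + dy, fit.peak.x + dx) for dy, dx in t.fg_offsets
    )
    return Detection2D(fit, footprint, accepted=not reasons, reject_reasons=reasons)


def merge_across_planes(
    detections: list[Detection2D],
    vol: ImageVolume | None = None,
    min_overlap_px: int = 1,
) -> list[Synapse3D]:
    """Merge accepted detections overlapping in XY on adjacent z-planes.

    Builds a graph with an edge between detections on planes z and z+1
    sharing at least ``min_overlap_px`` pixels; connected components become
    :class:`Synapse3D` objects whose voxels are the union of member
    footprints, with intensity-weighted centroids when a volume is given.
    """
    detections = [d for d in detections if d.accepted]
    n = len(detections)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    by_plane: dict[int, list[int]] = {}
    for i, d in enumerate(detections):
        by_plane.setdefault(d.z, []).append(i)
    for z, idxs in by_plane.items():
        for j in by_plane.get(z + 1, []):
            fpj = detections[j].footprint
            for i in idxs:
                if len(detections[i].footprint & fpj) >= min_overlap_px:
                    union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    synapses = []
    for members in groups.values():
        voxels = frozenset(
            (detections[i].z, y, x) for i in members for (y, x) in detections[i].footprint
        )
        if vol is not None:
            nz, ny, nx = vol.shape
            arr = np.array([v for v in voxels if 0 <= v[1] < ny and 0 <= v[2] < nx])
        else:
            arr = np.array(sorted(voxels))
        if vol is not None and len(arr):
            weights = vol.voxels[arr[:, 0], arr[:, 1], arr[:, 2]]
            total = float(weights.sum())
            centroid = (
                tuple((arr * weights[:, None]).sum(axis=0) / weights.sum())
                if weights.sum() > 0
                else tuple(arr.mean(axis=0))
            )
        else:
            total = 0.0
            centroid = tuple(arr.mean(axis=0)) if len(arr) else (0.0, 0.0, 0.0)
        synapses.append(Synapse3D(0, frozenset(map(tuple, arr.tolist())), centroid, total))

    synapses.sort(key=lambda s: (min(v[0] for v in s.voxels), s.centroid[1], s.centroid[2]))
    for i, s in enumerate(synapses, start=1):
        s.id = i
    return synapses


def filter_by_zspan(
    synapses: list[Synapse3D], span_min: int = 2, span_max: int = 6
) -> list[Synapse3D]:
    """Keep synapses occupying span_min-span_max adjacent z-planes."""
    return [s for s in synapses if span_min <= s.z_span <= span_max]


def detect_pipeline(
    vol: ImageVolume,
    config: DetectionConfig | None = None,
    family: list[EllipseTemplate] | None = None,
) -> tuple[list[Synapse3D], dict]:
    """Run the full detection chain on one volume.

    blur -> per-plane maxima -> farthest-first prune -> exclusion filter ->
    best template per candidate -> null threshold -> five acceptance rules ->
    adjacent-plane merge -> 2-6 plane z-span filter.  Deterministic given
    ``config.rng_seed``.  Returns the synapse list and a report of stage
    counts, the null threshold and the configuration.
    """
    config = config or DetectionConfig()
    blurred = blur_volume(vol, config.sigma_xy, config.sigma_z)
    peaks = find_local_maxima(blurred)
    pruned = farthest_first_prune(peaks, config.min_candidate_dist)
    mask = build_exclusion_mask(blurred, config.exclusion_z)
    candidates = filter_excluded(pruned, mask)

    if family is None:
        family = build_template_family(config)
    scorer = TemplateFamilyScorer(family, config.window_radius, config.snr_std_region)
    score_vol = blurred if config.snr_image == "blurred" else vol

    fits: list[TemplateFit] = []
    if candidates:
        zs = np.array([p.z for p in candidates])
        ys = np.array([p.y for p in candidates])
        xs = np.array([p.x for p in candidates])
        t_idx = np.empty(len(candidates), dtype=np.int64)
        snr1 = np.empty(len(candidates))
        snr3 = np.empty(len(candidates))
        snr7 = np.empty(len(candidates))
        for z in np.unique(zs):
            sel = np.flatnonzero(zs == z)
            w1 = extract_windows(score_vol.voxels[z], ys[sel], xs[sel], config.window_radius)
            idx, best = scorer.best(w1)
            t_idx[sel], snr1[sel] = idx, best
            p3 = _averaged_plane(score_vol.voxels, int(z), 1)
            p7 = _averaged_plane(score_vol.voxels, int(z), config.wide_halfwidth)
            w3 = extract_windows(p3, ys[sel], xs[sel], config.window_radius)
            w7 = extract_windows(p7, ys[sel], xs[sel], config.window_radius)
            snr3[sel] = _snr_for_templates(scorer, w3, idx)
            snr7[sel] = _snr_for_templates(scorer, w7, idx)
        for i, p in enumerate(candidates):
            fits.append(
                TemplateFit(p, family[int(t_idx[i])], float(snr1[i]), float(snr3[i]), float(snr7[i]))
            )

    if config.null_locations == "candidates" and not candidates:
        threshold = 0.0  # nothing to accept anyway
    else:
        threshold = snr_null_threshold(
            score_vol, family, mask,
            n=config.n_null_locations, pct=config.null_percentile,
            seed=config.rng_seed, config=config, scorer=scorer,
            candidates=candidates if config.null_locations == "candidates" else None,
            blurred=blurred if config.null_locations == "snapped" else None,
        )

    detections = [apply_acceptance_rules(f, threshold, config) for f in fits]
    accepted = [d for d in detections if d.accepted]
    merged = merge_across_planes(accepted, vol, config.min_overlap_px)
    synapses = filter_by_zspan(merged, config.z_span_min, config.z_span_max)

    report = {
        "n_maxima": len(peaks),
        "n_after_prune": len(pruned),
        "n_after_exclusion": len(candidates),
        "n_accepted_2d": len(accepted),
        "n_merged_3d": len(merged),
        "n_synapses": len(synapses),
        "null_threshold": threshold,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
    }
    return synapses, report


def _snr_for_templates(
    scorer: TemplateFamilyScorer, windows: np.ndarray, t_idx: np.ndarray
) -> np.ndarray:
    """Per-row SNR of each window against its own (already chosen) template."""
    Wm = np.ascontiguousarray(windows, dtype=np.float32)
    F = scorer.F[t_idx]
    B = scorer.B[t_idx]
    nf = scorer.nf[t_idx]
    nb = scorer.nb[t_idx]
    sq = Wm * Wm
    fg_sum = np.einsum("ij,ij->i", Wm, F)
    bg_sum = np.einsum("ij,ij->i", Wm, B)
    diff = fg_sum / nf - bg_sum / nb
    if scorer.std_region == "window":
        var = sq.mean(axis=1) - Wm.mean(axis=1) ** 2
    else:
        n = nf + nb
        s1 = fg_sum + bg_sum
        var = (np.einsum("ij,ij->i", sq, F) + np.einsum("ij,ij->i", sq, B)) / n - (s1 / n) ** 2
    std = np.sqrt(np.clip(var, 0.0, None))
    out = np.zeros_like(diff)
    ok = std > 1e-6
    out[ok] = diff[ok] / std[ok]
    return out
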