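"""Annotation agreement, precision/recall, two-channel overlap, and
spine-punctum colocalization with rotation controls.

Agreement between two annotation sets A and B follows the >=50%-shared-voxel
rule: for each synapse in A the best-overlapping synapse in B is found, and
the pair agrees when the shared voxel count reaches half the size of the A
synapse.  The definition is directional; both directions and their mean are
reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .core import AnnotationSet
from .quantify import mann_whitney_u


@dataclass
class AgreementReport:
    a_to_b: float
    b_to_a: float
    matches: list[tuple[int, Optional[int], int]] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return 0.5 * (self.a_to_b + self.b_to_a)


def _directional_matches(
    A: AnnotationSet, B: AnnotationSet, overlap_frac: float
) -> tuple[list[tuple[int, Optional[int], int]], float]:
    """Best-overlap matches of A's synapses into B and the agreeing fraction."""
    voxel_to_b: dict[tuple[int, int, int], int] = {}
    for label_b, vox in B.synapses.items():
        for v in vox:
            voxel_to_b[v] = label_b
    matches: list[tuple[int, Optional[int], int]] = []
    n_agree = 0
    for label_a in sorted(A.synapses):
        vox_a = A.synapses[label_a]
        counts: dict[int, int] = {}
        for v in vox_a:
            b = voxel_to_b.get(v)
            if b is not None:
                counts[b] = counts.get(b, 0) + 1
        if counts:
            best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
            label_b, shared = best
        else:
            label_b, shared = None, 0
        if label_b is not None and shared >= overlap_frac * len(vox_a):
            n_agree += 1
            matches.append((label_a, label_b, shared))
        else:
            matches.append((label_a, None, shared))
    frac = n_agree / len(A.synapses) if A.synapses else float("nan")
    return matches, frac


def match_annotations(
    A: AnnotationSet, B: AnnotationSet, overlap_frac: float = 0.5
) -> AgreementReport:
    """Directional agreement between annotation sets A and B.

    A synapse in A agrees with B when its best-overlapping partner in B
    shares at least ``overlap_frac`` of A's voxels (exactly 50% counts as
    agreement); ties between equally overlapping partners go to the smaller
    B label.  Returns both directions and the match list for A->B.
    """
    if A.shape is not None and B.shape is not None and A.shape != B.shape:
        raise ValueError(f"annotation grids differ: {A.shape} vs {B.shape}")
    matches_ab, a_to_b = _directional_matches(A, B, overlap_frac)
    _, b_to_a = _directional_matches(B, A, overlap_frac)
    return AgreementReport(a_to_b, b_to_a, matches_ab)


def precision_recall(
    auto: AnnotationSet, truth: AnnotationSet, overlap_frac: float = 0.5
) -> tuple[float, float, float]:
    """Precision, recall and F1 of automatic detections against ground truth.

    A true positive is an automatic synapse whose best truth partner shares
    >= overlap_frac of its voxels; recall is the matched fraction of truth
    synapses (same rule with roles swapped).  The false-positive rate is
    1 - precision and the false-negative rate 1 - recall.  Empty sets give
    NaN for the undefined quantity.
    """
    report = match_annotations(auto, truth, overlap_frac)
    precision = report.a_to_b
    recall = report.b_to_a
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan") if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    # empty auto: no detections means recall over truth is 0, precision undefined
    if not auto.synapses and truth.synapses:
        recall = 0.0
    return precision, recall, f1


def channel_overlap(
    setA: AnnotationSet, setB: AnnotationSet, overlap_frac: float = 0.5
) -> tuple[float, float, float]:
    """Two-channel ground-truth rates between independent synaptic markers.

    tp = fraction of channel-1 detections overlapping channel 2 (>=50% of
    shared voxels), fp = channel-1 without overlap (tp + fp = 1), fn =
    fraction of channel-2 detections without overlap into channel 1.
    """
    if not setA.synapses:
        return 0.0, 0.0, _fn_rate(setB, setA, overlap_frac)
    _, tp_rate = _directional_matches(setA, setB, overlap_frac)
    fn_rate = _fn_rate(setB, setA, overlap_frac)
    return tp_rate, 1.0 - tp_rate, fn_rate


def _fn_rate(setB: AnnotationSet, setA: AnnotationSet, overlap_frac: float) -> float:
    if not setB.synapses:
        return 0.0
    _, matched = _directional_matches(setB, setA, overlap_frac)
    return 1.0 - matched


def spine_colocalization(
    spine_set: AnnotationSet,
    puncta: AnnotationSet,
    max_edge_dist_um: float = 0.25,
    voxel_size: tuple[float, float, float] = (1.0, 0.096, 0.096),
) -> tuple[float, dict[int, float]]:
    """Fraction of spines with a punctum within ``max_edge_dist_um``.

    The edge-to-edge distance of a spine to a punctum is the minimum
    physical distance between their voxel centres (0 for overlapping
    footprints); a spine is colocalized when its nearest punctum lies closer
    than the threshold.  Returns the colocalized fraction and per-spine
    nearest-neighbour distances (infinite when there are no puncta).
    """
    scale = np.asarray(voxel_size, dtype=float)
    punct_vox = [v for vox in puncta.synapses.values() for v in vox]
    dists: dict[int, float] = {}
    if punct_vox:
        tree = cKDTree(np.asarray(punct_vox, dtype=float) * scale)
        for label, vox in spine_set.synapses.items():
            pts = np.asarray(sorted(vox), dtype=float) * scale
            d, _ = tree.query(pts)
            dists[label] = float(np.min(d))
    else:
        dists = {label: float("inf") for label in spine_set.synapses}
    if not dists:
        return float("nan"), dists
    frac = sum(1 for d in dists.values() if d < max_edge_dist_um) / len(dists)
    return frac, dists


def _rotate_voxels(
    vox: frozenset[tuple[int, int, int]], shape: tuple[int, int, int], angle_deg: int
) -> frozenset[tuple[int, int, int]]:
    """Rotate footprints about the XY centre by a multiple of 90 degrees."""
    _, ny, nx = shape
    if angle_deg % 90 != 0:
        raise ValueError("only multiples of 90 degrees are lattice-exact")
    if angle_deg % 360 in (90, 270) and ny != nx:
        raise ValueError("90/270 degree rotation requires a square XY grid")
    out = set()
    for z, y, x in vox:
        a = angle_deg % 360
        yy, xx = y, x
        for _ in range(a // 90):
            yy, xx = xx, ny - 1 - yy
        out.add((z, yy, xx))
    return frozenset(out)


def rotation_control(
    spine_set: AnnotationSet,
    puncta: AnnotationSet,
    angles: tuple[int, ...] = (90, 180, 270),
    max_edge_dist_um: float = 0.25,
    voxel_size: tuple[float, float, float] = (1.0, 0.096, 0.096),
    shape: Optional[tuple[int, int, int]] = None,
) -> dict[int, dict]:
    """Chance control: rotate the spine channel in XY and re-measure
    nearest-punctum distances, comparing each rotated distribution to the
    unrotated one with a two-sided Mann-Whitney U test."""
    shape = shape or spine_set.shape or puncta.shape
    if shape is None:
        raise ValueError("grid shape required (set AnnotationSet.shape or pass shape=)")
    _, base = spine_colocalization(spine_set, puncta, max_edge_dist_um, voxel_size)
    base_d = [base[k] for k in sorted(base)]
    results: dict[int, dict] = {0: {"distances": base_d, "p_value": 1.0}}
    for angle in angles:
        rotated = AnnotationSet(
            {lab: _rotate_voxels(v, shape, angle) for lab, v in spine_set.synapses.items()},
            source=spine_set.source,
            shape=shape,
        )
        frac, dists = spine_colocalization(rotated, puncta, max_edge_dist_um, voxel_size)
        dvals = [dists[k] for k in sorted(dists)]
        _, p = mann_whitney_u(dvals, base_d)
        results[angle] = {"distances": dvals, "p_value": p, "fraction_colocalized": frac}
    return results
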