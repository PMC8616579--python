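"""Elliptical matched-template family and SNR scoring.

A synapse is modelled as a bright ellipse on a darker surround.  The
template family enumerates foreground ellipses of 20-150 px area, four
roundness values (major/minor semi-axis ratio) from 1 to 2.5 and twelve
angles over [0, 2 pi), each rasterised inside a square window of radius
32 px together with a surrounding background ring of width 3 px.  A
candidate's score for a template is

    SNR = (mean foreground - mean background) / std(region)

with the population standard deviation taken over the template region
(foreground plus ring); the template maximising SNR is associated with the
candidate.  Scoring uses the raw (unblurred) image so that the noise
statistics in the denominator are unaltered.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import CandidatePeak, DetectionConfig, EllipseTemplate, ImageVolume, TemplateFit


def rasterize_ellipse(
    area_px: float,
    roundness: float,
    angle: float,
    window_radius: int = 32,
    bg_width: float = 3.0,
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Rasterise one elliptical foreground and its background ring.

    Semi-axes solve ``pi * a * b = area_px`` with ``a / b = roundness``;
    a pixel offset belongs to the foreground when its centre satisfies the
    rotated-ellipse inequality, and to the background when it lies within
    ``bg_width`` px (Euclidean) of the foreground without being part of it.
    Returns ``(fg_offsets, bg_offsets)`` as (dy, dx) tuples centred at (0, 0).
    """
    if not (20 <= area_px <= 150):
        raise ValueError(f"area_px {area_px} outside [20, 150]")
    if not (1.0 <= roundness <= 2.5):
        raise ValueError(f"roundness {roundness} outside [1, 2.5]")
    b = np.sqrt(area_px / (np.pi * roundness))
    a = roundness * b
    R = window_radius
    dy, dx = np.mgrid[-R : R + 1, -R : R + 1]
    # major axis along direction `angle`, measured from +x towards +y
    u = dx * np.cos(angle) + dy * np.sin(angle)
    v = -dx * np.sin(angle) + dy * np.cos(angle)
    fg = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    dist = ndimage.distance_transform_edt(~fg)
    bg = (dist <= bg_width) & ~fg
    fg_offsets = tuple(zip(dy[fg].tolist(), dx[fg].tolist()))
    bg_offsets = tuple(zip(dy[bg].tolist(), dx[bg].tolist()))
    return fg_offsets, bg_offsets


def build_template_family(config: DetectionConfig) -> list[EllipseTemplate]:
    """Enumerate the template family and drop duplicates.

    Areas are evenly spaced over the configured bounds, roundness over its
    bounds, angles over [0, 2 pi); templates with identical foreground masks
    (e.g. all rotations of a circle, or the pi-periodicity of an ellipse)
    are removed, and templates whose rasterised area falls outside the
    bounds are discarded.  The family is sorted by (rasterised area,
    roundness, angle) so that an argmax over the list resolves SNR ties in
    favour of smaller, rounder, less rotated templates.
    """
    areas = np.linspace(config.area_min_px, config.area_max_px, config.n_areas)
    roundnesses = np.linspace(config.roundness_min, config.roundness_max, config.n_roundness)
    angles = np.linspace(0.0, 2.0 * np.pi, config.n_angles, endpoint=False)
    templates: list[EllipseTemplate] = []
    seen: set[frozenset] = set()
    for area in areas:
        for roundness in roundnesses:
            for angle in angles:
                fg, bg = rasterize_ellipse(
                    float(area), float(roundness), float(angle),
                    config.window_radius, config.bg_width,
                )
                if not (config.area_min_px <= len(fg) <= config.area_max_px):
                    continue
                key = frozenset(fg)
                if key in seen:
                    continue
                seen.add(key)
                templates.append(
                    EllipseTemplate(float(area), float(roundness), float(angle), fg, bg)
                )
    if not templates:
        raise ValueError("no valid templates for the given configuration")
    templates.sort(key=lambda t: (t.area_px, t.roundness, t.angle))
    return templates


def template_snr(
    window: np.ndarray, template: EllipseTemplate, std_region: str = "region"
) -> float:
    """Matched-template SNR of one window patch.

    ``window`` is the (2R+1) x (2R+1) patch centred on the candidate.  The
    denominator is the population std over the template region (default) or
    over the full window (``std_region='window'``); zero spread gives SNR 0.
    """
    R = (window.shape[0] - 1) // 2
    if window.shape[0] != window.shape[1] or window.shape[0] % 2 == 0:
        raise ValueError(f"window must be odd square, got {window.shape}")
    fg_idx = tuple(np.array([(dy + R, dx + R) for dy, dx in template.fg_offsets]).T)
    bg_idx = tuple(np.array([(dy + R, dx + R) for dy, dx in template.bg_offsets]).T)
    fg_vals = window[fg_idx]
    bg_vals = window[bg_idx]
    if std_region == "window":
        std = float(window.std())
    elif std_region == "bg":
        std = float(bg_vals.std())
    else:
        std = float(np.concatenate([fg_vals, bg_vals]).std())
    if std == 0:
        return 0.0
    return float((fg_vals.mean() - bg_vals.mean()) / std)


class TemplateFamilyScorer:
    """Vectorised SNR scoring of many candidates against the whole family.

    Foreground/background masks are flattened into (n_templates, window_px)
    indicator matrices so that scoring a batch of windows reduces to a pair
    of matrix products.
    """

    def __init__(self, family: list[EllipseTemplate], window_radius: int,
                 std_region: str = "region"):
        self.family = family
        self.radius = window_radius
        self.std_region = std_region
        W = 2 * window_radius + 1
        self.window_px = W * W
        T = len(family)
        F = np.zeros((T, self.window_px), dtype=np.float32)
        B = np.zeros((T, self.window_px), dtype=np.float32)
        for i, t in enumerate(family):
            for dy, dx in t.fg_offsets:
                F[i, (dy + window_radius) * W + (dx + window_radius)] = 1.0
            for dy, dx in t.bg_offsets:
                B[i, (dy + window_radius) * W + (dx + window_radius)] = 1.0
        self.F = F
        self.B = B
        self.nf = F.sum(axis=1)
        self.nb = B.sum(axis=1)

    def score(self, windows: np.ndarray) -> np.ndarray:
        """SNR of each window (rows) against each template (columns)."""
        Wm = np.ascontiguousarray(windows, dtype=np.float32)
        sq = Wm * Wm
        fg_sum = Wm @ self.F.T
        bg_sum = Wm @ self.B.T
        diff = fg_sum / self.nf - bg_sum / self.nb
        if self.std_region == "window":
            var = sq.mean(axis=1) - Wm.mean(axis=1) ** 2
            std = np.sqrt(np.clip(var, 0.0, None))[:, None]
            std = np.broadcast_to(std, diff.shape)
        elif self.std_region == "bg":
            bg_sq = sq @ self.B.T
            var = bg_sq / self.nb - (bg_sum / self.nb) ** 2
            std = np.sqrt(np.clip(var, 0.0, None))
        else:
            fg_sq = sq @ self.F.T
            bg_sq = sq @ self.B.T
            n = self.nf + self.nb
            s1 = fg_sum + bg_sum
            var = (fg_sq + bg_sq) / n - (s1 / n) ** 2
            std = np.sqrt(np.clip(var, 0.0, None))
        snr = np.zeros_like(diff)
        ok = std > 1e-6
        snr[ok] = diff[ok] / std[ok]
        return snr

    def best(self, windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Index of the winning template and its SNR, per window row."""
        snr = self.score(windows)
        idx = np.argmax(snr, axis=1)  # family sorted; first max = tie-break
        return idx, snr[np.arange(len(idx)), idx]


def _reflect_indices(idx: np.ndarray, n: int) -> np.ndarray:
    """Map out-of-range indices back into [0, n) by symmetric reflection."""
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * n
    idx = np.mod(idx, period)
    return np.where(idx >= n, period - 1 - idx, idx)


def extract_window(plane: np.ndarray, y: int, x: int, radius: int) -> np.ndarray:
    """The (2R+1)^2 patch centred at (y, x), reflection-padded at borders."""
    ys = _reflect_indices(np.arange(y - radius, y + radius + 1), plane.shape[0])
    xs = _reflect_indices(np.arange(x - radius, x + radius + 1), plane.shape[1])
    return plane[np.ix_(ys, xs)]


def extract_windows(plane: np.ndarray, ys: np.ndarray, xs: np.ndarray, radius: int) -> np.ndarray:
    """Flattened windows for many (y, x) centres on one plane."""
    W = 2 * radius + 1
    out = np.empty((len(ys), W * W), dtype=np.float32)
    for i, (y, x) in enumerate(zip(ys, xs)):
        out[i] = extract_window(plane, int(y), int(x), radius).ravel()
    return out


def best_template(
    vol: ImageVolume,
    peak: CandidatePeak,
    family: list[EllipseTemplate],
    config: DetectionConfig | None = None,
) -> TemplateFit:
    """The family member maximising single-plane SNR at a candidate.

    Ties are broken towards smaller area, then smaller roundness, then
    smaller angle (the family's sort order).  ``snr3``/``snr7`` are filled
    in later by the slice-averaging stage.
    """
    config = config or DetectionConfig()
    scorer = TemplateFamilyScorer(family, config.window_radius, config.snr_std_region)
    window = extract_window(vol.voxels[peak.z], peak.y, peak.x, config.window_radius)
    idx, snr = scorer.best(window.ravel()[None, :])
    return TemplateFit(peak, family[int(idx[0])], float(snr[0]))
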