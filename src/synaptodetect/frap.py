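"""FRAP trace normalisation and one-phase decay fitting.

Recovery of fluorescence after photobleaching is fit over 0-30 min with

    Y(t) = (Y0 - Plateau) * exp(-k t) + Plateau

where Plateau is the maximum (asymptotic) fluorescence, Y0 the starting
fluorescence immediately after the bleach, k the recovery rate constant in
1/min and tau = 1/k.  The plateau, relative to the normalised pre-bleach
level, gives the mobile receptor fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class FrapFit:
    """One-phase decay fit result."""

    y0: float
    plateau: float
    k: float
    residual_sse: float
    n_points_used: int
    degenerate: bool = False

    @property
    def tau(self) -> float:
        return 1.0 / self.k if self.k > 0 else float("nan")

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (self.y0 - self.plateau) * np.exp(-self.k * t) + self.plateau

    def summary(self) -> str:
        lines = [
            "One-phase decay fit  Y(t) = (Y0 - Plateau) exp(-k t) + Plateau",
            f"  Y0       = {self.y0:.4f}",
            f"  Plateau  = {self.plateau:.4f}",
            f"  k        = {self.k:.4f} /min",
            f"  tau      = {self.tau:.2f} min",
            f"  SSE      = {self.residual_sse:.3e}  (n = {self.n_points_used})",
        ]
        if self.degenerate:
            lines.append("  [degenerate: flat trace, rate unidentifiable]")
        return "\n".join(lines)


def _coerce_trace(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, pd.DataFrame):
        tcol = "t_min" if "t_min" in trace.columns else trace.columns[0]
        vcol = "value" if "value" in trace.columns else trace.columns[1]
        return trace[tcol].to_numpy(float), trace[vcol].to_numpy(float)
    t, y = trace
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def normalize_frap(
    bleached_traces, unbleached_traces, baseline_mask
) -> np.ndarray:
    """Normalise bleached traces by the unbleached population and baseline.

    Each bleached trace is divided pointwise by the per-timepoint mean of
    the unbleached traces (cancelling imaging drift), then scaled so that
    its own mean over the baseline window equals 1.
    """
    bleached = np.atleast_2d(np.asarray(bleached_traces, dtype=float))
    unbleached = np.atleast_2d(np.asarray(unbleached_traces, dtype=float))
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    if bleached.shape[1] != unbleached.shape[1]:
        raise ValueError("bleached and unbleached traces must share timepoints")
    if baseline_mask.shape[0] != bleached.shape[1]:
        raise ValueError("baseline mask length must match the timepoints")
    if not baseline_mask.any():
        raise ValueError("baseline window is empty")
    ref = unbleached.mean(axis=0)
    if np.any(ref == 0):
        raise ValueError("unbleached mean is zero at some timepoint")
    out = bleached / ref
    base = out[:, baseline_mask].mean(axis=1)
    if np.any(base == 0):
        raise ValueError("zero baseline mean after reference normalisation")
    return out / base[:, None]


def fit_frap(trace, t_max: float = 30.0, robust: bool = False) -> FrapFit:
    """Least-squares one-phase decay fit over timepoints in [0, t_max].

    Initialisation: Y0 = value at the earliest timepoint, Plateau = value at
    the latest, k from a log-linear regression of |Plateau - Y|; bounds
    k > 0, 0 <= Plateau <= 2.  The fit is invariant to the ordering of the
    input timepoints.  A flat trace is flagged degenerate (plateau = the
    constant, rate unidentifiable) rather than fabricated.  With
    ``robust=True`` one pass discards points with absolute studentized
    residual > 3 and refits.
    """
    t, y = _coerce_trace(trace)
    if not np.all(np.isfinite(y)):
        raise ValueError("trace values must be finite")
    sel = (t >= 0) & (t <= t_max)
    t, y = t[sel], y[sel]
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if len(t) < 4:
        raise ValueError(f"need at least 4 timepoints in [0, {t_max}], got {len(t)}")

    if np.ptp(y) < 1e-12:
        c = float(y[0])
        return FrapFit(c, c, float("nan"), 0.0, len(t), degenerate=True)

    fit = _fit_once(t, y)
    if robust and len(t) > 4:
        r = y - fit.predict(t)
        s = r.std(ddof=1)
        if s > 0:
            keep = np.abs(r / s) <= 3.0
            if keep.sum() >= 4 and not keep.all():
                fit = _fit_once(t[keep], y[keep])
    return fit


def _fit_once(t: np.ndarray, y: np.ndarray) -> FrapFit:
    y0_init = float(y[0])
    plateau_init = float(np.clip(y[-1], 0.0, 2.0))
    k_init = _k_init(t, y, plateau_init)
    x0 = np.array([np.clip(y0_init, 0.0, 2.0), plateau_init, k_init])

    def resid(p):
        y0, plateau, k = p
        return (y0 - plateau) * np.exp(-k * t) + plateau - y

    res = least_squares(
        resid,
        x0,
        bounds=([0.0, 0.0, 1e-6], [2.0, 2.0, 10.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
        max_nfev=5000,
    )
    if not res.success:
        raise RuntimeError(f"one-phase decay fit did not converge: {res.message}")
    y0, plateau, k = res.x
    sse = float(np.sum(res.fun**2))
    return FrapFit(float(y0), float(plateau), float(k), sse, len(t))


def _k_init(t: np.ndarray, y: np.ndarray, plateau: float) -> float:
    """Rate-constant seed from a log-linear regression of |Plateau - Y|."""
    d = np.abs(plateau - y)
    ok = d > 1e-9
    if ok.sum() >= 2 and np.ptp(t[ok]) > 0:
        slope = np.polyfit(t[ok], np.log(d[ok]), 1)[0]
        if slope < 0:
            return float(np.clip(-slope, 1e-3, 10.0))
    return 0.1


def mobile_fraction(fit: FrapFit, prebleach: float = 1.0) -> float:
    """Fraction of the bleached signal recovered in the exponential phase:
    (plateau - y0) / (prebleach - y0)."""
    if prebleach <= fit.y0:
        raise ValueError("prebleach level must exceed the post-bleach Y0")
    return (fit.plateau - fit.y0) / (prebleach - fit.y0)
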