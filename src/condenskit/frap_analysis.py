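"""FRAP quantification: background subtraction, three-region normalization,
replicate averaging, and a single-exponential recovery fit.

The normalization follows the three-region scheme: region 1 is the bleached
spot within a condensate, region 2 a control region on an unbleached
condensate, region 3 the entire bleached condensate.  The default ("literal")
mode computes ``n(t) = (I1(t) − I2(t)) / I3(t)`` frame by frame, which
cancels any per-frame multiplicative gain (laser fluctuations); an
alternative ("divisive") mode computes ``n(t) = I1(t) / I2(t)``, i.e. region
1 divided by the control's trace, which additionally cancels acquisition
photobleaching and remains well-defined when the control condensate is as
bright as the bleached spot was before the bleach (a case in which the
additive subtraction is degenerate).  Either way the trace is then scaled so
the prebleach mean is 1 and reported as fractional recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import ImageStack, RoiSet

__all__ = [
    "FrapCurve",
    "RecoveryFit",
    "subtract_image_background",
    "extract_frap_curve",
    "average_curves",
    "fit_recovery",
]


@dataclass
class FrapCurve:
    """Raw three-region traces plus the normalized fractional-recovery trace."""

    t_s: np.ndarray
    i1: np.ndarray  # bleached spot
    i2: np.ndarray  # unbleached control condensate
    i3: np.ndarray  # whole bleached condensate
    bleach_frame: int
    n_raw: np.ndarray
    normalized: np.ndarray
    mode: str
    frame_interval: float

    def __post_init__(self) -> None:
        lengths = {len(self.t_s), len(self.i1), len(self.i2), len(self.i3),
                   len(self.n_raw), len(self.normalized)}
        if len(lengths) != 1:
            raise ValueError("all FRAP traces must have equal length")
        if not 0 < self.bleach_frame < len(self.t_s):
            raise ValueError("bleach_frame out of range")


@dataclass
class RecoveryFit:
    """Single-exponential recovery: N(t) = F0 + (F∞−F0)(1 − e^{−(t−t_b)/τ})."""

    f0: float
    f_inf: float
    tau_s: float
    mobile_fraction: float
    residual_rms: float
    clamped: bool = False
    tau_unidentifiable: bool = False


def subtract_image_background(
    stack: ImageStack, background_rois: RoiSet
) -> ImageStack:
    """Subtract the per-frame mean over background-ROI pixels from each frame.

    Background regions must contain no condensates; negative results are
    permitted (the output is floating point).
    """
    shape = stack.pixels.shape[-2:]
    mask = background_rois.role_mask("background", shape)
    non_bg_roles = {r.role for r in background_rois.rois.values()} - {"background"}
    for role in non_bg_roles:
        other = background_rois.role_mask(role, shape)
        if (mask & other).any():
            warnings.warn(
                f"background ROI overlaps a {role!r} ROI; background estimate "
                "may be contaminated",
                stacklevel=2,
            )
    pixels = stack.pixels.astype(float).copy()
    for f in range(stack.n_frames):
        for c in range(stack.n_channels):
            pixels[f, c] -= pixels[f, c][mask].mean()
    return ImageStack(
        pixels=pixels,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
        channel_names=stack.channel_names,
    )


def extract_frap_curve(
    stack: ImageStack,
    rois: RoiSet,
    bleach_frame: int,
    mode: str = "literal",
    eps_rel: float = 1e-6,
    channel: int = 0,
) -> FrapCurve:
    """Extract the three region traces and the normalized recovery curve.

    Expects a background-subtracted stack.  ``bleach_frame`` is the 0-based
    index of the first post-bleach frame, so frames ``0..bleach_frame-1``
    form the prebleach window.  See the module docstring for the two
    normalization modes; the literal mode errors when the prebleach
    normalizer is degenerate (|prebleach mean| below ``eps_rel`` times the
    prebleach region-3 scale), in which case the divisive mode applies.
    """
    if mode not in ("literal", "divisive"):
        raise ValueError(f"unknown mode {mode!r}; use 'literal' or 'divisive'")
    shape = stack.pixels.shape[-2:]
    m1 = rois.role_mask("bleached", shape)
    m2 = rois.role_mask("control", shape)
    m3 = rois.role_mask("whole_condensate", shape)
    frames = stack.pixels[:, channel].astype(float)
    i1 = frames[:, m1].mean(axis=1)
    i2 = frames[:, m2].mean(axis=1)
    i3 = frames[:, m3].mean(axis=1)
    if bleach_frame < 1:
        raise ValueError("need at least one prebleach frame")
    if bleach_frame >= stack.n_frames:
        raise ValueError("bleach_frame beyond the end of the movie")

    if mode == "literal":
        if np.any(i3 <= 0):
            raise ValueError(
                "region-3 intensity <= 0; check background subtraction/ROI"
            )
        n_raw = (i1 - i2) / i3
    else:
        if np.any(i2 <= 0):
            raise ValueError("control-region intensity <= 0 in divisive mode")
        n_raw = i1 / i2

    pre = n_raw[:bleach_frame]
    pre_scale = float(np.mean(np.abs(i3[:bleach_frame])))
    pre_mean = float(pre.mean())
    if abs(pre_mean) < eps_rel * max(pre_scale, 1e-300):
        raise ValueError(
            "degenerate prebleach normalizer (control matches the bleached "
            "spot); use mode='divisive'"
        )
    normalized = n_raw / pre_mean
    return FrapCurve(
        t_s=stack.times,
        i1=i1,
        i2=i2,
        i3=i3,
        bleach_frame=bleach_frame,
        n_raw=n_raw,
        normalized=normalized,
        mode=mode,
        frame_interval=stack.frame_interval,
    )


def average_curves(curves: list[FrapCurve]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean ± SEM over replicate curves aligned at the bleach frame.

    Returns ``(t_rel_s, mean, sem)`` where ``t_rel_s`` is time relative to
    the bleach frame over the frames common to all curves.  Requires >= 2
    curves with identical frame intervals; the result is invariant to the
    input order.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to average")
    dts = {round(c.frame_interval, 12) for c in curves}
    if len(dts) != 1:
        raise ValueError(f"mismatched frame intervals: {sorted(dts)}")
    pre = min(c.bleach_frame for c in curves)
    post = min(len(c.t_s) - c.bleach_frame for c in curves)
    aligned = np.stack(
        [c.normalized[c.bleach_frame - pre : c.bleach_frame + post] for c in curves]
    )
    # column-wise sort makes the reduction exactly input-order invariant
    aligned = np.sort(aligned, axis=0)
    mean = aligned.mean(axis=0)
    sem = aligned.std(axis=0, ddof=1) / np.sqrt(len(curves))
    t_rel = (np.arange(-pre, post)) * curves[0].frame_interval
    return t_rel, mean, sem


def _recovery_model(t, f0, f_inf, tau):
    return f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau))


def fit_recovery(curve: FrapCurve, min_post_points: int = 10) -> RecoveryFit:
    """Least-squares single-exponential fit on the post-bleach frames.

    Initialization: F0 = first post-bleach value, F∞ = mean of the last 10%
    of frames, τ = time to half-plateau; a small multi-start over τ guards
    against poor initial curvature.  The mobile fraction
    ``f_m = (F∞ − F0)/(1 − F0)`` is clamped to [0, 1] with a flag; a flat
    curve yields ``f_m = 0`` with τ flagged unidentifiable.
    """
    post = slice(curve.bleach_frame, None)
    t_post = curve.t_s[post] - curve.t_s[curve.bleach_frame]
    y = curve.normalized[post]
    if y.size < min_post_points:
        raise ValueError(f"need >= {min_post_points} post-bleach points")

    f0_init = float(y[0])
    tail = max(1, y.size // 10)
    finf_init = float(y[-tail:].mean())

    if abs(finf_init - f0_init) < 1e-9 or np.ptp(y) < 1e-12:
        return RecoveryFit(
            f0=f0_init,
            f_inf=finf_init,
            tau_s=float("nan"),
            mobile_fraction=0.0,
            residual_rms=float(np.sqrt(np.mean((y - y.mean()) ** 2))),
            tau_unidentifiable=True,
        )

    half = f0_init + 0.5 * (finf_init - f0_init)
    rising = finf_init >= f0_init
    crossed = np.nonzero(y >= half if rising else y <= half)[0]
    tau_init = float(t_post[crossed[0]]) if crossed.size else float(t_post[-1] / 3)
    tau_init = max(tau_init, curve.frame_interval)

    best = None
    for tau0 in (tau_init, tau_init / 3, tau_init * 3):
        try:
            popt, _ = curve_fit(
                _recovery_model,
                t_post,
                y,
                p0=[f0_init, finf_init, tau0],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        rms = float(np.sqrt(np.mean((_recovery_model(t_post, *popt) - y) ** 2)))
        if best is None or rms < best[0]:
            best = (rms, popt)
    if best is None:
        raise RuntimeError("recovery fit failed to converge from every start")
    rms, (f0, f_inf, tau) = best
    if f_inf < f0:
        warnings.warn("fitted plateau lies below the post-bleach floor", stacklevel=2)
    denom = 1.0 - f0
    fm = (f_inf - f0) / denom if abs(denom) > 1e-12 else float("nan")
    clamped = False
    if np.isfinite(fm) and not 0.0 <= fm <= 1.0:
        fm = float(np.clip(fm, 0.0, 1.0))
        clamped = True
    return RecoveryFit(
        f0=float(f0),
        f_inf=float(f_inf),
        tau_s=float(tau),
        mobile_fraction=float(fm),
        residual_rms=rms,
        clamped=clamped,
    )
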