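"""Sigmoid state definitions and dissociation-transition detection.

The bound ensemble of each descriptor shows a bell-shaped distribution.  A
logistic membership function

    m(x) = 1 / (1 + exp(-s (x - x0)))

is fitted to one half of that bell (the half the descriptor moves through
when the complex dissociates): the right side for the centre-of-mass
distance and for SASA, which grow during dissociation, and the left side
for the fraction of native contacts, which shrinks.  The product of two
memberships is the state curve: 1 in the bound basin, smoothly approaching
0 as the complex dissociates.  The first sustained drop of the
distance x Q state below 0.5 marks the start of dissociation; the first
sustained drop of the Q x SASA state below 0.05 marks the start of the
unbound state.  Frames in between are the encounter complex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .descriptors import DescriptorSeries
from .errors import (
    AlignmentError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "SigmoidFit",
    "StateSeries",
    "TransitionReport",
    "sigmoid",
    "fit_half_bell",
    "state_curve",
    "detect_transition",
    "classify_states",
    "fit_state_model",
]


@dataclass
class SigmoidFit:
    """Fitted logistic membership: slope ``s`` (signed) and midpoint ``x0``."""

    s: float
    x0: float
    side: str
    fit_residual: float = 0.0

    def membership(self, x) -> np.ndarray:
        return sigmoid(x, self.s, self.x0)


@dataclass
class StateSeries:
    values: np.ndarray
    descriptors_used: tuple[str, str]
    frame_spacing: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TransitionReport:
    t_dissociation: Optional[int]
    t_unbound: Optional[int]
    threshold_dissociation: float
    threshold_unbound: float
    min_dwell: int


def sigmoid(x, s: float, x0: float) -> np.ndarray:
    """Logistic membership 1/(1+exp(-s(x-x0))); saturates at float extremes."""
    z = np.clip(np.asarray(x, dtype=float) - x0, -1e300, 1e300) * s
    return 1.0 / (1.0 + np.exp(-np.clip(z, -700.0, 700.0)))


def _histogram_fd(values: np.ndarray):
    """Density histogram with Freedman-Diaconis bin width."""
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise DegenerateFitError("inter-quartile range is zero (flat distribution)")
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    n_bins = max(3, int(np.ceil((values.max() - values.min()) / width)))
    # descriptors with few distinct levels (e.g. a contact fraction) would
    # otherwise produce a comb histogram with empty bins between levels
    n_bins = min(n_bins, len(np.unique(values)))
    counts, edges = np.histogram(values, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def fit_half_bell(
    values: DescriptorSeries | np.ndarray,
    side: str,
    min_samples: int = 100,
) -> SigmoidFit:
    """Fit a logistic to one rescaled half of the bound-state distribution.

    A Freedman-Diaconis histogram is built, its mode located (ties broken
    toward the side that maximises the fitted half's span), the chosen half
    rescaled so the mode bin maps to 1, and the logistic least-squares
    fitted to (bin centre, rescaled height).  Right-side fits return a
    negative slope (decreasing membership), left-side fits a positive one.
    """
    if side not in ("left", "right"):
        raise InvalidParameterError("side must be 'left' or 'right'")
    vals = values.values if isinstance(values, DescriptorSeries) else np.asarray(values)
    vals = vals[np.isfinite(vals)]
    if len(vals) < min_samples:
        raise InsufficientDataError(
            f"need at least {min_samples} samples, got {len(vals)}"
        )
    counts, centers = _histogram_fd(vals)
    mode_candidates = np.flatnonzero(counts == counts.max())
    mode_idx = int(mode_candidates[0] if side == "right" else mode_candidates[-1])
    if side == "right":
        half_x = centers[mode_idx:]
        half_y = counts[mode_idx:]
    else:
        half_x = centers[: mode_idx + 1]
        half_y = counts[: mode_idx + 1]
    if len(half_x) < 3 or half_y.max() == 0:
        raise DegenerateFitError("histogram half too flat/narrow to fit")
    half_y = half_y / half_y.max()
    # the density is zero beyond the sampled range; encode that with
    # explicit zero bins (half again the half's span), otherwise the fit
    # under-weights the tail and the bound-basin membership sags
    step = np.mean(np.diff(half_x)) if len(half_x) > 1 else 1.0
    n_pad = max(2, len(half_x) // 2)
    if side == "right":
        pad = half_x[-1] + step * np.arange(1, n_pad + 1)
        half_x = np.concatenate([half_x, pad])
        half_y = np.concatenate([half_y, np.zeros(n_pad)])
        mode_pos = 0
    else:
        pad = half_x[0] - step * np.arange(n_pad, 0, -1)
        half_x = np.concatenate([pad, half_x])
        half_y = np.concatenate([np.zeros(n_pad), half_y])
        mode_pos = len(half_x) - 1
    # the mode bin maps to 1 by construction: anchor it with a strong weight
    weights = np.ones(len(half_x))
    weights[mode_pos] = 0.1

    sign = -1.0 if side == "right" else 1.0
    span = abs(half_x[-1] - half_x[0]) or abs(centers[-1] - centers[0]) or 1.0
    # midpoint guess: first crossing of 0.5 walking away from the mode
    order = np.arange(len(half_x)) if side == "right" else np.arange(len(half_x))[::-1]
    x0_guess = half_x[order[-1]]
    for i in order:
        if half_y[i] <= 0.5:
            x0_guess = half_x[i]
            break
    p0 = (sign * 4.0 / span, x0_guess)
    bounds = ((-np.inf, -np.inf), (0.0, np.inf)) if side == "right" else (
        (0.0, -np.inf),
        (np.inf, np.inf),
    )
    try:
        popt, _ = curve_fit(
            lambda x, s, x0: sigmoid(x, s, x0),
            half_x,
            half_y,
            p0=p0,
            sigma=weights,
            bounds=bounds,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise DegenerateFitError(f"logistic fit did not converge: {exc}") from exc
    s, x0 = popt
    if s == 0:
        raise DegenerateFitError("fitted slope is zero")
    # the histogram half decays toward its far tail; a fit that stays above
    # one half there did not resolve the flank (too few informative bins)
    far_x = half_x[-1] if side == "right" else half_x[0]
    if float(sigmoid(far_x, s, x0)) > 0.5:
        raise DegenerateFitError(
            "fitted membership does not decay across the histogram half"
        )
    residual = float(np.sum((sigmoid(half_x, s, x0) - half_y) ** 2))
    return SigmoidFit(s=float(s), x0=float(x0), side=side, fit_residual=residual)


def _fallback_fit(values: np.ndarray, side: str) -> SigmoidFit:
    """Step-like membership for a (near-)degenerate bound distribution.

    When the bound ensemble barely fluctuates, the histogram cannot
    constrain a logistic.  The membership then falls off five sample
    standard deviations away from the bound value (a strictly positive
    floor keeps the zero-noise case well defined as a step).
    """
    mode = float(np.median(values))
    scale = max(float(np.std(values)), 1e-9)
    sign = -1.0 if side == "right" else 1.0
    return SigmoidFit(s=sign * 2.0 / scale, x0=mode - sign * 5.0 * scale, side=side)


def fit_state_model(
    bound_descriptors: dict[str, DescriptorSeries | np.ndarray],
    min_samples: int = 100,
) -> dict[str, SigmoidFit]:
    """Fit the three membership functions on a bound reference window.

    Distance and SASA dissociate upward (right-side fits); the fraction of
    native contacts dissociates downward (left-side fit).  Degenerate bound
    distributions fall back to a steep membership around the bound value.
    """
    sides = {"com_distance": "right", "q_native": "left", "sasa": "right"}
    fits = {}
    for name, side in sides.items():
        series = bound_descriptors[name]
        vals = series.values if isinstance(series, DescriptorSeries) else series
        try:
            fits[name] = fit_half_bell(vals, side, min_samples=min_samples)
        except DegenerateFitError:
            fits[name] = _fallback_fit(np.asarray(vals, dtype=float), side)
    return fits


def state_curve(
    series1: DescriptorSeries,
    fit1: SigmoidFit,
    series2: DescriptorSeries,
    fit2: SigmoidFit,
) -> StateSeries:
    """Product of the two fitted memberships, per frame."""
    if len(series1) != len(series2):
        raise AlignmentError(
            f"series lengths differ: {len(series1)} vs {len(series2)}"
        )
    values = fit1.membership(series1.values) * fit2.membership(series2.values)
    return StateSeries(
        values=values,
        descriptors_used=(series1.name, series2.name),
        frame_spacing=series1.frame_spacing,
    )


def detect_transition(
    state: StateSeries | np.ndarray,
    threshold: float,
    min_dwell: int = 1,
) -> Optional[int]:
    """First frame where the state drops below threshold for min_dwell frames.

    Returns ``None`` when no sustained drop exists.  Lowering the threshold
    can only delay (never advance) the detected frame.
    """
    if not (0 < threshold < 1):
        raise InvalidParameterError("threshold must be in (0, 1)")
    if min_dwell < 1:
        raise InvalidParameterError("min_dwell must be >= 1")
    values = state.values if isinstance(state, StateSeries) else np.asarray(state)
    below = values < threshold
    if min_dwell > len(below):
        return None
    run = np.convolve(below.astype(int), np.ones(min_dwell, dtype=int), mode="valid")
    hits = np.flatnonzero(run == min_dwell)
    return int(hits[0]) if hits.size else None


def classify_states(
    descriptors: dict[str, DescriptorSeries],
    fits: dict[str, SigmoidFit],
    threshold_dissociation: float = 0.5,
    threshold_unbound: float = 0.05,
    min_dwell: int | None = None,
) -> tuple[np.ndarray, TransitionReport]:
    """Label every frame bound / encounter / unbound.

    The distance x Q state detects the start of dissociation at the
    logistic midpoint (threshold 0.5); the Q x SASA state detects the start
    of the unbound state where it approaches zero (threshold 0.05).  The
    default dwell is 1% of the trajectory length, at least 10 frames, so
    single-frame flickers do not trigger a transition.  If the unbound
    transition precedes the detected dissociation start, the latter is
    clamped so that bound <= encounter <= unbound always holds.
    """
    com = descriptors["com_distance"]
    q = descriptors["q_native"]
    area = descriptors["sasa"]
    n = len(com)
    if min_dwell is None:
        min_dwell = max(10, n // 100)
    min_dwell = min(min_dwell, n)

    diss_state = state_curve(com, fits["com_distance"], q, fits["q_native"])
    unb_state = state_curve(q, fits["q_native"], area, fits["sasa"])
    t_diss = detect_transition(diss_state, threshold_dissociation, min_dwell)
    t_unb = detect_transition(unb_state, threshold_unbound, min_dwell)
    if t_unb is not None and (t_diss is None or t_diss > t_unb):
        t_diss = t_unb

    labels = np.array(["bound"] * n, dtype=object)
    if t_diss is not None:
        labels[t_diss:] = "encounter"
    if t_unb is not None:
        labels[t_unb:] = "unbound"
    report = TransitionReport(
        t_dissociation=t_diss,
        t_unbound=t_unb,
        threshold_dissociation=threshold_dissociation,
        threshold_unbound=threshold_unbound,
        min_dwell=min_dwell,
    )
    return labels, report
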