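"""Microtubule biochemistry readouts.

Three small quantifications used to compare microtubule stability across
conditions:

* assembled-tubulin fraction from a fractionation blot — pellet band
  (polymerized tubulin, P) over total (P + supernatant S), as a percent;
* loading-normalized band intensity relative to a reference condition
  (fold of, e.g., control cells under vehicle);
* summaries of a turbidity polymerization curve (A340 vs time): lag
  time, maximal growth slope and final plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "percent_assembled",
    "relative_band",
    "turbidity_summary",
    "TurbiditySummary",
]


def percent_assembled(pellet: float, supernatant: float) -> float:
    """Percent assembled tubulin: 100 * P / (P + S).

    P and S are band intensities (arbitrary units >= 0) of the pellet
    (microtubule) and supernatant (soluble tubulin) fractions.
    """
    p = np.asarray(pellet, dtype=float)
    s = np.asarray(supernatant, dtype=float)
    if np.any(p < 0) or np.any(s < 0):
        raise ValueError("band intensities must be >= 0")
    total = p + s
    if np.any(total <= 0):
        raise ValueError("P + S must be > 0")
    out = 100.0 * p / total
    return out.item() if out.ndim == 0 else out


def relative_band(target: float, loading: float, ref_target: float, ref_loading: float) -> float:
    """Loading-normalized band level as fold of a reference condition.

    ``(target/loading) / (ref_target/ref_loading)``; the reference
    condition against itself is exactly 1.
    """
    vals = np.asarray([target, loading, ref_target, ref_loading], dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("all band intensities must be finite and > 0")
    return float((target / loading) / (ref_target / ref_loading))


@dataclass
class TurbiditySummary:
    lag_time_min: float       # NaN when the curve never clears the lag criterion
    max_slope_per_min: float  # A340/min
    plateau: float            # A340
    lag_defined: bool


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    ypad = np.pad(y, pad, mode="edge")
    return np.convolve(ypad, kernel, mode="valid")[: len(y)]


def turbidity_summary(
    time_min,
    a340,
    smooth_window: int = 5,
    lag_fraction: float = 0.1,
) -> TurbiditySummary:
    """Summarize a tubulin polymerization turbidity curve.

    * plateau: mean of the final 10% of points (at least one point);
    * max slope: maximum slope of centered 5-point linear fits;
    * lag time: first time the smoothed curve exceeds
      ``initial + lag_fraction * (plateau - initial)``; flagged
      undefined for flat curves.

    Requires >= 10 strictly increasing time points.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(a340, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and absorbance must be 1-D and the same length")
    if len(t) < 10:
        raise ValueError("need at least 10 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    if not np.all(np.isfinite(y)):
        raise ValueError("absorbance values must be finite")

    n_tail = max(1, int(round(0.1 * len(t))))
    plateau = float(np.mean(y[-n_tail:]))

    # centered 5-point local slopes
    half = 2
    slopes = [
        np.polyfit(t[i - half : i + half + 1], y[i - half : i + half + 1], 1)[0]
        for i in range(half, len(t) - half)
    ]
    max_slope = float(np.max(slopes)) if slopes else 0.0

    smoothed = _moving_average(y, smooth_window)
    initial = float(smoothed[0])
    rise = plateau - initial
    if abs(rise) < 1e-12:
        return TurbiditySummary(np.nan, max_slope, plateau, lag_defined=False)
    level = initial + lag_fraction * rise
    above = np.nonzero(smoothed > level)[0] if rise > 0 else np.nonzero(smoothed < level)[0]
    if above.size == 0:
        return TurbiditySummary(np.nan, max_slope, plateau, lag_defined=False)
    return TurbiditySummary(float(t[above[0]]), max_slope, plateau, lag_defined=True)
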