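"""Dose-response curve fitting and simple viability/tumor summaries.

The central fit is the four-parameter logistic (4PL, variable slope) in
log10 dose:

    y(d) = bottom + (top - bottom) / (1 + 10**(hill * (log10(d) - log10(IC50))))

With hill > 0 the curve falls with dose and IC50 is the concentration at
the midpoint between the fitted plateaus.  Vehicle wells (dose 0) anchor
the top plateau via the initial guess but are excluded from the log-dose
least squares.  Degenerate inputs (flat response, |hill| < 0.1,
non-convergence) yield status 'undetermined' rather than a fabricated
number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "four_pl",
    "fit_ic50",
    "ic50_fold_change",
    "relative_survival",
    "colony_efficiency",
    "tumor_volume",
    "IC50Fit",
]

#: fits with fitted dynamic range below this are reported undetermined
MIN_DYNAMIC_RANGE = 0.05
#: fits shallower than this Hill slope magnitude are reported undetermined
MIN_HILL = 0.1


def four_pl(dose, bottom, top, log10_ic50, hill):
    """4PL response at ``dose`` (>0); decreasing in dose when hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (np.log10(dose) - log10_ic50)))


@dataclass
class IC50Fit:
    """Result of a 4PL dose-response fit."""

    status: str                       # 'ok' | 'undetermined'
    ic50: float = np.nan              # same unit as the input doses
    bottom: float = np.nan
    top: float = np.nan
    hill: float = np.nan
    log10_ic50: float = np.nan
    se: dict = field(default_factory=dict)   # parameter standard errors
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def fit_ic50(concentration, response) -> IC50Fit:
    """Fit a variable-slope 4PL and report the IC50.

    ``concentration`` in any consistent unit (e.g. nM); zero entries are
    vehicle wells used only to seed the top plateau.  ``response`` is
    viability as fraction of vehicle.  Requires >= 5 distinct positive
    concentrations.
    """
    conc = np.asarray(concentration, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentration and response must have the same length")
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0 (0 = vehicle)")

    pos = conc > 0
    x = conc[pos]
    y = resp[pos]
    if len(np.unique(x)) < 5:
        raise ValueError("need >= 5 distinct positive concentrations")

    vehicle = resp[~pos]
    top0 = float(np.mean(vehicle)) if vehicle.size else float(np.max(y))
    bottom0 = float(np.min(y))
    if np.ptp(y) < MIN_DYNAMIC_RANGE:
        return IC50Fit(status="undetermined", message="flat response")

    # midpoint dose as IC50 seed
    half = (top0 + bottom0) / 2.0
    idx = int(np.argmin(np.abs(y - half)))
    p0 = (bottom0, top0, float(np.log10(x[idx])), 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        try:
            popt, pcov = optimize.curve_fit(
                four_pl, x, y, p0=p0, maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            return IC50Fit(status="undetermined", message=f"no convergence: {exc}")

    bottom, top, log10_ic50, hill = (float(v) for v in popt)
    if top < bottom:  # reparameterize so top > bottom, flipping the slope
        bottom, top, hill = top, bottom, -hill
    if (top - bottom) < MIN_DYNAMIC_RANGE:
        return IC50Fit(status="undetermined", message="fitted dynamic range below tolerance")
    if abs(hill) < MIN_HILL:
        return IC50Fit(status="undetermined", message="fitted Hill slope below tolerance")

    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(4, np.nan)
    se = dict(zip(("bottom", "top", "log10_ic50", "hill"), (float(v) for v in perr)))
    return IC50Fit(
        status="ok",
        ic50=float(10.0 ** log10_ic50),
        bottom=bottom,
        top=top,
        hill=hill,
        log10_ic50=log10_ic50,
        se=se,
    )


def ic50_fold_change(fit_num: IC50Fit, fit_den: IC50Fit, ci: float = 0.95):
    """Ratio of two fitted IC50s with a delta-method confidence interval.

    Works on the log10 scale: log10 ratio = log10_ic50_num - log10_ic50_den
    with variance the sum of the two squared standard errors.
    """
    if not (fit_num.ok and fit_den.ok):
        raise ValueError("both fits must have status 'ok'")
    log_ratio = fit_num.log10_ic50 - fit_den.log10_ic50
    var = fit_num.se.get("log10_ic50", np.nan) ** 2 + fit_den.se.get("log10_ic50", np.nan) ** 2
    z = stats.norm.ppf(0.5 + ci / 2.0)
    half = z * np.sqrt(var)
    return {
        "fold_change": float(10.0 ** log_ratio),
        "ci_low": float(10.0 ** (log_ratio - half)),
        "ci_high": float(10.0 ** (log_ratio + half)),
        "ci_level": ci,
    }


def relative_survival(conf_drug: float, conf_vehicle: float) -> float:
    """Relative survival (%): 100 * drug-treated confluence / vehicle confluence."""
    if conf_vehicle <= 0:
        raise ValueError("vehicle confluence must be > 0")
    if conf_drug < 0:
        raise ValueError("drug confluence must be >= 0")
    return 100.0 * conf_drug / conf_vehicle


def colony_efficiency(n_drug: int, n_vehicle: int) -> float:
    """Relative colony-forming efficiency (%): 100 * drug colonies / vehicle colonies."""
    if int(n_vehicle) != n_vehicle or int(n_drug) != n_drug:
        raise ValueError("colony counts must be integers")
    if n_vehicle <= 0:
        raise ValueError("vehicle colony count must be > 0")
    if n_drug < 0:
        raise ValueError("colony counts must be >= 0")
    return 100.0 * n_drug / n_vehicle


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Ellipsoid-approximation tumor volume V = L * W^2 / 2 (mm^3).

    L is the longest and W the shortest caliper dimension; swapped with a
    warning if given in the wrong order.
    """
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("tumor dimensions must be > 0")
    if width_mm > length_mm:
        warnings.warn(
            "width > length; swapping to enforce the longest/shortest convention",
            stacklevel=2,
        )
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm * width_mm / 2.0
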