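"""RBE curve families over dose per fraction and over LET, and crossovers.

RBE falls monotonically from RBEmax (zero dose) to RBEmin (high dose), and
rises with LET up to the turnover. Because tissues with low alpha/beta have
large RBEmax but small RBEmin, while high-alpha/beta tissues are the
reverse, two dose curves at the same LET can cross: above the crossover
dose the high-alpha/beta tissue has the larger RBE.
"""

from __future__ import annotations

from typing import NamedTuple, Optional, Sequence

from scipy.optimize import brentq

from .core import (
    DEFAULT_CALIBRATION,
    PROTON,
    Calibration,
    IonSpec,
    LQParams,
    rbe_at_dose,
)

__all__ = ["CurvePoint", "rbe_dose_curve", "rbe_let_curve", "find_crossover_dose"]

CROSSOVER_BRACKET = (1e-3, 100.0)  # Gy; spans clinical fraction sizes widely
CROSSOVER_TOL = 1e-6  # Gy


class CurvePoint(NamedTuple):
    """One sample of an RBE curve; abscissa is Gy or keV.um^-1 by context."""

    abscissa: float
    rbe: float
    rbe_max: float
    rbe_min: float


def rbe_dose_curve(
    low: LQParams,
    let: float,
    dose_grid: Sequence[float],
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> list[CurvePoint]:
    """RBE vs dose per fraction at fixed LET, sorted by dose."""
    points = []
    for d in sorted(dose_grid):
        r = rbe_at_dose(low, let, d, ion, calib)
        points.append(CurvePoint(d, r.rbe, r.rbe_max, r.rbe_min))
    return points


def rbe_let_curve(
    low: LQParams,
    dose_per_fraction: float,
    let_grid: Sequence[float],
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> list[CurvePoint]:
    """RBE vs LET at fixed dose per fraction, sorted by LET."""
    points = []
    for let in sorted(let_grid):
        r = rbe_at_dose(low, let, dose_per_fraction, ion, calib)
        points.append(CurvePoint(let, r.rbe, r.rbe_max, r.rbe_min))
    return points


def find_crossover_dose(
    low_a: LQParams,
    low_b: LQParams,
    let: float,
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> Optional[float]:
    """Dose per fraction where the two tissues' RBE curves cross, if any.

    Scans the bracket (0.001, 100) Gy for a sign change of
    ``RBE_A(d) - RBE_B(d)`` and refines it by root bracketing to 1e-6 Gy.
    Returns None when the curves do not cross in the bracket (including the
    identical-tissue and zero-LET cases).
    """
    if let < 0:
        raise ValueError("let must be >= 0")

    def diff(d: float) -> float:
        ra = rbe_at_dose(low_a, let, d, ion, calib).rbe
        rb = rbe_at_dose(low_b, let, d, ion, calib).rbe
        return ra - rb

    lo, hi = CROSSOVER_BRACKET
    # geometric scan: dose curves vary fastest near zero dose. Samples at
    # rounding-noise level are treated as zero and skipped unless flanked
    # by genuinely opposite signs, so identical curves (and the zero-LET
    # case, where both RBEs are 1 up to rounding) yield None.
    n_scan = 200
    noise = 1e-12
    ratio = (hi / lo) ** (1.0 / n_scan)
    d_last, f_last = None, 0.0  # last sample clearly away from zero
    for i in range(n_scan + 1):
        d = lo * ratio**i
        f = diff(d)
        if abs(f) <= noise:
            continue
        if f_last != 0.0 and f_last * f < 0:
            return float(brentq(diff, d_last, d, xtol=CROSSOVER_TOL))
        d_last, f_last = d, f
    return None
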