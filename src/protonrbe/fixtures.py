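"""Deterministic generators for SOBP-like grids and synthetic survival tables.

The SOBP (spread-out Bragg peak) grid is a stylised 1-D depth profile
replicated laterally: an entrance dose ramp, a uniform plateau across the
target span, and a short linear distal fall-off; LET rises from 1.5 to 9
keV.um^-1 across the target (the band clinical plans occupy) and keeps
rising, more steeply, through the fall-off — the distal-edge pattern that
makes range-shift hazards biologically meaningful, since a shift carries
both high dose and high LET past the planned boundary. It is not a
transport calculation: no lateral scatter, straggling or nuclear halo.

The survival-table generator emulates an alpha-vs-LET data set: alpha
linear in LET with Gaussian noise, LET spread over (0, 40] so at least one
point lies beyond the proton turnover and exercises the fit's exclusion
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import SurvivalRecord
from .planmaps import DoseLETGrid

__all__ = ["SOBPSpec", "make_sobp_grid", "make_survival_table"]


@dataclass(frozen=True)
class SOBPSpec:
    """Geometry and physics of the stylised SOBP depth profile.

    Depths in mm; doses per fraction in Gy; LET in keV.um^-1. Defaults give
    a 60 mm deep grid at 1 mm spacing with a 2 Gy plateau over 25-45 mm and
    target LET spanning exactly [1.5, 9].
    """

    depth_mm: float = 60.0
    spacing_mm: float = 1.0
    sobp_start_mm: float = 25.0
    sobp_end_mm: float = 45.0
    plateau_dose: float = 2.0
    entrance_dose: float = 1.4      # ~70% of plateau, typical proton entrance
    let_entry: float = 0.5
    let_min_target: float = 1.5
    let_max_target: float = 9.0
    falloff_mm: float = 4.0
    distal_let_slope_factor: float = 3.0  # distal LET rise vs in-target slope
    lateral_voxels: int = 5         # per lateral axis; grid is depth x lat x lat
    target_lateral_margin: int = 1  # lateral voxels outside PTV on each side

    def __post_init__(self) -> None:
        if not 0 < self.sobp_start_mm < self.sobp_end_mm < self.depth_mm:
            raise ValueError("require 0 < sobp_start < sobp_end < depth")
        if not self.let_min_target < self.let_max_target:
            raise ValueError("require let_min_target < let_max_target")
        if self.spacing_mm <= 0 or self.plateau_dose <= 0 or self.falloff_mm <= 0:
            raise ValueError("spacing, plateau_dose and falloff must be positive")
        if self.entrance_dose < 0 or self.let_entry < 0:
            raise ValueError("entrance_dose and let_entry must be >= 0")


def _depth_profile(spec: SOBPSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(depth_mm, dose, let) 1-D arrays for the spec."""
    n = int(round(spec.depth_mm / spec.spacing_mm))
    depth = np.arange(n) * spec.spacing_mm
    dose = np.empty(n)
    let = np.empty(n)
    start, end = spec.sobp_start_mm, spec.sobp_end_mm
    fall_end = end + spec.falloff_mm

    # dose: linear entrance ramp -> plateau -> linear fall-off -> zero
    ramp = depth < start
    dose[ramp] = spec.entrance_dose + (
        (spec.plateau_dose - spec.entrance_dose) * depth[ramp] / start
    )
    plateau = (depth >= start) & (depth <= end)
    dose[plateau] = spec.plateau_dose
    falling = (depth > end) & (depth < fall_end)
    dose[falling] = spec.plateau_dose * (fall_end - depth[falling]) / spec.falloff_mm
    dose[depth >= fall_end] = 0.0

    # LET: ramp to target floor, linear rise across target, steeper rise
    # through the fall-off, then constant
    target_slope = (spec.let_max_target - spec.let_min_target) / (end - start)
    let[ramp] = spec.let_entry + (
        (spec.let_min_target - spec.let_entry) * depth[ramp] / start
    )
    let[plateau] = spec.let_min_target + target_slope * (depth[plateau] - start)
    distal_slope = spec.distal_let_slope_factor * target_slope
    distal = depth > end
    let[distal] = np.minimum(
        spec.let_max_target + distal_slope * (depth[distal] - end),
        spec.let_max_target + distal_slope * spec.falloff_mm,
    )
    return depth, dose, let


def make_sobp_grid(spec: SOBPSpec = SOBPSpec()) -> DoseLETGrid:
    """Build the deterministic SOBP dose/LET grid with nested ICRU masks.

    The depth profile is replicated across two lateral axes. PTV covers the
    plateau span (inclusive of both endpoints, so its LET range is exactly
    [let_min_target, let_max_target]) within the central lateral block;
    CTV and GTV are the PTV shrunk by 2 and 4 mm along depth; OTV is the
    complement of the PTV.
    """
    depth, dose1d, let1d = _depth_profile(spec)
    nlat = spec.lateral_voxels
    shape = (len(depth), nlat, nlat)
    dose = np.broadcast_to(dose1d[:, None, None], shape).copy()
    let = np.broadcast_to(let1d[:, None, None], shape).copy()

    lat = np.zeros(nlat, dtype=bool)
    m = spec.target_lateral_margin
    lat[m : nlat - m] = True
    lateral = lat[None, :, None] & lat[None, None, :]

    def depth_band(lo_mm: float, hi_mm: float) -> np.ndarray:
        band = (depth >= lo_mm) & (depth <= hi_mm)
        return band[:, None, None] & lateral

    ptv = depth_band(spec.sobp_start_mm, spec.sobp_end_mm)
    ctv = depth_band(spec.sobp_start_mm + 2, spec.sobp_end_mm - 2)
    gtv = depth_band(spec.sobp_start_mm + 4, spec.sobp_end_mm - 4)
    masks = {"GTV": gtv, "CTV": ctv, "PTV": ptv, "OTV": ~ptv}
    return DoseLETGrid(
        dose=dose,
        let=let,
        spacing=(spec.spacing_mm,) * 3,
        beam_axis=0,
        masks=masks,
    )


def make_survival_table(
    alpha0: float = 0.12,
    slope: float = 0.02,
    n: int = 20,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> list[SurvivalRecord]:
    """Synthetic alpha-vs-LET records: alpha0 + slope*LET + N(0, noise_sd).

    LET values are evenly spread over (0, 40], so for any n >= 2 the table
    includes points beyond the 30.5 keV.um^-1 proton turnover. Deterministic
    for a fixed seed; noise_sd = 0 gives exactly collinear records.
    """
    if n < 2:
        raise ValueError(f"need n >= 2 records, got {n}")
    rng = np.random.default_rng(seed)
    lets = np.linspace(40.0 / n, 40.0, n)
    alphas = alpha0 + slope * lets + rng.normal(0.0, noise_sd, size=n)
    records = []
    for let, alpha in zip(lets, alphas):
        if alpha <= 0:
            alpha = 1e-6  # keep records valid under extreme noise draws
        records.append(SurvivalRecord(float(let), float(alpha)).validate())
    return records
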