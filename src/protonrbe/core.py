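"""LET-dependent linear-quadratic radiosensitivity scaling and iso-effect RBE.

The model takes a tissue's low-LET (photon, control-radiation)
radiosensitivity pair (``alpha_L`` in Gy^-1, ``beta_L`` in Gy^-2) and scales
both linearly with the proton dose-averaged LET up to a turnover LET
(``LET_U``, 30.5 keV.um^-1 for protons), beyond which effectiveness is
clamped at its plateau value rather than modelled as declining (overkill).

The slope of the alpha rise is not a universal constant: it is set per
tissue by a saturation relation linking ``alpha_L`` to the maximum
achievable alpha at the turnover point,

    alpha_U = A * (1 - exp(-lambda * alpha_L)),

so that radioresistant tissues (small ``alpha_L``) gain proportionally more
from LET than radiosensitive ones. The default ceiling ``A`` and rate
``lambda`` are calibrated so that the V-79 cell line (``alpha_L`` = 0.12
Gy^-1) reproduces the published fitted line ``alpha_H = 0.12 + 0.02 LET``.

RBE at a dose per fraction ``d`` is the iso-effect ratio: the photon dose
producing the same log cell kill ``E = alpha_H d + beta_H d^2`` under the
low-LET parameters, divided by ``d``. Its zero-dose limit is
``RBEmax = alpha_H/alpha_L`` and its infinite-dose limit is
``RBEmin = sqrt(beta_H/beta_L)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "LQParams",
    "IonSpec",
    "Calibration",
    "ScaledLQ",
    "RBEResult",
    "PROTON",
    "HELIUM",
    "CARBON",
    "DEFAULT_CALIBRATION",
    "load_config",
    "calibration_from_config",
    "alpha_ceiling",
    "scale_radiosensitivity",
    "rbe_limits",
    "iso_effective_photon_dose",
    "rbe_at_dose",
    "prescribe_proton_dose",
]

# Default calibration constants (all configurable through `load_config`):
# ceiling A of the alpha saturation curve, the V-79 anchor that fixes the
# saturation rate, the proton turnover LET, and the beta-coupling strength.
DEFAULT_ALPHA_CEILING = 2.0      # Gy^-1
DEFAULT_ANCHOR_ALPHA_LOW = 0.12  # Gy^-1, V-79 control alpha
DEFAULT_ANCHOR_SLOPE = 0.02      # Gy^-1 per keV.um^-1, V-79 fitted slope
DEFAULT_LET_TURNOVER = 30.5      # keV.um^-1, proton LET of max effectiveness
DEFAULT_BETA_COUPLING = 0.15     # Gy^-1/2


@dataclass(frozen=True)
class LQParams:
    """Low-LET (control radiation) linear-quadratic radiosensitivity.

    Parameters
    ----------
    alpha : float
        Linear coefficient, Gy^-1. Must be positive.
    beta : float
        Quadratic coefficient, Gy^-2. Must be non-negative; ``beta == 0``
        denotes a purely exponential survival curve.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @property
    def alpha_beta_ratio(self) -> float:
        """alpha/beta in Gy; defined only for beta > 0."""
        if self.beta == 0:
            raise ValueError("alpha/beta undefined for beta = 0")
        return self.alpha / self.beta


@dataclass(frozen=True)
class IonSpec:
    """Ion species, characterised by its turnover LET.

    ``let_turnover`` is the LET of maximum biological effectiveness in
    keV.um^-1; all tissues share it for a given ion.
    """

    name: str
    let_turnover: float

    def __post_init__(self) -> None:
        if not self.let_turnover > 0:
            raise ValueError("let_turnover must be > 0")


PROTON = IonSpec("proton", DEFAULT_LET_TURNOVER)
# Preset turnover constants only; no ion-specific calibration is attempted.
HELIUM = IonSpec("helium", 110.0)
CARBON = IonSpec("carbon", 200.0)


@dataclass(frozen=True)
class Calibration:
    """Constants of the saturation and beta-coupling laws.

    Attributes
    ----------
    alpha_ceiling : float
        Ceiling ``A`` of the alpha saturation curve, Gy^-1.
    alpha_rate : float
        Saturation rate ``lambda``, Gy. Normally solved from the anchor via
        :meth:`from_anchor` rather than set directly.
    beta_coupling : float
        ``c_beta`` in Gy^-1/2; 0 leaves beta LET-invariant.
    """

    alpha_ceiling: float
    alpha_rate: float
    beta_coupling: float = DEFAULT_BETA_COUPLING

    def __post_init__(self) -> None:
        if not self.alpha_ceiling > 0:
            raise ValueError("alpha_ceiling must be > 0")
        if not self.alpha_rate > 0:
            raise ValueError("alpha_rate must be > 0")
        if self.beta_coupling < 0:
            raise ValueError("beta_coupling must be >= 0")

    @classmethod
    def from_anchor(
        cls,
        alpha_ceiling: float = DEFAULT_ALPHA_CEILING,
        anchor_alpha_low: float = DEFAULT_ANCHOR_ALPHA_LOW,
        anchor_slope: float = DEFAULT_ANCHOR_SLOPE,
        let_turnover: float = DEFAULT_LET_TURNOVER,
        beta_coupling: float = DEFAULT_BETA_COUPLING,
    ) -> "Calibration":
        """Solve the saturation rate from the anchor identity.

        The rate ``lambda`` is fixed so that the anchor tissue's ceiling
        equals the value implied by its published linear fit:
        ``A (1 - exp(-lambda a0)) = a0 + s * LET_U`` with ``a0`` the anchor
        alpha and ``s`` the anchor slope. The solution is closed-form.
        """
        alpha_u = anchor_alpha_low + anchor_slope * let_turnover
        if not 0 < alpha_u < alpha_ceiling:
            raise ValueError(
                f"anchor alpha_U={alpha_u} must lie in (0, ceiling={alpha_ceiling})"
            )
        rate = -math.log1p(-alpha_u / alpha_ceiling) / anchor_alpha_low
        return cls(alpha_ceiling, rate, beta_coupling)


DEFAULT_CALIBRATION = Calibration.from_anchor()


def load_config(path) -> dict:
    """Read a plain ``key = value`` text config file.

    Recognised keys: ``alpha_ceiling``, ``anchor_alpha_low``,
    ``anchor_slope``, ``let_turnover``, ``beta_coupling``. Blank lines and
    ``#`` comments are ignored.
    """
    known = {
        "alpha_ceiling",
        "anchor_alpha_low",
        "anchor_slope",
        "let_turnover",
        "beta_coupling",
    }
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            out[key] = float(value.strip())
    return out


def calibration_from_config(config: dict) -> tuple[Calibration, IonSpec]:
    """Build (Calibration, IonSpec) from a config dict, defaulting missing keys."""
    let_u = config.get("let_turnover", DEFAULT_LET_TURNOVER)
    calib = Calibration.from_anchor(
        alpha_ceiling=config.get("alpha_ceiling", DEFAULT_ALPHA_CEILING),
        anchor_alpha_low=config.get("anchor_alpha_low", DEFAULT_ANCHOR_ALPHA_LOW),
        anchor_slope=config.get("anchor_slope", DEFAULT_ANCHOR_SLOPE),
        let_turnover=let_u,
        beta_coupling=config.get("beta_coupling", DEFAULT_BETA_COUPLING),
    )
    return calib, IonSpec("proton", let_u)


@dataclass(frozen=True)
class ScaledLQ:
    """High-LET radiosensitivity pair at a given LET."""

    alpha_h: float  # Gy^-1
    beta_h: float   # Gy^-2
    let: float      # keV.um^-1


@dataclass(frozen=True)
class RBEResult:
    """Iso-effect RBE for one (tissue, LET, dose-per-fraction) query.

    ``iso_photon_dose`` is the photon dose (Gy) producing the same effect,
    i.e. ``rbe * dose_per_fraction`` (Equivalent-Gy). ``degenerate_beta``
    flags the ``beta_L = 0`` case where RBEmin has no finite definition and
    is reported as 1.
    """

    rbe: float
    rbe_max: float
    rbe_min: float
    dose_per_fraction: float
    let: float
    iso_photon_dose: float
    degenerate_beta: bool = False


# ---------------------------------------------------------------------------
# Model operations
# ---------------------------------------------------------------------------

def alpha_ceiling(alpha_low: float, calib: Calibration = DEFAULT_CALIBRATION) -> float:
    """Maximum alpha at the turnover LET for a tissue with low-LET ``alpha_low``.

    Saturation law ``alpha_U = A (1 - exp(-lambda alpha_L))``: strictly
    increasing and concave in ``alpha_L``, through the origin.
    """
    if not alpha_low > 0:
        raise ValueError(f"alpha_low must be > 0, got {alpha_low}")
    return calib.alpha_ceiling * -math.expm1(-calib.alpha_rate * alpha_low)


def _scaling_slopes(
    low: LQParams, ion: IonSpec, calib: Calibration
) -> tuple[float, float]:
    """Per-unit-LET increments (k_alpha, k_beta) for one tissue.

    ``k_alpha = (alpha_U - alpha_L)/LET_U``. Beta rises linearly so that at
    the turnover ``sqrt(beta_H/beta_L)`` equals ``1 + c_beta sqrt(alpha/beta)``,
    giving ``k_beta = beta_L (R_U^2 - 1)/LET_U``; beta_L = 0 gives k_beta = 0.
    """
    alpha_u = alpha_ceiling(low.alpha, calib)
    if alpha_u <= low.alpha:
        raise ValueError(
            f"alpha_low={low.alpha} exceeds the usable range of the "
            f"saturation law (alpha_U={alpha_u})"
        )
    k_alpha = (alpha_u - low.alpha) / ion.let_turnover
    if low.beta > 0:
        r_u = 1.0 + calib.beta_coupling * math.sqrt(low.alpha / low.beta)
        k_beta = low.beta * (r_u * r_u - 1.0) / ion.let_turnover
    else:
        k_beta = 0.0
    return k_alpha, k_beta


def scale_radiosensitivity(
    low: LQParams,
    let: float,
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> ScaledLQ:
    """Scale (alpha, beta) linearly with LET, clamped at the turnover plateau.

    ``alpha_H(L) = alpha_L + k_alpha min(L, LET_U)`` and likewise for beta;
    for ``L > LET_U`` both stay at their turnover values (no overkill
    decline is modelled — clinical plans stay far below the turnover).
    """
    if let < 0:
        raise ValueError(f"let must be >= 0, got {let}")
    k_alpha, k_beta = _scaling_slopes(low, ion, calib)
    eff = min(let, ion.let_turnover)
    return ScaledLQ(
        alpha_h=low.alpha + k_alpha * eff,
        beta_h=low.beta + k_beta * eff,
        let=let,
    )


def rbe_limits(low: LQParams, scaled: ScaledLQ) -> tuple[float, float]:
    """Asymptotic RBE limits (RBEmax, RBEmin).

    ``RBEmax = alpha_H/alpha_L`` (zero-dose limit) and
    ``RBEmin = sqrt(beta_H/beta_L)`` (infinite-dose limit). For
    ``beta_L = 0`` RBEmin is defined as 1; ``beta_L = 0`` with
    ``beta_H > 0`` is degenerate (RBEmin would diverge) and rejected.
    """
    if not low.alpha > 0:
        raise ValueError("low.alpha must be > 0")
    rbe_max = scaled.alpha_h / low.alpha
    if low.beta > 0:
        rbe_min = math.sqrt(scaled.beta_h / low.beta)
    elif scaled.beta_h > 0:
        raise ValueError(
            "degenerate: beta_L = 0 with beta_H > 0 gives an undefined-high RBEmin"
        )
    else:
        rbe_min = 1.0
    return rbe_max, rbe_min


def iso_effective_photon_dose(low: LQParams, effect: float) -> float:
    """Photon dose (Gy) producing log-survival ``effect`` under ``low``.

    Positive root of ``beta_L D^2 + alpha_L D - E = 0``; linear closed form
    ``E/alpha_L`` when ``beta_L = 0``.
    """
    if effect < 0:
        raise ValueError(f"effect must be >= 0, got {effect}")
    if effect == 0:
        return 0.0
    if low.beta == 0:
        return effect / low.alpha
    disc = low.alpha * low.alpha + 4.0 * low.beta * effect
    return (-low.alpha + math.sqrt(disc)) / (2.0 * low.beta)


def rbe_at_dose(
    low: LQParams,
    let: float,
    dose_per_fraction: float,
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> RBEResult:
    """Iso-effective RBE at a given LET and proton dose per fraction.

    Computes the proton effect ``E = alpha_H d + beta_H d^2``, finds the
    photon dose giving the same effect, and reports the ratio. At ``d = 0``
    the analytic limit RBEmax is returned.
    """
    if dose_per_fraction < 0:
        raise ValueError(f"dose_per_fraction must be >= 0, got {dose_per_fraction}")
    scaled = scale_radiosensitivity(low, let, ion, calib)
    degenerate = low.beta == 0
    rbe_max, rbe_min = rbe_limits(low, scaled)
    d = dose_per_fraction
    if d == 0:
        rbe = rbe_max
        iso = 0.0
    else:
        effect = scaled.alpha_h * d + scaled.beta_h * d * d
        iso = iso_effective_photon_dose(low, effect)
        rbe = iso / d
    return RBEResult(
        rbe=rbe,
        rbe_max=rbe_max,
        rbe_min=rbe_min,
        dose_per_fraction=d,
        let=let,
        iso_photon_dose=iso,
        degenerate_beta=degenerate,
    )


def prescribe_proton_dose(photon_dose: float, rbe: float) -> float:
    """Proton physical dose delivering a photon prescription at a given RBE.

    The clinic's conversion: the equivalent x-ray dose divided by the
    allocated RBE (e.g. 76 Gy at RBE 1.1 -> 69.09 Gy proton dose).
    """
    if not rbe > 0:
        raise ValueError(f"rbe must be > 0, got {rbe}")
    return photon_dose / rbe


# ---------------------------------------------------------------------------
# Vectorised field evaluation (used by the voxel-map layer)
# ---------------------------------------------------------------------------

def rbe_fields(
    low: LQParams,
    let: np.ndarray,
    dose: np.ndarray,
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise (rbe, iso_photon_dose) over LET/dose arrays for one tissue.

    Identical maths to :func:`rbe_at_dose`, applied with numpy; zero-dose
    voxels receive ``rbe = RBEmax`` and iso dose 0.
    """
    let = np.asarray(let, dtype=float)
    dose = np.asarray(dose, dtype=float)
    if np.any(let < 0):
        raise ValueError("let must be >= 0 everywhere")
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0 everywhere")
    k_alpha, k_beta = _scaling_slopes(low, ion, calib)
    eff = np.minimum(let, ion.let_turnover)
    alpha_h = low.alpha + k_alpha * eff
    beta_h = low.beta + k_beta * eff
    effect = alpha_h * dose + beta_h * dose * dose
    if low.beta == 0:
        iso = effect / low.alpha
    else:
        disc = low.alpha * low.alpha + 4.0 * low.beta * effect
        iso = (-low.alpha + np.sqrt(disc)) / (2.0 * low.beta)
    rbe_max = alpha_h / low.alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        rbe = np.where(dose > 0, iso / np.where(dose > 0, dose, 1.0), rbe_max)
    return rbe, iso
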