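"""Least-squares fitting of alpha against LET from survival-parameter tables.

Cell-survival experiments report (LET, alpha, beta) rows; alpha rises
linearly with LET up to the turnover, so the fit uses ordinary least
squares on the pre-turnover records only (LET <= cutoff, inclusive — the
turnover point itself is the maximum of the linear rise). Post-turnover
records are excluded, not discarded: they are echoed back for inspection.
Beta columns are parsed but never fitted; reported beta trends with LET are
generally too unreliable to regress.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import pandas as pd
from scipy import stats

from .core import DEFAULT_LET_TURNOVER

__all__ = [
    "SurvivalRecord",
    "AlphaLetFit",
    "InsufficientDataError",
    "fit_alpha_vs_let",
    "read_survival_table",
]


class InsufficientDataError(ValueError):
    """Fewer than two usable records below the LET cutoff."""


class SurvivalRecord(NamedTuple):
    let: float            # keV.um^-1
    alpha: float          # Gy^-1
    beta: Optional[float] = None  # Gy^-2, optional and never fitted

    def validate(self) -> "SurvivalRecord":
        if self.let < 0:
            raise ValueError(f"let must be >= 0, got {self.let}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        return self


@dataclass(frozen=True)
class AlphaLetFit:
    """OLS line alpha = intercept + slope * LET over pre-turnover records."""

    intercept: float  # Gy^-1
    slope: float      # Gy^-1 per keV.um^-1
    n_used: int
    excluded: tuple[SurvivalRecord, ...]

    def predict(self, let: float) -> float:
        return self.intercept + self.slope * let


def fit_alpha_vs_let(
    records: Sequence[SurvivalRecord],
    let_cutoff: float = DEFAULT_LET_TURNOVER,
) -> AlphaLetFit:
    """Fit alpha vs LET by unweighted OLS, excluding post-turnover records.

    Records with ``let <= let_cutoff`` enter the fit; the rest are returned
    in ``excluded``. Raises :class:`InsufficientDataError` with fewer than
    two usable records.
    """
    records = [SurvivalRecord(*r).validate() for r in records]
    used = [r for r in records if r.let <= let_cutoff]
    excluded = tuple(r for r in records if r.let > let_cutoff)
    if len(used) < 2:
        raise InsufficientDataError(
            f"need >= 2 records with let <= {let_cutoff}, got {len(used)}"
        )
    lets = [r.let for r in used]
    alphas = [r.alpha for r in used]
    if len(set(lets)) < 2:
        raise InsufficientDataError("all usable records share one LET value")
    res = stats.linregress(lets, alphas)
    return AlphaLetFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        n_used=len(used),
        excluded=excluded,
    )


def read_survival_table(path) -> list[SurvivalRecord]:
    """Read a delimited text table with header ``let,alpha[,beta]``."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"let", "alpha"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    has_beta = "beta" in df.columns
    return [
        SurvivalRecord(
            float(row.let),
            float(row.alpha),
            float(row.beta) if has_beta and pd.notna(row.beta) else None,
        ).validate()
        for row in df.itertuples()
    ]
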