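"""Qualitative ICRU-volume outcome matrix for proton vs photon plans.

A plan comparison is summarised as a dose-status triple over the ICRU
volumes — GTV, the combined CTV+PTV shell, and OTV (everything outside the
PTV) — each "up", "equal" or "down" for the proton plan relative to the
best photon plan. Four canonical rows map to tabulated outcome labels with
footnote caveats; the other 23 triples are deliberately not assigned labels
(dose and LET changes act non-linearly on cell kill), only two monotonic
directional rules are reported as hints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["PlanStatus", "OutcomeAssessment", "classify_plan", "CAVEATS", "LEVELS"]

LEVELS = ("up", "equal", "down")
LABELS = ("Much better", "Better", "Equal", "Worse", "Better or worse")

# Footnote caveats keyed by the printed codes (meanings paraphrased).
CAVEATS = {
    "*": (
        "Reduced dose outside the CTV+PTV may improve tolerance (less late "
        "vascular insufficiency in the OTV); the row may be acceptable for "
        "non-essential tissue or small essential-tissue volumes."
    ),
    "**": (
        "An equal outcome holds only if the assumed RBE is correct."
    ),
    "***": (
        "For radiosensitive tumour classes, x-ray control is already very "
        "high and dose escalation gains nothing; such tumours may also have "
        "RBE below 1.1, risking under-dosage if 1.1 is assumed."
    ),
    "****": (
        "CTV/PTV dose reductions can arise from range uncertainty and tissue "
        "movement (worse with scanned beams); extending the PTV or raising "
        "local dose is a trade-off against OTV gains."
    ),
}

DIRECTIONAL_HINTS = (
    "A dose shift from GTV to other parts of the PTV is expected to reduce "
    "tumour control while enhancing normal-tissue toxicity within the PTV.",
    "A dose shift from within the PTV to the OTV is expected to reduce "
    "tumour control probability; OTV effects depend on the organ at risk's "
    "tolerance and RBE.",
)


@dataclass(frozen=True)
class PlanStatus:
    """Dose status of the proton plan in each ICRU volume: up/equal/down."""

    gtv: str
    ctv_ptv: str
    otv: str

    def __post_init__(self) -> None:
        for name in ("gtv", "ctv_ptv", "otv"):
            value = getattr(self, name)
            if value not in LEVELS:
                raise ValueError(
                    f"{name} must be one of {LEVELS}, got {value!r}"
                )


@dataclass(frozen=True)
class OutcomeAssessment:
    """Outcome labels per volume, with footnote caveats.

    ``tabulated`` is False for the 23 status triples outside the canonical
    table; those carry no labels, only ``hints``. ``rbe_conditional`` is
    set whenever any label is "Equal" (an equal outcome presupposes a
    correct RBE).
    """

    tumour_control: Optional[str]
    ctv_ptv_side_effects: Optional[str]
    otv_side_effects: Optional[str]
    caveats: tuple[str, ...] = ()
    rbe_conditional: bool = False
    tabulated: bool = True
    hints: tuple[str, ...] = ()


# The four canonical rows: status triple -> (labels, caveat codes).
_TABLE: dict[tuple[str, str, str], tuple[tuple[str, str, str], tuple[str, ...]]] = {
    ("up", "up", "down"): (("Much better", "Worse", "Better"), ("***", "*")),
    ("up", "equal", "down"): (("Better", "Equal", "Better"), ("***", "**")),
    ("equal", "equal", "down"): (("Equal", "Equal", "Better"), ("**",)),
    ("equal", "down", "down"): (("Worse", "Better", "Better or worse"), ("****",)),
}


def classify_plan(status: PlanStatus) -> OutcomeAssessment:
    """Map a dose-status triple to its tabulated outcome row, or to hints.

    The four canonical rows return their exact labels and footnote codes;
    any other combination returns a "not tabulated" assessment carrying the
    two monotonic directional rules as hints.
    """
    key = (status.gtv, status.ctv_ptv, status.otv)
    if key in _TABLE:
        labels, codes = _TABLE[key]
        return OutcomeAssessment(
            tumour_control=labels[0],
            ctv_ptv_side_effects=labels[1],
            otv_side_effects=labels[2],
            caveats=codes,
            rbe_conditional="Equal" in labels,
            tabulated=True,
        )
    return OutcomeAssessment(
        tumour_control=None,
        ctv_ptv_side_effects=None,
        otv_side_effects=None,
        tabulated=False,
        hints=DIRECTIONAL_HINTS,
    )
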