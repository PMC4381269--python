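"""Voxel maps: dose/LET grids -> RBE and Equivalent-Gy maps, range shifts.

A plan is represented as paired per-fraction dose and dose-averaged LET
values on a small voxel grid with named boolean structure masks
(GTV/CTV/PTV/OTV). The RBE model is applied voxelwise under a per-mask
tissue assignment to produce RBE and equivalent-photon-dose (Equivalent-Gy)
fields. A millimetre range shift translates the dose and LET patterns along
the beam axis in whole-voxel steps — the clinically feared failure mode
where high dose *and* high LET appear deeper than planned — while the
anatomical masks stay fixed.

Grid file format (plain delimited text, long form)::

    # meta: shape=60,5,5 spacing=1.0,1.0,1.0 beam_axis=0
    x,y,z,dose,let[,mask_GTV,...]
    0,0,0,1.4,0.5,0,...

with 0-based integer voxel indices, one row per voxel, masks as 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_CALIBRATION,
    PROTON,
    Calibration,
    IonSpec,
    LQParams,
    rbe_fields,
)

__all__ = [
    "DoseLETGrid",
    "TissueAssignment",
    "GridFormatError",
    "read_grid",
    "write_grid",
    "compute_rbe_grid",
    "shift_range",
    "mask_summary",
]


class GridFormatError(ValueError):
    """Malformed grid file or inconsistent field shapes."""


@dataclass
class DoseLETGrid:
    """Paired dose/LET voxel grid with optional masks and derived fields.

    ``dose`` is per-fraction Gy, ``let`` keV.um^-1, both shaped ``shape``
    (1-3 axes). ``spacing`` is mm per voxel per axis. ``beam_axis`` indexes
    the depth axis along which range shifts act. ``rbe`` and ``eq_dose``
    are None until :func:`compute_rbe_grid` fills them.
    """

    dose: np.ndarray
    let: np.ndarray
    spacing: tuple[float, ...]
    beam_axis: int = 0
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    rbe: Optional[np.ndarray] = None
    eq_dose: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.let = np.asarray(self.let, dtype=float)
        if self.dose.shape != self.let.shape:
            raise GridFormatError(
                f"dose shape {self.dose.shape} != let shape {self.let.shape}"
            )
        if not 1 <= self.dose.ndim <= 3:
            raise GridFormatError("grid must have 1-3 axes")
        if len(self.spacing) != self.dose.ndim:
            raise GridFormatError("spacing length must match grid dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise GridFormatError("spacing must be positive")
        if not 0 <= self.beam_axis < self.dose.ndim:
            raise GridFormatError(f"beam_axis {self.beam_axis} out of range")
        if np.any(self.dose < 0):
            raise GridFormatError("dose must be >= 0 everywhere")
        if np.any(self.let < 0):
            raise GridFormatError("let must be >= 0 everywhere")
        for name, m in self.masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.dose.shape:
                raise GridFormatError(f"mask {name!r} shape mismatch")
            self.masks[name] = m

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dose.shape


# mask name -> low-LET LQ parameters; unassigned voxels use `default`.
# Masks listed later take precedence on overlap, so order assignments
# outermost-first (e.g. OTV, PTV, CTV, GTV).
@dataclass(frozen=True)
class TissueAssignment:
    assignments: tuple[tuple[str, LQParams], ...]
    default: LQParams

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, LQParams], default: LQParams
    ) -> "TissueAssignment":
        return cls(tuple(mapping.items()), default)

    def validate_against(self, grid: DoseLETGrid) -> None:
        for name, _ in self.assignments:
            if name not in grid.masks:
                raise ValueError(f"assignment references unknown mask {name!r}")


def write_grid(grid: DoseLETGrid, path) -> None:
    """Write a grid in the long-form delimited text format."""
    shape = grid.shape
    idx = np.indices(shape).reshape(len(shape), -1)
    # pad index columns to x,y,z regardless of dimensionality
    cols = {}
    for axis, name in enumerate("xyz"):
        cols[name] = idx[axis] if axis < len(shape) else np.zeros(idx.shape[1], int)
    cols["dose"] = grid.dose.ravel()
    cols["let"] = grid.let.ravel()
    if grid.rbe is not None:
        cols["rbe"] = grid.rbe.ravel()
    if grid.eq_dose is not None:
        cols["eq_dose"] = grid.eq_dose.ravel()
    for name, m in grid.masks.items():
        cols[f"mask_{name}"] = m.ravel().astype(int)
    df = pd.DataFrame(cols)
    shape_s = ",".join(str(n) for n in shape)
    spacing_s = ",".join(repr(float(s)) for s in grid.spacing)
    with open(path, "w") as fh:
        fh.write(f"# meta: shape={shape_s} spacing={spacing_s} beam_axis={grid.beam_axis}\n")
        df.to_csv(fh, index=False)


def read_grid(path) -> DoseLETGrid:
    """Read a grid written by :func:`write_grid`; round-trips exactly."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# meta:"):
            raise GridFormatError("missing '# meta:' header line")
        meta = {}
        for token in header[len("# meta:"):].split():
            key, _, value = token.partition("=")
            meta[key] = value
        try:
            shape = tuple(int(n) for n in meta["shape"].split(","))
            spacing = tuple(float(s) for s in meta["spacing"].split(","))
            beam_axis = int(meta.get("beam_axis", 0))
        except (KeyError, ValueError) as exc:
            raise GridFormatError(f"bad meta header: {header!r}") from exc
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("dose", "let"):
        if col not in df.columns:
            raise GridFormatError(f"grid file missing {col!r} column")
    n_vox = int(np.prod(shape))
    if len(df) != n_vox:
        raise GridFormatError(f"expected {n_vox} voxel rows, got {len(df)}")
    # rows may arrive in any order; sort by index columns
    axes = list("xyz")[: len(shape)]
    df = df.sort_values(list("xyz")).reset_index(drop=True)

    def unflatten(col):
        return df[col].to_numpy().reshape(shape)

    masks = {
        c[len("mask_"):]: unflatten(c).astype(bool)
        for c in df.columns
        if c.startswith("mask_")
    }
    grid = DoseLETGrid(
        dose=unflatten("dose"),
        let=unflatten("let"),
        spacing=spacing,
        beam_axis=beam_axis,
        masks=masks,
    )
    if "rbe" in df.columns:
        grid.rbe = unflatten("rbe")
    if "eq_dose" in df.columns:
        grid.eq_dose = unflatten("eq_dose")
    return grid


def compute_rbe_grid(
    grid: DoseLETGrid,
    tissues: TissueAssignment,
    ion: IonSpec = PROTON,
    calib: Calibration = DEFAULT_CALIBRATION,
) -> DoseLETGrid:
    """Voxelwise RBE and Equivalent-Gy fields under a tissue assignment.

    Each voxel's tissue is the last assignment whose mask covers it (the
    default tissue where none does); then ``rbe = rbe_at_dose(tissue, let,
    dose)`` and ``eq_dose = rbe * dose``. Zero-dose voxels get
    ``rbe = RBEmax`` and ``eq_dose = 0``. Returns a new grid; the input is
    untouched.
    """
    tissues.validate_against(grid)
    # voxel -> tissue index; later assignments override earlier on overlap
    tissue_list = [tissues.default] + [t for _, t in tissues.assignments]
    owner = np.zeros(grid.shape, dtype=int)
    for i, (name, _) in enumerate(tissues.assignments, start=1):
        owner[grid.masks[name]] = i
    rbe = np.empty(grid.shape)
    eq = np.empty(grid.shape)
    for i, tissue in enumerate(tissue_list):
        sel = owner == i
        if not np.any(sel):
            continue
        r, iso = rbe_fields(tissue, grid.let[sel], grid.dose[sel], ion, calib)
        rbe[sel] = r
        eq[sel] = iso
    return DoseLETGrid(
        dose=grid.dose.copy(),
        let=grid.let.copy(),
        spacing=grid.spacing,
        beam_axis=grid.beam_axis,
        masks={k: v.copy() for k, v in grid.masks.items()},
        rbe=rbe,
        eq_dose=eq,
    )


def _shift_field(a: np.ndarray, k: int, axis: int) -> np.ndarray:
    """Translate ``a`` by ``k`` voxels along ``axis``, edge-filling vacated voxels."""
    if k == 0:
        return a.copy()
    out = np.empty_like(a)
    src = np.moveaxis(a, axis, 0)
    dst = np.moveaxis(out, axis, 0)
    if k > 0:  # deeper: pattern moves to larger indices, entrance edge fills
        dst[k:] = src[:-k]
        dst[:k] = src[0]
    else:
        k = -k
        dst[:-k] = src[k:]
        dst[-k:] = src[-1]
    return out


def shift_range(grid: DoseLETGrid, shift_mm: float) -> DoseLETGrid:
    """Translate dose and LET along the beam axis by a millimetre range shift.

    The shift snaps to the nearest whole voxel (``round(shift_mm/spacing)``,
    no interpolation). Positive shifts move the pattern deeper; vacated
    voxels take the nearest original edge value. Masks (anatomy) do not
    move; derived rbe/eq_dose fields are dropped and must be recomputed.
    """
    spacing = grid.spacing[grid.beam_axis]
    k = int(round(shift_mm / spacing))
    extent = grid.shape[grid.beam_axis]
    if abs(k) >= extent:
        raise ValueError(
            f"shift of {k} voxels exceeds beam-axis extent {extent}"
        )
    return DoseLETGrid(
        dose=_shift_field(grid.dose, k, grid.beam_axis),
        let=_shift_field(grid.let, k, grid.beam_axis),
        spacing=grid.spacing,
        beam_axis=grid.beam_axis,
        masks={k_: v.copy() for k_, v in grid.masks.items()},
    )


def mask_summary(
    grid: DoseLETGrid, mask_names: Optional[Sequence[str]] = None
) -> dict:
    """Per-mask {mean, min, max} of rbe and eq_dose; empty masks flagged.

    Requires rbe/eq_dose to have been computed. ``mask_names`` defaults to
    all masks on the grid.
    """
    if grid.rbe is None or grid.eq_dose is None:
        raise ValueError("compute_rbe_grid must run before mask_summary")
    if mask_names is None:
        mask_names = list(grid.masks)
    out: dict = {}
    for name in mask_names:
        m = grid.masks[name]
        if not np.any(m):
            out[name] = {"empty": True}
            continue
        out[name] = {
            "empty": False,
            "n_voxels": int(m.sum()),
            "rbe": {
                "mean": float(grid.rbe[m].mean()),
                "min": float(grid.rbe[m].min()),
                "max": float(grid.rbe[m].max()),
            },
            "eq_dose": {
                "mean": float(grid.eq_dose[m].mean()),
                "min": float(grid.eq_dose[m].min()),
                "max": float(grid.eq_dose[m].max()),
            },
        }
    return out
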