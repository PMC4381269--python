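# Methods

## Model

Cell survival under the linear-quadratic (LQ) model is
−ln SF = αd + βd², with α (Gy⁻¹) the initial-slope and β (Gy⁻²) the
quadratic radiosensitivity; α/β (Gy) is the dose at which the two
components kill equally. The package treats a tissue's photon (low-LET)
pair (α_L, β_L) as the sole biological input and derives its proton
radiosensitivity at any dose-averaged LET L in three steps.

**1. Saturation ceiling.** The maximum α a tissue can reach at the
turnover LET is tied to its photon α by

    α_U = A (1 − e^{−λ α_L}),

strictly increasing and concave, through the origin. Defaults A = 2.0 Gy⁻¹
and λ ≈ 3.78547 Gy; λ is not a free parameter but is solved in closed form
from the anchor identity α_U(0.12) = 0.12 + 0.02 × 30.5 = 0.73 Gy⁻¹, i.e.
the requirement that the V-79 cell line reproduce its published fitted
line α_H = 0.12 + 0.02 LET. Radioresistant tissues (small α_L) therefore
get proportionally larger LET gains than radiosensitive ones, whose α is
already near saturation.

**2. Linear LET scaling with clamp.** Both parameters rise linearly with
LET to their turnover values at LET_U and stay there:

    α_H(L) = α_L + (α_U − α_L)/LET_U · min(L, LET_U)
    β_H(L) = β_L (1 + min(L, LET_U)/LET_U · (R_U² − 1)),  R_U = 1 + c_β √(α_L/β_L)

The β law is chosen so that β_H is linear in L and the high-dose RBE limit
at the turnover, RBEmin(LET_U) = √(β_H/β_L) = R_U, is one plus a term
proportional to √(α/β) — the direct-proportionality RBEmin is expected to
obey — while RBEmax = α_H/α_L remains inversely related to α/β. Setting
c_β = 0 makes β LET-invariant, a common simpler modelling choice.

**3. Iso-effect RBE.** At dose per fraction d the proton effect is
E = α_H d + β_H d². The iso-effective photon dose is the positive root of
β_L D² + α_L D = E (closed form; E/α_L when β_L = 0) and RBE = D/d. At
d = 0 the analytic limit RBEmax is returned instead of 0/0. The root
satisfies the LQ identity to better than 1e−9 relative; the test suite
cross-checks it against an independent bisection root-finder on 1,000
random parameter draws.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `alpha_ceiling` (A) | Gy⁻¹ | 2.0 | ceiling of the α saturation curve |
| `alpha_rate` (λ) | Gy | ≈3.78547 | saturation rate, solved from the anchor |
| `anchor_alpha_low` | Gy⁻¹ | 0.12 | anchor tissue's photon α (V-79) |
| `anchor_slope` | Gy⁻¹ per keV·µm⁻¹ | 0.02 | anchor tissue's α-vs-LET slope |
| `let_turnover` (LET_U) | keV·µm⁻¹ | 30.5 | proton LET of maximum effectiveness |
| `beta_coupling` (c_β) | Gy⁻¹ᐟ² | 0.15 | strength of the β rise with LET |

All are overridable through a plain `key = value` config file
(`--config`); λ is always re-solved from the anchor after overrides.
Helium and carbon `IonSpec` presets carry only their turnover constants
(110 and 200 keV·µm⁻¹); no ion-specific calibration is attempted.

## Design choices

- **Clamp, not overkill.** Beyond LET_U effectiveness is held at its
  plateau rather than declining. Clinical SOBP plans occupy 1.5–9
  keV·µm⁻¹, far below the turnover, so the post-turnover shape is
  irrelevant to the supported use cases and post-turnover survival data
  are too sparse to fit.
- **LET semantics.** Each query or voxel carries a single scalar
  interpreted as dose-averaged LET; no microdosimetric spectrum handling.
- **β_L = 0 tissues.** RBE uses the linear closed form; RBEmin is reported
  as 1 with a `degenerate_beta` flag, since √(β_H/β_L) is undefined.
- **α-vs-LET fitting** is unweighted OLS on records with LET ≤ cutoff
  (inclusive — the turnover point is the maximum of the linear rise);
  post-cutoff records are echoed in `excluded`, never silently dropped.
  β columns are parsed but never fitted: reported β trends with LET in
  survival tables are generally artefacts of the fitting process.
- **Grid format** is long-form delimited text with a `# meta:` header
  (shape, spacing, beam axis) — inspectable and diffable; DICOM-RT/NIfTI
  import is out of scope. Round-trips are bit-exact (the reader uses
  round-trip float parsing).
- **Range shifts snap to whole voxels** (nearest), with no interpolation,
  matching the millimetre-exchange heuristic under uniform tissue density;
  vacated voxels take the nearest original edge value, and anatomical
  masks do not move. Derived RBE fields are invalidated by a shift and
  must be recomputed.
- **Tissue assignment precedence**: later assignments override earlier on
  mask overlap, so nested volumes are listed outermost-first
  (OTV, PTV, CTV, GTV); unassigned voxels take a declared default tissue.
- **Crossover search** brackets (0.001, 100) Gy — two orders of magnitude
  either side of clinical fraction sizes — with a 200-point geometric scan
  refined by Brent's method to 1e−6 Gy. Differences within 1e−12 of zero
  are treated as rounding noise, so identical tissues and the zero-LET
  case correctly return "no crossover".
- **ICRU matrix**: only the four canonical dose-status rows carry outcome
  labels; the remaining 23 triples are deliberately left unlabelled
  (dose and LET act non-linearly on cell kill) and return two monotonic
  directional rules — dose shifted out of the GTV or out of the PTV
  reduces expected tumour control — as hints. The `rbe_conditional` flag
  marks any "Equal" outcome as contingent on the RBE allocation being
  correct.

## Synthetic data

`make_sobp_grid` builds a stylised spread-out-Bragg-peak depth profile
replicated laterally on a 60 × 5 × 5 voxel grid at 1 mm spacing: an
entrance ramp from 1.4 Gy to a uniform 2 Gy plateau over 25–45 mm, a 4 mm
linear distal fall-off, and LET rising from 1.5 to 9 keV·µm⁻¹ across the
target (the band clinical plans occupy) then three times more steeply
through the fall-off. Nested GTV ⊂ CTV ⊂ PTV masks sit inside the plateau;
OTV is the PTV complement. This captures the one feature that matters for
range-shift hazard analysis — high dose and high LET arriving together
just past the planned boundary — but is not a transport calculation: no
lateral scatter, energy straggling, nuclear halo, or out-of-field LET
structure from scanned beams. Passing tests on these grids validate the
mapping and shift machinery, not the physics of any real plan.

`make_survival_table` emulates an α-vs-LET data set: α = α₀ + s·L plus
Gaussian noise (default σ = 0.01 Gy⁻¹, n = 20, seeded), with LET spread
over (0, 40] so at least one point always exercises the fit's
post-turnover exclusion rule. Problem sizes throughout the test suite and
acceptance script (≤ 1,500-voxel grids, ≤ 1,000-draw oracle comparisons,
n ≤ 1,000 fit tables) keep every check comfortably desk-scale while still
exercising each code path.

## Known limitations

- The saturation constants (A, λ) and the β-coupling law are calibrated
  stand-ins anchored to a single published fit line; users with direct
  measurements of α_U for their cell systems should recalibrate via the
  config file.
- The guarantee that α/β rises with LET holds when the saturation gain
  outpaces the β coupling, i.e. α_U/α_L > R_U². This covers clinically
  representative tissues (roughly α_L ≤ 0.5 Gy⁻¹ with α/β between 1 and
  20 Gy) but fails for extremely radiosensitive systems (e.g. α_L = 1.0
  Gy⁻¹, β_L = 0.035 Gy⁻²), where RBEmin exceeds RBEmax and RBE *rises*
  with dose per fraction. The implementation handles the regime correctly
  (RBE still runs monotonically between its limits); the property tests
  assert the rising-α/β trend only on the representative domain.
- Voxel maps are evaluative, not predictive of outcome: no TCP/NTCP
  models, no DVH machinery, and no Monte Carlo LET computation.
- RBE queries assume the turnover-clamped linear-scaling model everywhere;
  no track-structure, repair-kinetics or bystander effects.
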