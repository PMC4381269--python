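# protonrbe

Tools for modelling the relative biological effectiveness (RBE) of proton
beams as a function of linear energy transfer (LET), dose per fraction and
tissue radiosensitivity — for medical physicists and radiobiologists who
want to move beyond the single clinical RBE allocation of 1.1.

## The problem

Proton therapy converts photon prescriptions to proton doses with a fixed
RBE of 1.1, yet RBE demonstrably varies with LET (which rises steeply near
the end of the proton range), with dose per fraction, and with the
tissue's own photon radiosensitivity. Underestimating RBE in late-reacting
normal tissue risks toxicity; overestimating it in a radiosensitive tumour
risks under-dosage. Evaluating either risk requires voxel-level maps of
dose, LET and RBE, and a model linking them.

## The model

A tissue is characterised by its low-LET (photon) linear-quadratic
parameters α_L (Gy⁻¹) and β_L (Gy⁻²), where −ln SF = αd + βd². Both are
scaled linearly with LET up to the proton turnover LET_U = 30.5 keV·µm⁻¹,
beyond which they clamp at their plateau (overkill decline is not
modelled; clinical plans stay in the 1.5–9 keV·µm⁻¹ band):

    α_H(L) = α_L + (α_U − α_L)/LET_U · min(L, LET_U)
    β_H(L) = β_L · (1 + min(L, LET_U)/LET_U · (R_U² − 1)),   R_U = 1 + c_β √(α_L/β_L)

The per-tissue ceiling α_U comes from a saturation relation,
α_U = A (1 − e^{−λ α_L}), with A = 2.0 Gy⁻¹ and λ ≈ 3.785 Gy fixed so that
the V-79 cell line (α_L = 0.12 Gy⁻¹) reproduces its published fitted line
α_H = 0.12 + 0.02·LET. RBE at dose per fraction d is then the iso-effect
ratio: the photon dose producing the same effect E = α_H d + β_H d²,
divided by d. Its limits are RBEmax = α_H/α_L at zero dose and
RBEmin = √(β_H/β_L) at high dose.

The package also provides: α-vs-LET least-squares fitting with
post-turnover exclusion; RBE/Equivalent-Gy voxel maps on dose-LET grids
with millimetre range-shift perturbation; the qualitative ICRU
(GTV/CTV+PTV/OTV) outcome matrix; and deterministic generators for
SOBP-like grids and synthetic survival tables.

## Worked example

    $ protonrbe rbe --alpha 0.12 --beta 0.035 --let 2 --dose 2
    {"rbe": 1.1582708522771674, "rbe_max": 1.3333333333333335,
     "rbe_min": 1.0205313600536132, "iso_photon_dose": 2.316541704554335}

At LET 2 keV·µm⁻¹ and 2 Gy per fraction a V-79-like tissue has RBE ≈ 1.16:
a 2 Gy proton fraction is biologically equivalent to 2.32 Gy of photons.
The same query at zero dose would give RBEmax = 1.33, and at very high
dose RBEmin = 1.02 — RBE falls as dose per fraction rises.

    $ protonrbe curve --mode dose --alpha 0.12 --beta 0.035 --let 6 --grid 1:4:1
    abscissa,rbe,rbe_max,rbe_min
    1.0,1.5903127693285313,2.0,1.0604021739692133
    2.0,1.4423610190619824,2.0,1.0604021739692133
    3.0,1.3616254031199453,2.0,1.0604021739692133
    4.0,1.3099371144711711,2.0,1.0604021739692133

The same library surface is available in Python:

```python
from protonrbe import LQParams, rbe_at_dose

r = rbe_at_dose(LQParams(alpha=0.12, beta=0.035), let=6.0, dose_per_fraction=1.8)
print(r.rbe)   # 1.4644363883671012
```

Other subcommands: `protonrbe fit` (α-vs-LET OLS from a `let,alpha[,beta]`
table), `protonrbe map` (RBE/Equivalent-Gy maps with `--shift` range
perturbation and per-mask JSON summaries), `protonrbe icru` (dose-status
triple classification) and `protonrbe fixture` (test-data generators).

## Layout

- `src/protonrbe/core.py` — LQ types, calibration, LET scaling, iso-effect RBE
- `src/protonrbe/curves.py` — RBE-vs-dose/LET curve families, crossover search
- `src/protonrbe/fitting.py` — α-vs-LET OLS with turnover exclusion
- `src/protonrbe/planmaps.py` — dose-LET voxel grids, RBE maps, range shifts
- `src/protonrbe/icru.py` — qualitative ICRU dose-status outcome matrix
- `src/protonrbe/fixtures.py` — deterministic SOBP grid and survival-table generators
- `src/protonrbe/cli.py` — the `protonrbe` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
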