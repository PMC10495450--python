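# Methods

This note documents the models, numerical choices and known limitations
behind `carotidwk`.

## Per-segment physics

Each arterial segment is a straight rigid-walled cylinder for
resistance purposes and a thin-walled elastic tube for compliance
purposes:

* `R = 128 μ l / (π D⁴)` (Poiseuille). No tapering, curvature,
  entrance-length or pulsatile (Womersley) corrections are applied, and
  the viscosity is a constant Newtonian value even though a Carreau
  curve is provided for reference — the non-Newtonian model belongs to
  3D CFD set-ups, not to the lumped formulas.
* `C = π D³ l / (4 G h)`. Only the product `G h` (Pa·m) is identifiable
  from a compliance value, so Young's modulus and wall thickness are
  carried jointly as a single "stiffness product".

**Default viscosity 0.0035 Pa·s.** Two blood viscosities circulate with
the bundled atlas (0.004 Pa·s for a simplified Newtonian set-up, 0.0035
Pa·s as the infinite-shear Carreau limit). Only 0.0035 reproduces the
atlas's per-segment resistances from their printed geometry, so it is
the package default; 0.004 is available as `NEWTONIAN_BLOOD`, and the
ambiguity is an entry in the discrepancy report.

**Stiffness products.** The atlas never states `G` or `h`. Inverting
`C = π D³ l / (4 G h)` row by row shows the implied `G h` clusters by
subtree: ≈ 2700 Pa·m for the intracranial (ICA-side) rows, ≈ 2333 Pa·m
for the ECA-side rows, and ≈ 23 400 Pa·m for the two tiny ophthalmic
vessels. These medians are the per-group defaults (`GH_DEFAULTS`); any
group or individual label can be overridden. Because the defaults are
reconstructions, the *printed* per-branch compliances — not recomputed
ones — are the canonical inputs to compliance reductions; recomputation
from geometry sits behind explicit wall-property overrides.

**Units.** All arithmetic is SI. Millimetre columns exist only in the
on-disk table formats and are converted at I/O time. Exported tables
round millimetre values to 9 decimals, which is far below any anatomical
measurement precision and makes export → import → export byte-stable.

## Composition algebra

Resistances combine like resistors, compliances like capacitors
(parallel: sum; series: harmonic sum). The capacitor analogy for
compliance is forced by the arithmetic of the bundled reduction chains
and verified against their tabulated values. Multiplicities are
per-leaf parallel copy counts and may be fractional (7.6 perforators).
Chains are evaluated in definition order at full floating precision —
never through the 3-significant-figure tabulated intermediates — and
comparisons against tabulated values use a 1 % relative tolerance to
absorb their per-row rounding.

A leaf may carry a separate `compliance_factor`. This exists purely to
encode the as-published dialect, whose distal-M4 step applies 16 lateral
orbitofrontal copies in the resistance chain but a single copy in the
compliance chain. The self-consistent dialect drops these overrides so
both chains use identical multiplicities. Both dialects share identical
base rows; the resistance chains are identical between dialects.

## The bundled atlas and its anomalies

38 segments (B1–B38), 29 reduction steps (19 ICA-side, 10 ECA-side),
and a parent→child topology table. The topology is informational; the
recipes are the source of truth for reduction order, because the
published arrangement places side branches in parallel with their trunk
and reuses trunk segments in ways a plain tree cannot express. Four
tabulated segments (B11, B13, B20, B21) appear in no reduction chain.

Documented anomalies, surfaced by `discrepancy_report()` and never
silently corrected:

* **B11** — the tabulated resistance follows from the row's diameter
  only with the alternate length 7.68 mm (stored on the row), not the
  tabulated 17.6 mm.
* **B13** — resistance reproduces only to ≈ 1.5 %, several times the
  rounding error of every other row, and the implied wall stiffness is
  an outlier.
* **R19 / C19** — the distal-ICA totals match *neither* the series nor
  the parallel composition of their stated inputs (R7/R18, C7/C18).
  Evaluation uses the parallel composition (the MCA and ACA trees are
  anatomically parallel), giving 7.88×10⁷ / 2.97×10⁻¹⁴ against the
  tabulated 5.89×10⁷ / 3.79×10⁻¹⁴. Outlet BC assembly carries both,
  tagged `printed` and `recomputed`, and the CLI warns when emitting the
  printed ICA outlet.
* **C1 / C7** — the LOFA multiplicity inconsistency described above and
  the MCA-branch total it propagates into.
* **R9/C9** — the MOFA step text says 16 parallel copies; the tabulated
  values correspond to the segment table's count of 15.
* **μ** — the viscosity ambiguity above.

The numeric part of the report is recomputed at run time by a generic
audit (`audit_tables`) at a 1 % threshold: tight enough to catch B13,
loose enough that rows that merely suffer 3-significant-figure rounding
(all ≤ 0.5 %) stay clean.

## Outlet boundary conditions

An outlet named X is the plane where a 3D model is truncated. `Rp` is
the lumped trunk element immediately downstream of the plane, `Rd` and
`C` the reduction of everything beyond it:

| outlet | Rp | Rd | C |
|---|---|---|---|
| ICA | B1 | R19 | C19 |
| ECA | B37 | R29 | C29 |
| MCA | R6 (M1 trunk + perforators) | R4 | C4 |
| ACA | B14 (A1 trunk) | R17 | C17 |
| M2 | B6 (M3 trunk) | R2 | C2 |
| M1, ophthalmic | 9 % of total | 91 % of total | subtree C |

For M1 and the ophthalmic artery the downstream tree reduces to a
single lump with no identifiable trunk segment, so the total resistance
is split by a conventional proximal fraction (9 %, in the range of
characteristic-impedance fractions used when tuning RCR outlets from a
total resistance alone). `Rp + Rd` always equals the subtree total.
The distal reference pressure defaults to 0 Pa — no venous reference is
published — and is configurable per outlet.

## 0D simulator

* **Scheme.** Backward Euler on the linear state equations. For a
  single outlet the state is the interface pressure; for multiple
  outlets each carries a capacitor-node pressure `Pc_i`, and the shared
  junction pressure is eliminated in closed form,
  `P_node = (Q_in + Σ Pc_i/Rp_i) / Σ(1/Rp_i)`, which makes the outlet
  flows sum to the inflow identically (observed balance error ~1e-15
  relative). The coupled update matrix is constant and LU-factored
  once. Backward Euler is first-order (verified by a dt-halving test)
  and unconditionally stable, which matters because atlas compliances
  give time-constant ratios spanning several orders of magnitude.
* **dQ/dt** comes from a periodic cubic spline of the waveform samples,
  not finite differences.
* **Defaults.** `dt = T/1000`, `max_cycles = 7`, convergence tolerance
  1e-4 (relative change of cycle-mean pressure and per-outlet mean
  flows between consecutive cycles). Initial capacitor pressures start
  at the distal reference; the transient is discarded by the
  convergence detector. `dt` coarser than `T/64` is rejected.
* **Oracles.** Constant inflow settles to `Pd + Q(Rp+Rd)` exactly (it
  is a fixed point of the discrete update). Sinusoidal forcing is
  checked against the impedance-phasor solution
  `P = Pd + Q₀(Rp+Rd) + Re[Z(ω)·Q̂·e^{iωt}]`,
  `Z(ω) = Rp + Rd/(1+iωRdC)`; at `dt = T/4000` the stepper agrees to
  ~3e-5 relative. Converged mean splits equal the inverse
  total-resistance divider for equal distal pressures (compliances carry
  no mean current over a cycle).

## Synthetic inflow

No clinical inflow waveform is published, so the generator stands in: a
truncated Fourier pulse `Q = Q̄(1 + Σ a_k cos(2πkt/T + φ_k))` with exact
cycle mean `Q̄`, defaulting to three harmonics (amplitudes 0.55 / 0.28 /
0.12) chosen to give a carotid-like systolic peak ≈ 1.9× mean and a
diastolic floor ≈ 0.6× mean. Presets exist for the two cardiac periods
used by the validation scenarios, 0.55 s and 0.753 s, with mean
5.35 cm³/s. Parameter sets producing negative flow are rejected unless
explicitly allowed. The generator emulates periodicity, pulsatility and
mean level only — not beat-to-beat variability, measured harmonic
content, or flow reversal — so simulator tests demonstrate correctness
of the 0D network dynamics, not fidelity to any patient's waveform.

## Known limitations

* The 0D ICA/ECA mean split implied by the bundled as-published totals
  is ≈ 40 % ICA, far from the ≈ 70/30 clinical split that 3D CFD with
  these parameters has been reported to achieve. The 0D
  resistive-divider result is a mathematical consequence of the printed
  totals; the exact boundary-condition configuration used in any 3D
  solver cannot be reconstructed from them. The package reports the 0D
  prediction and does not force agreement.
* No 1D pulse-wave propagation, no inertance (4-element Windkessel), no
  fluid–structure interaction, no patient-specific tree building.
* The atlas makes no claim of anatomical completeness (small M2 and
  ophthalmic branches are deliberately absent).

## Problem sizes

The test suite and the acceptance script run everything at full fidelity
— the atlas is only 38 segments and the simulator a handful of states —
except that randomized split checks use 5 outlet sets of 2–4 outlets
and the stepper-oracle comparison uses 4000 steps/cycle, both chosen as
comfortably sufficient for the tolerances quoted above.
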