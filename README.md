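# carotidwk

**Three-element Windkessel outlet boundary conditions for carotid-artery
CFD, estimated analytically from downstream vessel geometry.**

## The problem

Image-based CFD of the carotid bifurcation needs outlet boundary
conditions that represent everything downstream of the model's cut
planes — the middle cerebral (MCA), anterior cerebral (ACA), ophthalmic
and facial arterial beds. The usual three-element Windkessel (RCR)
model lumps each bed into a proximal resistance `Rp`, a compliance `C`
and a distal resistance `Rd`, but its parameters are normally tuned by
trial and error against clinical data that is often unavailable.
`carotidwk` implements the alternative: estimate the parameters directly
from published anatomical geometry of the downstream tree.

The per-segment physics is classical. A segment of diameter `D` and
length `l` carrying laminar flow of a fluid with viscosity `μ` has
Poiseuille resistance and elastic-tube compliance

    R = 128 μ l / (π D⁴)          C = π D³ l / (4 G h)

with `G h` the wall stiffness product (Young's modulus × wall
thickness). Segments then combine like circuit elements — series:
`R = ΣRᵢ`, `1/C = Σ1/Cᵢ`; parallel: `1/R = Σnᵢ/Rᵢ`, `C = ΣnᵢCᵢ`, with
possibly fractional branch counts `nᵢ` — reducing a whole subtree to a
single lumped element. For a prescribed outlet flow `Q(t)` the RCR
interface pressure `P(t)` obeys

    Q (1 + Rp/Rd) + C Rp dQ/dt = (P − Pd)/Rd + C dP/dt

which the package integrates with backward Euler; several outlets can
share a junction node whose pressure is eliminated exactly so that the
outlet flows sum to the prescribed inflow.

The package bundles a 38-segment atlas of the carotid tree (ICA trunk,
MCA segments M1–M4, ACA segments A1–A5 and their cortical/perforating
branches, the ophthalmic pair, and the ECA facial branches) with
reference resistance/compliance values and the named reduction chains
R1–R29 / C1–C29 that collapse each subtree. The reference tables
contain documented internal inconsistencies; the atlas reproduces them
faithfully in an `as-published` dialect, provides a `self-consistent`
dialect, and enumerates every anomaly in a discrepancy report rather
than silently fixing anything.

## Worked example

Emit the ECA outlet boundary condition (SI units):

```sh
$ carotidwk bc --outlet ECA
[
  {
    "outlet": "ECA",
    "Rp": 11100000.0,
    "C": 3.89e-13,
    "Rd": 31900000.0,
    "distal_pressure": 0.0,
    "units": "SI",
    "provenance": "printed",
    "display": { "Rp": "1.11E+07", "C": "3.89E-13", "Rd": "3.19E+07" }
  }
]
```

`Rp` is the proximal ECA trunk resistance, `Rd` and `C` the reduced
distal facial tree (chain steps R29/C29). Simulate both carotid outlets
fed by a synthetic pulsatile common-carotid inflow (period 0.55 s, mean
5.35 cm³/s):

```sh
$ carotidwk simulate --outlets ICA,ECA --output run.csv --summary run.json
cycles run: 2 (converged: True)
mean split ICA: 40.30%
mean split ECA: 59.70%
wrote run.csv
```

The converged cycle-mean split equals the inverse total-resistance
divider of the two outlets — with the bundled as-published totals the 0D
network sends 40.3 % of the common-carotid flow to the ICA. (A healthy
carotid bifurcation splits roughly 70/30 in favour of the ICA; the gap
is a property of the published resistance totals themselves, and is one
reason the package reports both printed and recomputed values.) The
same library calls are available in Python:

```python
import carotidwk as cw

bcs = cw.outlet_boundary_conditions()          # all seven outlets
eca = bcs.get("ECA", "printed")                # WindkesselBC(Rp, C, Rd, Pd)
inflow = cw.synth_inflow(period=0.55, mean_flow=5.35e-6)
result = cw.multi_outlet_split(inflow, {"ICA": bcs.get("ICA"), "ECA": eca})
print(result.mean_splits)                      # {'ICA': 0.403, 'ECA': 0.597}
```

Inspect the atlas and its known anomalies:

```sh
$ carotidwk atlas --report
carotid atlas v1.0, dialect=as-published: 38 segments, 29 reduction steps
   id                       kind      value_a      value_b  ...
  B11         segment-resistance 2.360000e+07 5.408524e+07  ...
  R19       reduction-resistance 5.890000e+07 7.877335e+07  ...
  ...
```

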