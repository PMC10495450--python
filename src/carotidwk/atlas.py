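"""Bundled carotid arterial tree atlas.

The package ships a 38-segment description (labels B1–B38) of the
vasculature distal to the common carotid bifurcation — the internal
carotid (ICA) trunk with its middle cerebral (MCA, segments M1–M4),
anterior cerebral (ACA, segments A1–A5) and ophthalmic subtrees, and the
external carotid (ECA) trunk with its facial branches — together with
the named series/parallel reduction chains (R1–R29 / C1–C29) that
collapse each subtree to a lumped distal element, and reference
resistance/compliance values rounded to three significant figures.

The reference tables contain a handful of internal inconsistencies
(mismatched branch counts between the resistance and compliance chains,
one distal total that matches neither composition of its inputs, two
segment rows whose resistance does not follow from their printed
geometry).  Two recipe dialects are therefore provided:

* ``as-published`` — reproduces the reference arithmetic exactly as
  tabulated, inconsistencies included;
* ``self-consistent`` — applies identical branch multiplicities to the
  resistance and compliance chains.

Anomalies are surfaced by :func:`discrepancy_report`, never silently
corrected.  Reference per-branch compliances (not recomputed ones) are
the canonical inputs to compliance reductions, because the wall
stiffness behind them is not published; recomputation from geometry is
available behind explicit wall-property overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .network import (RecipeEntry, RecipeTable, ReductionNode,
                      combine_parallel, evaluate_recipes)
from .sim import WindkesselBC
from .vessel import (DEFAULT_BLOOD, GH_DEFAULTS, FluidProperties,
                     LumpedElement, VesselSegment, WallProperties,
                     calibrate_stiffness_product, elastic_compliance,
                     poiseuille_resistance)

__all__ = [
    "AtlasRow",
    "Atlas",
    "OutletBCSet",
    "ATLAS_VERSION",
    "DIALECTS",
    "OUTLET_NAMES",
    "PROXIMAL_FRACTION",
    "load_atlas",
    "recompute_table",
    "outlet_boundary_conditions",
    "audit_tables",
    "discrepancy_report",
]

ATLAS_VERSION = "1.0"
DIALECTS = ("as-published", "self-consistent")

#: Outlets for which boundary conditions can be assembled.
OUTLET_NAMES = ("ICA", "ECA", "MCA", "ACA", "M1", "M2", "ophthalmic")

#: Proximal share of the total resistance used when an outlet's
#: downstream tree reduces to a single lump with no identifiable trunk
#: segment (conventional characteristic-impedance fraction).
PROXIMAL_FRACTION = 0.09


@dataclass(frozen=True)
class AtlasRow:
    """One atlas segment: geometry (if any) plus reference R and C."""

    label: str
    name: str
    segment: VesselSegment | None
    printed_resistance: float
    printed_compliance: float
    group: str
    alt_length_mm: float | None = None
    anomaly: str = ""

    @property
    def printed_element(self) -> LumpedElement:
        return LumpedElement(self.printed_resistance, self.printed_compliance)


@dataclass(frozen=True)
class Atlas:
    """Immutable atlas fixture: rows, reduction recipes and topology."""

    version: str
    dialect: str
    rows: tuple[AtlasRow, ...]
    recipes: RecipeTable
    topology: tuple[tuple[str, str, float], ...]

    def row(self, label: str) -> AtlasRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(f"unknown atlas label {label!r}")

    def base_elements(self) -> dict[str, LumpedElement]:
        """Reference (printed) lumped element of every segment row."""
        return {r.label: r.printed_element for r in self.rows}

    def evaluate(self) -> dict[str, LumpedElement]:
        """Full-precision evaluation of every reduction intermediate."""
        return evaluate_recipes(self.recipes, self.base_elements())


def _data_text(filename: str) -> str:
    return (resources.files("carotidwk") / "data" / filename).read_text()


def _load_rows() -> tuple[AtlasRow, ...]:
    frame = pd.read_csv(
        resources.files("carotidwk") / "data" / "carotid_segments.csv",
        dtype={"label": str, "name": str, "group": str, "anomaly": str},
    )
    rows = []
    for rec in frame.to_dict("records"):
        label = rec["label"]
        has_geom = not (pd.isna(rec["diameter_mm"]) or pd.isna(rec["length_mm"]))
        segment = None
        if has_geom:
            segment = VesselSegment.from_mm(
                label=label,
                name=rec["name"],
                diameter_mm=float(rec["diameter_mm"]),
                length_mm=float(rec["length_mm"]),
                multiplicity=float(rec["count"]),
                group=rec["group"],
            )
        alt = rec.get("alt_length_mm")
        rows.append(
            AtlasRow(
                label=label,
                name=rec["name"],
                segment=segment,
                printed_resistance=float(rec["printed_resistance"]),
                printed_compliance=float(rec["printed_compliance"]),
                group=rec["group"],
                alt_length_mm=None if pd.isna(alt) else float(alt),
                anomaly="" if pd.isna(rec.get("anomaly")) else str(rec["anomaly"]),
            )
        )
    return tuple(rows)


def _node_from_dict(spec: Mapping, dialect: str) -> ReductionNode:
    children = []
    for child in spec["children"]:
        cf = child.get("compliance_factor")
        if dialect == "self-consistent":
            cf = None
        children.append(
            ReductionNode.leaf(child["ref"], factor=child.get("factor", 1.0),
                               compliance_factor=cf)
        )
    if spec["mode"] == "series":
        return ReductionNode.series(*children)
    return ReductionNode.parallel(*children)


def _load_recipes(dialect: str) -> tuple[RecipeTable, dict[str, float]]:
    entries: list[RecipeEntry] = []
    printed: dict[str, float] = {}
    for filename in ("recipes_ica.yaml", "recipes_eca.yaml"):
        doc = yaml.safe_load(_data_text(filename))
        for spec in doc["entries"]:
            entries.append(
                RecipeEntry(
                    name=spec["name"],
                    node=_node_from_dict(spec, dialect),
                    aliases=tuple(spec.get("aliases", ())),
                    note=spec.get("note", ""),
                )
            )
            printed[spec["name"]] = float(spec["printed_resistance"])
            for alias in spec.get("aliases", ()):
                printed[alias] = float(spec["printed_compliance"])
    return RecipeTable(tuple(entries)), printed


def printed_intermediates() -> dict[str, float]:
    """Reference values of every reduction intermediate (R* and C* names)."""
    _, printed = _load_recipes("as-published")
    return printed


def load_atlas(dialect: str = "as-published") -> Atlas:
    """Load the bundled carotid atlas in the requested recipe dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    rows = _load_rows()
    recipes, _ = _load_recipes(dialect)
    recipes.validate(r.label for r in rows)
    topo_doc = yaml.safe_load(_data_text("topology.yaml"))
    topology = tuple(
        (e["parent"], e["child"], float(e.get("multiplicity", 1.0)))
        for e in topo_doc["edges"]
    )
    return Atlas(version=ATLAS_VERSION, dialect=dialect, rows=rows,
                 recipes=recipes, topology=topology)


def recompute_table(
    atlas: Atlas | None = None,
    fluid: FluidProperties = DEFAULT_BLOOD,
    wall_overrides: Mapping[str, float] | None = None,
    use_alt_length: bool = False,
) -> pd.DataFrame:
    """Re-derive every atlas row from its geometry and compare.

    Resistance is recomputed from the Poiseuille formula; compliance
    from the elastic-tube formula using per-group default stiffness
    products, overridable per group or per label via ``wall_overrides``
    (Pa m).  Geometry-free rows (the composed ophthalmic lump B28) are
    recomputed as the parallel combination of their constituent rows.
    ``use_alt_length`` substitutes documented alternate lengths where
    present.  Returns one row per label with relative errors and
    propagated anomaly notes.
    """
    if atlas is None:
        atlas = load_atlas()
    overrides = dict(wall_overrides or {})
    records = []
    for row in atlas.rows:
        rec: dict = {
            "label": row.label,
            "name": row.name,
            "group": row.group,
            "printed_resistance": row.printed_resistance,
            "printed_compliance": row.printed_compliance,
            "anomaly": row.anomaly,
        }
        if row.segment is None:
            # Composed lump: parallel combination of the ophthalmic leaves.
            parts = [atlas.row(lbl).printed_element for lbl in ("B26", "B27")]
            composed = combine_parallel(parts)
            rec.update(
                method="composed",
                computed_resistance=composed.resistance,
                computed_compliance=composed.compliance,
                stiffness_product=math.nan,
            )
        else:
            seg = row.segment
            if use_alt_length and row.alt_length_mm is not None:
                seg = VesselSegment.from_mm(
                    seg.label, seg.name, seg.diameter * 1e3, row.alt_length_mm,
                    seg.multiplicity, seg.group,
                )
            gh = overrides.get(row.label, overrides.get(row.group,
                                                       GH_DEFAULTS[row.group]))
            rec.update(
                method="geometry",
                computed_resistance=poiseuille_resistance(seg, fluid),
                computed_compliance=elastic_compliance(seg, WallProperties(gh)),
                stiffness_product=calibrate_stiffness_product(
                    seg.diameter, seg.length, row.printed_compliance
                ),
            )
        rec["rel_error_resistance"] = (
            abs(rec["computed_resistance"] - row.printed_resistance)
            / row.printed_resistance
        )
        rec["rel_error_compliance"] = (
            abs(rec["computed_compliance"] - row.printed_compliance)
            / row.printed_compliance
        )
        records.append(rec)
    cols = ["label", "name", "group", "method",
            "printed_resistance", "computed_resistance", "rel_error_resistance",
            "printed_compliance", "computed_compliance", "rel_error_compliance",
            "stiffness_product", "anomaly"]
    return pd.DataFrame(records, columns=cols)


def _bc(rp: float, c: float, rd: float, distal_pressure: float) -> WindkesselBC:
    return WindkesselBC(proximal_resistance=rp, compliance=c,
                        distal_resistance=rd, distal_pressure=distal_pressure)


def _assemble(values: Mapping[str, float], distal_pressure: float) -> dict[str, WindkesselBC]:
    """Build the outlet map from a name->value mapping of R/C quantities.

    ``values`` must contain, for every outlet, the keys used below;
    printed and recomputed variants supply different numbers through the
    same wiring.  Outlets whose downstream tree is a single lump
    (ophthalmic, M1) split the total resistance into a conventional
    proximal fraction and a distal remainder.
    """
    f = PROXIMAL_FRACTION
    return {
        "ICA": _bc(values["B1_r"], values["C19"], values["R19"], distal_pressure),
        "ECA": _bc(values["B37_r"], values["C29"], values["R29"], distal_pressure),
        "MCA": _bc(values["R6"], values["C4"], values["R4"], distal_pressure),
        "ACA": _bc(values["B14_r"], values["C17"], values["R17"], distal_pressure),
        "M1": _bc(f * values["R4"], values["C4"], (1 - f) * values["R4"],
                  distal_pressure),
        "M2": _bc(values["B6_r"], values["C2"], values["R2"], distal_pressure),
        "ophthalmic": _bc(f * values["B28_r"], values["B28_c"],
                          (1 - f) * values["B28_r"], distal_pressure),
    }


@dataclass(frozen=True)
class OutletBCSet:
    """Windkessel boundary conditions for the carotid outlets.

    Each outlet carries two provenance variants: ``printed`` (assembled
    from the rounded reference tables) and ``recomputed`` (assembled
    from the full-precision recipe evaluation).  ``flags`` documents
    outlets whose printed values are anomalous.
    """

    dialect: str
    printed: Mapping[str, WindkesselBC]
    recomputed: Mapping[str, WindkesselBC]
    flags: Mapping[str, str]

    def get(self, outlet: str, provenance: str = "printed") -> WindkesselBC:
        if provenance not in ("printed", "recomputed"):
            raise ValueError(f"unknown provenance {provenance!r}")
        table = self.printed if provenance == "printed" else self.recomputed
        if outlet not in table:
            raise KeyError(
                f"unknown outlet {outlet!r}; expected one of {tuple(table)}"
            )
        return table[outlet]

    def names(self) -> tuple[str, ...]:
        return tuple(self.printed)


def outlet_boundary_conditions(
    dialect: str = "as-published",
    distal_pressure: float = 0.0,
    atlas: Atlas | None = None,
) -> OutletBCSet:
    """Assemble three-element Windkessel BCs for every carotid outlet.

    The ICA outlet takes the proximal ICA trunk (B1) as Rp and the
    distal-tree totals (R19/C19) as Rd/C; the ECA outlet takes the
    proximal ECA trunk (B37) and the R29/C29 totals; MCA, ACA, M1, M2
    and ophthalmic are assembled from the corresponding subtree
    reductions.  The printed ICA distal totals are flagged: they match
    neither the series nor the parallel composition of their inputs.
    """
    if atlas is None:
        atlas = load_atlas(dialect)
    elif atlas.dialect != dialect:
        raise ValueError("atlas dialect does not match requested dialect")
    evaluated = atlas.evaluate()
    printed_inter = printed_intermediates()

    def row_r(lbl: str) -> float:
        return atlas.row(lbl).printed_resistance

    def row_c(lbl: str) -> float:
        return atlas.row(lbl).printed_compliance

    shared = {
        "B1_r": row_r("B1"), "B37_r": row_r("B37"), "B14_r": row_r("B14"),
        "B6_r": row_r("B6"), "B28_r": row_r("B28"), "B28_c": row_c("B28"),
    }
    printed_vals = dict(shared)
    printed_vals.update({k: printed_inter[k] for k in
                         ("R19", "C19", "R29", "C29", "R6", "R4", "C4",
                          "R17", "C17", "R2", "C2")})
    recomputed_vals = dict(shared)
    recomputed_vals.update({
        "R19": evaluated["R19"].resistance, "C19": evaluated["C19"].compliance,
        "R29": evaluated["R29"].resistance, "C29": evaluated["C29"].compliance,
        "R6": evaluated["R6"].resistance, "R4": evaluated["R4"].resistance,
        "C4": evaluated["C4"].compliance, "R17": evaluated["R17"].resistance,
        "C17": evaluated["C17"].compliance, "R2": evaluated["R2"].resistance,
        "C2": evaluated["C2"].compliance,
    })
    comp = combine_parallel([atlas.row("B26").printed_element,
                             atlas.row("B27").printed_element])
    recomputed_vals["B28_r"] = comp.resistance
    recomputed_vals["B28_c"] = comp.compliance

    flags = {
        "ICA": (
            "printed distal totals R19/C19 match neither the series nor the "
            "parallel composition of R7/R18 (C7/C18); recomputed variant uses "
            "the parallel composition"
        ),
    }
    return OutletBCSet(
        dialect=dialect,
        printed=_assemble(printed_vals, distal_pressure),
        recomputed=_assemble(recomputed_vals, distal_pressure),
        flags=flags,
    )


def audit_tables(
    rows: tuple[AtlasRow, ...] | None = None,
    recipes: RecipeTable | None = None,
    fluid: FluidProperties = DEFAULT_BLOOD,
    rel_tol: float = 0.01,
    reference_intermediates: Mapping[str, float] | None = None,
) -> list[dict]:
    """Numeric audit: recompute everything, list mismatches above ``rel_tol``.

    Checks every geometric row's resistance against its reference value
    and every reduction intermediate (evaluated at full precision from
    the reference per-segment values) against its reference value.
    Returns a deterministic list of mismatch records; empty for a
    self-consistent table.
    """
    if rows is None or recipes is None:
        atlas = load_atlas("as-published")
        rows = rows if rows is not None else atlas.rows
        recipes = recipes if recipes is not None else atlas.recipes
    findings: list[dict] = []
    for row in rows:
        if row.segment is None:
            continue
        computed = poiseuille_resistance(row.segment, fluid)
        err = abs(computed - row.printed_resistance) / row.printed_resistance
        if err > rel_tol:
            findings.append({
                "id": row.label, "kind": "segment-resistance",
                "reference": row.printed_resistance, "recomputed": computed,
                "rel_error": err, "note": row.anomaly,
            })
    base = {r.label: r.printed_element for r in rows}
    evaluated = evaluate_recipes(recipes, base)
    if reference_intermediates is None:
        reference_intermediates = printed_intermediates()
    return findings + _recipe_findings(evaluated, recipes,
                                       reference_intermediates, rel_tol)


def _recipe_findings(evaluated, recipes: RecipeTable,
                     printed: Mapping[str, float], rel_tol: float) -> list[dict]:
    findings = []
    for entry in recipes:
        for name, attr in ((entry.name, "resistance"), *(
                (a, "compliance") for a in entry.aliases)):
            if name not in printed:
                continue
            computed = getattr(evaluated[name], attr)
            ref = printed[name]
            err = abs(computed - ref) / ref
            if err > rel_tol:
                findings.append({
                    "id": name, "kind": f"reduction-{attr}",
                    "reference": ref, "recomputed": computed,
                    "rel_error": err, "note": entry.note,
                })
    return findings


def discrepancy_report() -> pd.DataFrame:
    """Every known mismatch between the reference tables and recomputation.

    Enumerates, with both candidate values, the documented anomaly set:
    two segment rows whose printed resistance does not follow from their
    printed geometry (B11, B13), the irreproducible distal ICA totals
    (R19, C19), the branch-count inconsistency between the resistance
    and compliance chains of the distal M4 step and the MCA total it
    propagates into (C1, C7), the MOFA count mismatch between step text
    and tabulated value (R9/C9), and the two tabulated blood viscosities
    (mu).  Deterministic and sorted by id.
    """
    atlas = load_atlas("as-published")
    evaluated = atlas.evaluate()
    records: list[dict] = []

    numeric = audit_tables(atlas.rows, atlas.recipes, rel_tol=0.01)
    for f in numeric:
        records.append({
            "id": f["id"], "kind": f["kind"], "value_a": f["reference"],
            "value_b": f["recomputed"], "note": f["note"] or
            "reference value not reproduced by recomputation",
        })

    sc = load_atlas("self-consistent").evaluate()
    for name in ("C1", "C7"):
        records.append({
            "id": name, "kind": "multiplicity-inconsistency",
            "value_a": evaluated[name].compliance,
            "value_b": sc[name].compliance,
            "note": ("compliance chain uses a single LOFA copy where the "
                     "resistance chain uses 16; value_b applies 16 to both"),
        })
    el = atlas.row("B22").printed_element
    records.append({
        "id": "R9/C9", "kind": "multiplicity-inconsistency",
        "value_a": el.resistance / 15.0, "value_b": el.resistance / 16.0,
        "note": ("MOFA step text says 16 parallel copies but the tabulated "
                 "values correspond to the segment count of 15"),
    })
    records.append({
        "id": "mu", "kind": "parameter-ambiguity",
        "value_a": 0.0035, "value_b": 0.004,
        "note": ("two blood viscosities are quoted; only 0.0035 Pa s (the "
                 "infinite-shear Carreau value) reproduces the per-segment "
                 "resistances"),
    })
    frame = pd.DataFrame(records, columns=["id", "kind", "value_a",
                                           "value_b", "note"])
    return frame.sort_values("id", kind="stable").reset_index(drop=True)
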