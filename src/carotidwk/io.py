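"""File formats: segment tables, waveforms, recipes, boundary conditions.

Everything is plain text.  Segment tables are CSV (or an equivalent
JSON list of records) with header ``label,name,diameter_mm,length_mm,
count,group``; geometry columns are millimetres on disk and converted to
SI metres on read.  Waveforms are two-column CSV ``time_s,flow_m3s``
spanning one period.  Boundary conditions and run summaries are JSON
with full-precision values plus 3-significant-figure display fields.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .network import RecipeEntry, RecipeTable, ReductionNode
from .sim import SimResult, Waveform, WindkesselBC
from .vessel import VesselSegment

__all__ = [
    "read_segment_table",
    "write_segment_table",
    "read_waveform",
    "write_waveform",
    "read_recipes",
    "write_recipes",
    "bc_to_dict",
    "write_bc_json",
    "read_bc_json",
    "write_sim_result",
]

SEGMENT_COLUMNS = ("label", "name", "diameter_mm", "length_mm", "count", "group")


def _display(value: float) -> str:
    """3-significant-figure scientific display, mirroring tabular style."""
    return f"{value:.2E}"


def read_segment_table(path: str | Path) -> list[VesselSegment]:
    """Read a segment table (CSV or JSON by extension) into SI segments.

    Rejects malformed rows with the (1-based, header-inclusive) line
    number, duplicate labels, and unknown groups; row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        first_line = 1
    else:
        frame = pd.read_csv(path, dtype={"label": str, "name": str, "group": str})
        missing = [c for c in SEGMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        records = frame.to_dict("records")
        first_line = 2  # header is line 1
    segments: list[VesselSegment] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        line = first_line + i
        try:
            count = rec.get("count", 1)
            if count is None or (isinstance(count, float) and math.isnan(count)):
                count = 1
            seg = VesselSegment.from_mm(
                label=str(rec["label"]),
                name=str(rec.get("name", "")),
                diameter_mm=float(rec["diameter_mm"]),
                length_mm=float(rec["length_mm"]),
                multiplicity=float(count),
                group=str(rec["group"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
        if seg.label in seen:
            raise ValueError(f"{path}, line {line}: duplicate label {seg.label!r}")
        seen.add(seg.label)
        segments.append(seg)
    return segments


def write_segment_table(segments: Sequence[VesselSegment], path: str | Path) -> None:
    """Write segments back to CSV or JSON (mm units), roundtrip-stable."""
    path = Path(path)
    # mm values rounded to 9 decimals: removes conversion noise far below
    # measurement precision and makes export -> import -> export idempotent
    records = [
        {
            "label": s.label,
            "name": s.name,
            "diameter_mm": round(s.diameter * 1e3, 9),
            "length_mm": round(s.length * 1e3, 9),
            "count": round(s.multiplicity, 9),
            "group": s.group,
        }
        for s in segments
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    else:
        pd.DataFrame(records, columns=SEGMENT_COLUMNS).to_csv(path, index=False)


def read_waveform(path: str | Path, period: float | None = None) -> Waveform:
    """Read a ``time_s,flow_m3s`` CSV covering one period.

    The period defaults to the last time sample (the grid should close
    the cycle at t = T).
    """
    frame = pd.read_csv(path)
    for col in ("time_s", "flow_m3s"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    t = frame["time_s"].to_numpy(dtype=float)
    q = frame["flow_m3s"].to_numpy(dtype=float)
    if period is None:
        period = float(t[-1])
    return Waveform(period=period, time=t, flow=q)


def write_waveform(waveform: Waveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": waveform.time, "flow_m3s": waveform.flow}).to_csv(
        Path(path), index=False
    )


def _node_to_dict(node: ReductionNode) -> dict:
    if node.mode != "leaf":
        raise ValueError("only flat recipes (leaf children) are serialised")
    out: dict = {"ref": node.ref, "factor": node.factor}
    if node.compliance_factor is not None:
        out["compliance_factor"] = node.compliance_factor
    return out


def write_recipes(recipes: RecipeTable, path: str | Path) -> None:
    """Serialise a recipe table to YAML ({name, mode, children:[{ref, factor}]})."""
    entries = []
    for entry in recipes:
        entries.append({
            "name": entry.name,
            "aliases": list(entry.aliases),
            "mode": entry.node.mode,
            "children": [_node_to_dict(c) for c in entry.node.children],
            "note": entry.note,
        })
    Path(path).write_text(yaml.safe_dump({"entries": entries}, sort_keys=False))


def read_recipes(path: str | Path) -> RecipeTable:
    doc = yaml.safe_load(Path(path).read_text())
    entries = []
    for spec in doc["entries"]:
        children = [
            ReductionNode.leaf(c["ref"], factor=c.get("factor", 1.0),
                               compliance_factor=c.get("compliance_factor"))
            for c in spec["children"]
        ]
        node = (ReductionNode.series(*children) if spec["mode"] == "series"
                else ReductionNode.parallel(*children))
        entries.append(RecipeEntry(name=spec["name"], node=node,
                                   aliases=tuple(spec.get("aliases", ())),
                                   note=spec.get("note", "")))
    return RecipeTable(tuple(entries))


def bc_to_dict(outlet: str, bc: WindkesselBC, provenance: str) -> dict:
    """Solver-agnostic JSON record for one outlet boundary condition."""
    return {
        "outlet": outlet,
        "Rp": bc.proximal_resistance,
        "C": bc.compliance,
        "Rd": bc.distal_resistance,
        "distal_pressure": bc.distal_pressure,
        "units": "SI",
        "provenance": provenance,
        "display": {
            "Rp": _display(bc.proximal_resistance),
            "C": _display(bc.compliance),
            "Rd": _display(bc.distal_resistance),
        },
    }


def write_bc_json(
    bcs: Mapping[str, WindkesselBC], path: str | Path, provenance: str
) -> None:
    records = [bc_to_dict(name, bc, provenance) for name, bc in bcs.items()]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_bc_json(path: str | Path) -> dict[str, WindkesselBC]:
    records = json.loads(Path(path).read_text())
    return {
        rec["outlet"]: WindkesselBC(
            proximal_resistance=rec["Rp"],
            compliance=rec["C"],
            distal_resistance=rec["Rd"],
            distal_pressure=rec.get("distal_pressure", 0.0),
        )
        for rec in records
    }


def write_sim_result(result: SimResult, csv_path: str | Path,
                     summary_path: str | Path | None = None) -> None:
    """Tidy per-step CSV plus an optional JSON run summary."""
    data = {"time_s": result.time, "pressure_pa": result.pressure}
    for name, q in result.flows.items():
        data[f"flow_{name}_m3s"] = q
    pd.DataFrame(data).to_csv(Path(csv_path), index=False)
    if summary_path is not None:
        summary = {
            "cycles": result.cycles_run,
            "converged": result.converged,
            "converged_cycle": result.converged_cycle,
            "mean_splits": result.mean_splits,
            "flow_balance_error": result.flow_balance_error,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")
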