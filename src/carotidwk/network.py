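"""Electrical-analog composition algebra for lumped vascular elements.

Resistances and compliances of vessel segments combine like resistors
and capacitors in a circuit:

===========  =========================  =====================
arrangement  resistance                 compliance
===========  =========================  =====================
series       R = sum(R_i)               1/C = sum(1/C_i)
parallel     1/R = sum(n_i / R_i)       C = sum(n_i * C_i)
===========  =========================  =====================

``n_i`` is the (possibly fractional) number of identical parallel copies
of element *i* — perforator bundles such as 7.6 subcallosal branches are
handled without rounding.

Reduction recipes — ordered, named series/parallel composition
expressions over a base table of segment elements — are represented as
small trees (:class:`ReductionNode`) and evaluated in definition order at
full floating-point precision.  A comparison helper scores evaluated
chains against externally tabulated (rounded) values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .vessel import LumpedElement

__all__ = [
    "ReductionNode",
    "RecipeEntry",
    "RecipeTable",
    "combine_series",
    "combine_parallel",
    "scale_parallel",
    "evaluate_recipes",
    "compare_to_printed",
]

_MODES = ("leaf", "series", "parallel")


@dataclass(frozen=True)
class ReductionNode:
    """A node of a reduction expression.

    Leaves reference a named element and carry a parallel multiplicity
    ``factor`` (> 0, fractional allowed).  ``compliance_factor`` lets a
    leaf apply a different multiplicity to the compliance than to the
    resistance; it defaults to ``factor`` and exists only to encode
    published reduction tables whose resistance and compliance chains
    disagree about a branch count.  Internal nodes combine their children
    in ``series`` or ``parallel``.
    """

    mode: str
    ref: str | None = None
    factor: float = 1.0
    compliance_factor: float | None = None
    children: tuple["ReductionNode", ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown node mode {self.mode!r}")
        if self.mode == "leaf":
            if not self.ref:
                raise ValueError("leaf node requires a ref")
            if not (self.factor > 0 and math.isfinite(self.factor)):
                raise ValueError(f"leaf {self.ref}: factor must be > 0")
            if self.compliance_factor is not None and not (
                self.compliance_factor > 0 and math.isfinite(self.compliance_factor)
            ):
                raise ValueError(f"leaf {self.ref}: compliance_factor must be > 0")
        else:
            if len(self.children) < 1:
                raise ValueError(f"{self.mode} node requires at least one child")

    # -- constructors -------------------------------------------------
    @classmethod
    def leaf(cls, ref: str, factor: float = 1.0,
             compliance_factor: float | None = None) -> "ReductionNode":
        return cls("leaf", ref=ref, factor=float(factor),
                   compliance_factor=None if compliance_factor is None
                   else float(compliance_factor))

    @classmethod
    def series(cls, *children: "ReductionNode") -> "ReductionNode":
        return cls("series", children=tuple(children))

    @classmethod
    def parallel(cls, *children: "ReductionNode") -> "ReductionNode":
        return cls("parallel", children=tuple(children))

    def references(self) -> tuple[str, ...]:
        """All element names referenced below this node, in order."""
        if self.mode == "leaf":
            return (self.ref,)  # type: ignore[return-value]
        out: list[str] = []
        for child in self.children:
            out.extend(child.references())
        return tuple(out)


@dataclass(frozen=True)
class RecipeEntry:
    """One named step of a reduction chain.

    ``aliases`` are alternative names resolving to the same evaluated
    element (a resistance chain ``R7`` and compliance chain ``C7`` with
    identical structure share one entry).
    """

    name: str
    node: ReductionNode
    aliases: tuple[str, ...] = ()
    note: str = ""


@dataclass(frozen=True)
class RecipeTable:
    """Ordered, named reduction recipes; later entries may cite earlier ones."""

    entries: tuple[RecipeEntry, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for entry in self.entries:
            for name in (entry.name, *entry.aliases):
                if name in seen:
                    raise ValueError(f"duplicate recipe name {name!r}")
                seen.add(name)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.entries)

    def validate(self, base_labels: Iterable[str]) -> None:
        """Check every reference resolves to a base label or an earlier entry."""
        known = set(base_labels)
        for entry in self.entries:
            for ref in entry.node.references():
                if ref not in known:
                    raise ValueError(
                        f"recipe {entry.name!r} references unknown element {ref!r}"
                    )
            known.add(entry.name)
            known.update(entry.aliases)


def combine_series(elements: Sequence[LumpedElement]) -> LumpedElement:
    """Series combination: resistances add, compliances add harmonically."""
    if len(elements) == 0:
        raise ValueError("combine_series requires at least one element")
    resistance = sum(e.resistance for e in elements)
    inv_c = 0.0
    for e in elements:
        if e.compliance == 0.0:
            raise ValueError("series combination undefined for zero compliance")
        inv_c += 1.0 / e.compliance
    return LumpedElement(resistance, 1.0 / inv_c)


def scale_parallel(element: LumpedElement, factor: float,
                   compliance_factor: float | None = None) -> LumpedElement:
    """``factor`` identical copies of ``element`` in parallel: R/n and n*C."""
    if not (factor > 0 and math.isfinite(factor)):
        raise ValueError(f"factor must be > 0, got {factor!r}")
    cf = factor if compliance_factor is None else compliance_factor
    return LumpedElement(element.resistance / factor, element.compliance * cf)


def combine_parallel(
    elements: Sequence[LumpedElement],
    factors: Sequence[float] | None = None,
) -> LumpedElement:
    """Parallel combination with per-element multiplicities.

    1/R = sum(n_i / R_i) and C = sum(n_i * C_i); ``factors`` defaults to
    all ones and may be fractional.
    """
    if len(elements) == 0:
        raise ValueError("combine_parallel requires at least one element")
    if factors is None:
        factors = [1.0] * len(elements)
    if len(factors) != len(elements):
        raise ValueError("factors and elements must have equal length")
    inv_r = 0.0
    compliance = 0.0
    for e, n in zip(elements, factors):
        if not (n > 0 and math.isfinite(n)):
            raise ValueError(f"parallel factor must be > 0, got {n!r}")
        if e.resistance == 0.0:
            raise ValueError("parallel combination undefined for zero resistance")
        inv_r += n / e.resistance
        compliance += n * e.compliance
    return LumpedElement(1.0 / inv_r, compliance)


def _evaluate_node(node: ReductionNode,
                   resolved: Mapping[str, LumpedElement]) -> LumpedElement:
    if node.mode == "leaf":
        try:
            base = resolved[node.ref]  # type: ignore[index]
        except KeyError:
            raise KeyError(node.ref) from None
        return scale_parallel(base, node.factor, node.compliance_factor)
    children = [_evaluate_node(child, resolved) for child in node.children]
    if node.mode == "series":
        return combine_series(children)
    return combine_parallel(children)


def evaluate_recipes(
    recipes: RecipeTable, base: Mapping[str, LumpedElement]
) -> dict[str, LumpedElement]:
    """Evaluate every recipe in definition order at full precision.

    Returns a mapping containing every entry name (and alias) in
    definition order.  Intermediates feed later entries unrounded; a
    dangling reference raises a ``ValueError`` naming the offending
    recipe.
    """
    resolved: dict[str, LumpedElement] = dict(base)
    out: dict[str, LumpedElement] = {}
    for entry in recipes:
        try:
            element = _evaluate_node(entry.node, resolved)
        except KeyError as exc:
            raise ValueError(
                f"recipe {entry.name!r} references unknown element {exc.args[0]!r}"
            ) from None
        for name in (entry.name, *entry.aliases):
            if name in resolved:
                raise ValueError(f"recipe {entry.name!r} redefines {name!r}")
            resolved[name] = element
            out[name] = element
    return out


def compare_to_printed(
    computed: Mapping[str, float],
    printed: Mapping[str, float],
    rel_tol: float = 0.01,
) -> pd.DataFrame:
    """Score computed values against a rounded reference table.

    Returns a deterministic, name-sorted frame with one row per name in
    the union of the two mappings: ``computed``, ``printed``,
    ``rel_error`` (|computed - printed| / |printed|) and ``passed`` at
    ``rel_tol``.  Missing values are reported (NaN), never fatal.
    """
    names = sorted(set(computed) | set(printed))
    rows = []
    for name in names:
        c = computed.get(name, math.nan)
        p = printed.get(name, math.nan)
        if math.isnan(c) or math.isnan(p) or p == 0.0:
            err = math.nan
            ok = False
        else:
            err = abs(c - p) / abs(p)
            ok = err <= rel_tol
        rows.append({"name": name, "computed": c, "printed": p,
                     "rel_error": err, "passed": ok})
    return pd.DataFrame(rows, columns=["name", "computed", "printed",
                                       "rel_error", "passed"])
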