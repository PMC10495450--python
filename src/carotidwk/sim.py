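"""Transient 0D simulation of three-element Windkessel (RCR) outlets.

The three-element Windkessel places a proximal resistor ``Rp`` in series
with a parallel capacitor ``C`` / distal resistor ``Rd`` pair that
drains to a distal reference pressure ``Pd``.  For a prescribed outlet
flow ``Q(t)`` the interface pressure ``P(t)`` obeys the linear ODE

    Q (1 + Rp/Rd) + C Rp dQ/dt = (P - Pd)/Rd + C dP/dt .

Two solvers are provided:

* :func:`rcr_outlet_pressure` — one outlet, prescribed periodic flow,
  integrated to periodic steady state;
* :func:`multi_outlet_split` — several RCR outlets fed from a shared
  pressure node with a prescribed total inflow; the node pressure is
  eliminated in closed form each step so that the outlet flows sum to
  the inflow exactly, and per-cycle mean flow splits are reported.

Time integration is implicit (backward) Euler on the linear state
equations, unconditionally stable for the stiff time-constant ratios
that vascular RCR networks produce.  ``dQ/dt`` comes from a periodic
cubic spline of the waveform samples.  A deterministic truncated-Fourier
generator (:func:`synth_inflow`) provides synthetic pulsatile inflow
with an exactly prescribed cycle mean.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.linalg import lu_factor, lu_solve

from .vessel import _require_positive

__all__ = [
    "WindkesselBC",
    "Waveform",
    "SimResult",
    "rcr_outlet_pressure",
    "multi_outlet_split",
    "synth_inflow",
    "periodic_convergence",
    "resistive_divider_splits",
    "INFLOW_PRESETS",
]


@dataclass(frozen=True)
class WindkesselBC:
    """Three-element Windkessel outlet boundary condition (SI units)."""

    proximal_resistance: float  # Rp, kg m^-4 s^-1
    compliance: float  # C, kg^-1 m^4 s^2
    distal_resistance: float  # Rd, kg m^-4 s^-1
    distal_pressure: float = 0.0  # Pa, reference at the far side of Rd

    def __post_init__(self) -> None:
        _require_positive(self.proximal_resistance, "proximal_resistance")
        _require_positive(self.compliance, "compliance")
        _require_positive(self.distal_resistance, "distal_resistance")
        if not (math.isfinite(self.distal_pressure) and self.distal_pressure >= 0.0):
            raise ValueError("distal_pressure must be finite and >= 0")

    @property
    def total_resistance(self) -> float:
        return self.proximal_resistance + self.distal_resistance

    @property
    def time_constant(self) -> float:
        """Relaxation time Rd*C of the capacitor node (s)."""
        return self.distal_resistance * self.compliance


@dataclass(frozen=True)
class Waveform:
    """One period of a periodic flow record.

    ``time`` is a strictly increasing grid in seconds starting at 0 and
    lying within ``[0, period]`` with at least 16 samples; ``flow`` is
    in m^3/s.  If the grid stops short of ``period`` the record wraps
    around periodically; if it includes ``period`` the first and last
    samples must agree.
    """

    period: float
    time: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        _require_positive(self.period, "period")
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "flow", q)
        if t.ndim != 1 or q.shape != t.shape:
            raise ValueError("time and flow must be 1-D arrays of equal length")
        if t.size < 16:
            raise ValueError("waveform requires at least 16 samples per period")
        if not np.all(np.diff(t) > 0):
            raise ValueError("waveform time grid must be strictly increasing")
        if t[0] != 0.0 or t[-1] > self.period * (1 + 1e-12):
            raise ValueError("waveform grid must start at 0 and lie within [0, period]")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(q))):
            raise ValueError("waveform samples must be finite")

    @cached_property
    def _closed(self) -> tuple[np.ndarray, np.ndarray]:
        t, q = self.time, self.flow
        if abs(t[-1] - self.period) <= 1e-12 * self.period:
            scale = max(np.max(np.abs(q)), 1e-300)
            if abs(q[-1] - q[0]) > 1e-9 * scale:
                raise ValueError(
                    "non-periodic waveform grid: first and last samples differ"
                )
            return t, q
        return np.append(t, self.period), np.append(q, q[0])

    @cached_property
    def _spline(self) -> CubicSpline:
        tc, qc = self._closed
        qc = qc.copy()
        qc[-1] = qc[0]  # enforce exact closure for the periodic spline
        return CubicSpline(tc, qc, bc_type="periodic")

    def flow_at(self, t) -> np.ndarray:
        """Periodic spline evaluation of Q at arbitrary times."""
        return self._spline(np.mod(t, self.period))

    def dflow_at(self, t) -> np.ndarray:
        """Periodic spline evaluation of dQ/dt at arbitrary times."""
        return self._spline(np.mod(t, self.period), 1)

    def mean(self) -> float:
        """Trapezoid cycle mean of the flow over one period."""
        tc, qc = self._closed
        return float(np.trapezoid(qc, tc) / self.period)


@dataclass(frozen=True)
class SimResult:
    """Output of a 0D transient run.

    ``pressure`` is the shared interface/junction pressure trace (Pa) on
    ``time`` (s, spanning all simulated cycles); ``flows`` maps outlet
    name to its flow trace (m^3/s).  ``cycle_summaries`` holds one row
    per completed cycle with the cycle-mean pressure, per-outlet mean
    flows, and mean flow-split fractions; ``mean_splits`` are the splits
    of the last completed cycle.  ``flow_balance_error`` is the largest
    absolute mismatch between the summed outlet flows and the inflow at
    any accepted step (single-outlet runs report 0).
    """

    time: np.ndarray
    pressure: np.ndarray
    flows: dict[str, np.ndarray]
    cycles_run: int
    converged: bool
    converged_cycle: int
    cycle_summaries: pd.DataFrame
    mean_splits: dict[str, float]
    flow_balance_error: float = 0.0


def synth_inflow(
    period: float = 0.55,
    mean_flow: float = 5.35e-6,
    harmonics: Sequence[float] | None = None,
    phases: Sequence[float] | None = None,
    samples: int = 256,
    allow_negative: bool = False,
) -> Waveform:
    """Deterministic truncated-Fourier pulsatile inflow.

    Q(t) = mean_flow * (1 + sum_k a_k cos(2 pi k t / T + phi_k))

    ``harmonics`` are relative amplitudes ``a_k`` (fractions of the
    mean) and default to a carotid-like pulse shape; the construction
    makes the cycle mean exactly ``mean_flow``.  Parameter sets whose
    flow dips below zero are rejected unless ``allow_negative``.
    """
    _require_positive(period, "period")
    _require_positive(mean_flow, "mean_flow")
    if samples < 16:
        raise ValueError("samples must be >= 16")
    if harmonics is None:
        harmonics = DEFAULT_HARMONICS
        if phases is None:
            phases = DEFAULT_PHASES
    harmonics = np.asarray(harmonics, dtype=float)
    if phases is None:
        phases = np.zeros_like(harmonics)
    phases = np.asarray(phases, dtype=float)
    if phases.shape != harmonics.shape:
        raise ValueError("phases and harmonics must have equal length")

    def shape(t: np.ndarray) -> np.ndarray:
        s = np.ones_like(t)
        for k, (a, phi) in enumerate(zip(harmonics, phases), start=1):
            s = s + a * np.cos(2 * np.pi * k * t / period + phi)
        return s

    fine = shape(np.linspace(0.0, period, 4096, endpoint=False))
    if np.min(fine) <= 0 and not allow_negative:
        raise ValueError(
            "harmonic amplitudes produce non-positive flow; pass "
            "allow_negative=True to permit this"
        )
    t = np.linspace(0.0, period, samples + 1)  # closed uniform grid
    q = mean_flow * shape(t)
    q[-1] = q[0]
    return Waveform(period=period, time=t, flow=q)


#: Default relative harmonic amplitudes/phases of the synthetic pulse.
DEFAULT_HARMONICS = (0.55, 0.28, 0.12)
DEFAULT_PHASES = (-1.9, 2.6, 0.9)

#: Named inflow presets for the two cardiac-cycle periods used in the
#: validation scenarios (means in m^3/s; 5.35 cm^3/s for the simplified
#: carotid scenario).
INFLOW_PRESETS = {
    "carotid-0.55s": dict(period=0.55, mean_flow=5.35e-6),
    "carotid-0.753s": dict(period=0.753, mean_flow=5.35e-6),
}


def periodic_convergence(cycle_summaries, tol: float = 1e-4) -> int:
    """First cycle at periodic steady state.

    ``cycle_summaries`` is an (n_cycles, n_quantities) array-like (or
    DataFrame) of per-cycle summary statistics.  Returns the 1-based
    index of the first cycle whose maximum relative change against the
    previous cycle is below ``tol``; returns -1 (with a warning) if no
    cycle qualifies.  At least two completed cycles are required.
    """
    if isinstance(cycle_summaries, pd.DataFrame):
        values = cycle_summaries.to_numpy(dtype=float)
    else:
        values = np.atleast_2d(np.asarray(cycle_summaries, dtype=float))
    if values.shape[0] < 2:
        raise ValueError("periodic_convergence requires at least 2 completed cycles")
    _require_positive(tol, "tol")
    floor = max(np.max(np.abs(values)), 1e-300) * 1e-15
    for c in range(1, values.shape[0]):
        prev, cur = values[c - 1], values[c]
        rel = np.abs(cur - prev) / np.maximum(np.abs(prev), floor)
        if np.max(rel) < tol:
            return c + 1
    warnings.warn("no periodic steady state reached within the supplied cycles")
    return -1


def _resolve_dt(period: float, dt: float | None) -> tuple[float, int]:
    if dt is None:
        dt = period / 1000.0
    _require_positive(dt, "dt")
    if dt > period / 64.0:
        raise ValueError(f"dt={dt} too coarse; require dt <= period/64")
    steps = max(int(round(period / dt)), 64)
    return period / steps, steps


def _summaries_frame(names: Sequence[str], rows: list[dict]) -> pd.DataFrame:
    cols = ["cycle", "mean_pressure"]
    cols += [f"mean_flow_{n}" for n in names] + [f"split_{n}" for n in names]
    return pd.DataFrame(rows, columns=cols)


def rcr_outlet_pressure(
    waveform: Waveform,
    bc: WindkesselBC,
    dt: float | None = None,
    max_cycles: int = 7,
    tol: float = 1e-4,
    p_init: float | None = None,
    name: str = "outlet",
) -> SimResult:
    """Pressure at a single RCR outlet with prescribed periodic flow.

    Integrates the RCR pressure ODE with backward Euler, cycling the
    waveform until the cycle-mean pressure changes by less than ``tol``
    (relative) between consecutive cycles, or ``max_cycles`` is reached.
    The initial pressure defaults to the distal reference pressure.
    """
    _require_positive(tol, "tol")
    dt, steps = _resolve_dt(waveform.period, dt)
    rp, rd, c, pd_ref = (bc.proximal_resistance, bc.distal_resistance,
                         bc.compliance, bc.distal_pressure)
    k = dt / (rd * c)
    p = pd_ref if p_init is None else float(p_init)

    times = [0.0]
    pressures = [p]
    summary_rows: list[dict] = []
    converged = False
    converged_cycle = -1
    cycles_run = 0
    prev_mean: float | None = None

    for cycle in range(1, max_cycles + 1):
        cycle_ps = []
        for n in range(1, steps + 1):
            t1 = (cycle - 1) * waveform.period + n * dt
            q1 = float(waveform.flow_at(t1))
            dq1 = float(waveform.dflow_at(t1))
            p = (p + dt * (q1 * (1 + rp / rd) / c + rp * dq1) + k * pd_ref) / (1 + k)
            if not math.isfinite(p):
                raise RuntimeError(
                    f"pressure integration diverged (non-finite) at dt={dt}"
                )
            times.append(t1)
            pressures.append(p)
            cycle_ps.append(p)
        cycles_run = cycle
        mean_p = float(np.mean(cycle_ps))
        summary_rows.append({"cycle": cycle, "mean_pressure": mean_p,
                             f"mean_flow_{name}": waveform.mean(),
                             f"split_{name}": 1.0})
        if prev_mean is not None:
            scale = max(abs(prev_mean), 1e-300)
            if abs(mean_p - prev_mean) / scale < tol:
                converged = True
                converged_cycle = cycle
                break
        prev_mean = mean_p

    t_arr = np.asarray(times)
    return SimResult(
        time=t_arr,
        pressure=np.asarray(pressures),
        flows={name: np.asarray(waveform.flow_at(t_arr))},
        cycles_run=cycles_run,
        converged=converged,
        converged_cycle=converged_cycle,
        cycle_summaries=_summaries_frame([name], summary_rows),
        mean_splits={name: 1.0},
    )


def _as_bc_mapping(
    bcs: Sequence[WindkesselBC] | Mapping[str, WindkesselBC],
    names: Sequence[str] | None,
) -> dict[str, WindkesselBC]:
    if isinstance(bcs, Mapping):
        return dict(bcs)
    if names is None:
        names = [f"outlet{i + 1}" for i in range(len(bcs))]
    if len(names) != len(bcs):
        raise ValueError("names and bcs must have equal length")
    return dict(zip(names, bcs))


def multi_outlet_split(
    inflow: Waveform,
    bcs: Sequence[WindkesselBC] | Mapping[str, WindkesselBC],
    dt: float | None = None,
    max_cycles: int = 7,
    tol: float = 1e-4,
    names: Sequence[str] | None = None,
) -> SimResult:
    """Flow split among RCR outlets sharing one junction node.

    Each outlet carries a capacitor-node pressure state ``Pc_i`` with
    outlet flow ``Q_i = (P_node - Pc_i)/Rp_i``; the junction pressure is
    eliminated in closed form each step,

        P_node = (Q_in + sum(Pc_i / Rp_i)) / sum(1 / Rp_i) ,

    so the outlet flows sum to the prescribed inflow identically.  The
    coupled backward-Euler update is a constant linear system, factored
    once.  Per-cycle mean flows and split fractions are reported and
    convergence is judged on cycle-mean pressure and flows.
    """
    _require_positive(tol, "tol")
    bc_map = _as_bc_mapping(bcs, names)
    if len(bc_map) < 2:
        raise ValueError("multi_outlet_split requires at least 2 outlets")
    outlet_names = list(bc_map)
    bc_list = [bc_map[n] for n in outlet_names]
    n_out = len(bc_list)
    dt, steps = _resolve_dt(inflow.period, dt)

    g = np.array([1.0 / b.proximal_resistance for b in bc_list])
    s_total = g.sum()
    a = np.array([1.0 / (b.proximal_resistance * b.compliance) for b in bc_list])
    b_ = np.array([1.0 / (b.distal_resistance * b.compliance) for b in bc_list])
    pd_ref = np.array([b.distal_pressure for b in bc_list])

    # Backward-Euler system matrix for the capacitor pressures.
    m = np.eye(n_out) + dt * np.diag(a + b_) - dt * np.outer(a, g) / s_total
    lu = lu_factor(m)

    pc = pd_ref.copy().astype(float)
    p_node0 = (float(inflow.flow_at(0.0)) + g @ pc) / s_total
    times = [0.0]
    node_p = [p_node0]
    flows = [(p_node0 - pc) * g]
    summary_rows: list[dict] = []
    balance_err = 0.0
    converged = False
    converged_cycle = -1
    cycles_run = 0
    prev_summary: np.ndarray | None = None

    for cycle in range(1, max_cycles + 1):
        cyc_p = np.empty(steps)
        cyc_q = np.empty((steps, n_out))
        for n in range(steps):
            t1 = (cycle - 1) * inflow.period + (n + 1) * dt
            qin1 = float(inflow.flow_at(t1))
            rhs = pc + dt * (a * qin1 / s_total + b_ * pd_ref)
            pc = lu_solve(lu, rhs)
            p_node = (qin1 + g @ pc) / s_total
            q_out = (p_node - pc) * g
            if not (math.isfinite(p_node) and np.all(np.isfinite(pc))):
                raise RuntimeError(
                    f"junction integration diverged (non-finite) at dt={dt}"
                )
            balance_err = max(balance_err, abs(q_out.sum() - qin1))
            times.append(t1)
            node_p.append(p_node)
            flows.append(q_out)
            cyc_p[n] = p_node
            cyc_q[n] = q_out
        cycles_run = cycle
        mean_q = cyc_q.mean(axis=0)
        mean_in = mean_q.sum()
        splits = mean_q / mean_in
        row = {"cycle": cycle, "mean_pressure": float(cyc_p.mean())}
        row.update({f"mean_flow_{n}": v for n, v in zip(outlet_names, mean_q)})
        row.update({f"split_{n}": v for n, v in zip(outlet_names, splits)})
        summary_rows.append(row)
        summary = np.concatenate(([cyc_p.mean()], mean_q))
        if prev_summary is not None:
            floor = max(np.max(np.abs(summary)), 1e-300) * 1e-15
            rel = np.abs(summary - prev_summary) / np.maximum(np.abs(prev_summary), floor)
            if np.max(rel) < tol:
                converged = True
                converged_cycle = cycle
                break
        prev_summary = summary

    flows_arr = np.asarray(flows)
    last = summary_rows[-1]
    return SimResult(
        time=np.asarray(times),
        pressure=np.asarray(node_p),
        flows={n: flows_arr[:, i] for i, n in enumerate(outlet_names)},
        cycles_run=cycles_run,
        converged=converged,
        converged_cycle=converged_cycle,
        cycle_summaries=_summaries_frame(outlet_names, summary_rows),
        mean_splits={n: float(last[f"split_{n}"]) for n in outlet_names},
        flow_balance_error=float(balance_err),
    )


def resistive_divider_splits(
    bcs: Sequence[WindkesselBC] | Mapping[str, WindkesselBC],
    names: Sequence[str] | None = None,
) -> dict[str, float]:
    """Cycle-mean flow splits predicted by the total-resistance divider.

    For equal distal pressures the compliances carry no mean current, so
    the mean split of outlet *i* is (1/(Rp_i+Rd_i)) / sum_j 1/(Rp_j+Rd_j).
    """
    bc_map = _as_bc_mapping(bcs, names)
    cond = {n: 1.0 / b.total_resistance for n, b in bc_map.items()}
    total = sum(cond.values())
    return {n: v / total for n, v in cond.items()}
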