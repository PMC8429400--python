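"""Kinetic model of Golgi luminal pH under pump / leak / anion-exchange fluxes.

State variables are luminal pH and the luminal concentrations (mM) of Cl-,
HCO3- and dissolved CO2.  Acid equivalents delivered to or removed from the
lumen move the pH through a constant intrinsic buffering capacity beta
(mM per pH unit); the bicarbonate system is treated kinetically
(H+ + HCO3- <-> CO2 + H2O, pKa 6.4) so that buffering by bicarbonate and
the egress of CO2 emerge from the reaction and a first-order CO2
permeability rather than being folded into beta.

Flux terms (all expressed in mM/min of the transported species):

* V-ATPase pumping: Michaelis-Menten in bath ATP times a linear
  back-pressure factor that vanishes at ``pump_ph_floor``; zeroed by the
  inhibitor flag on the bath.
* Passive H+ leak: first-order in the trans-membrane free-proton
  concentration difference.
* Electroneutral 1:1 Cl-/HCO3- exchange: mass-action antiport on the
  cross-product difference, saturably normalised and gated by a base-10
  logistic in luminal pH (the exchanger stalls below ~pH 5).
* Cl- channel: concentration-gradient flux at clamped 0 mV membrane
  potential.
* CO2 escape: first-order, scaled by the compartment surface/volume ratio.

The model is intentionally phenomenological: rate laws are the simplest
forms consistent with the stated stoichiometry and pH dependence, with
parameters shipped as editable presets rather than hard-coded constants.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "GolgiCompartment",
    "BathState",
    "TransporterParams",
    "Protocol",
    "Trajectory",
    "IntegrationError",
    "step_fluxes",
    "simulate",
    "resting_pH",
    "leak_phase",
    "load_preset",
    "available_presets",
    "permeabilized_bath",
]

#: surface/volume ratio (um^2 per fL) of the default compartment; used to
#: normalise the CO2 escape rate so preset values are effective min^-1.
_REFERENCE_SA_OVER_V = 60.0


class IntegrationError(RuntimeError):
    """Raised when the stiff integrator fails; carries the last valid state."""

    def __init__(self, message: str, last_state: np.ndarray | None = None, t: float | None = None):
        super().__init__(message)
        self.last_state = last_state
        self.t = t


@dataclass
class GolgiCompartment:
    """Geometry, intrinsic buffering and initial luminal composition."""

    volume_fl: float = 10.0
    surface_area_um2: float = 600.0
    buffer_capacity: float = 40.0  # mM per pH unit, bicarbonate excluded
    ph: float = 6.5
    cl_mM: float = 4.0
    hco3_mM: float = 2.0
    co2_mM: float = 1.5

    def __post_init__(self) -> None:
        for name in ("volume_fl", "surface_area_um2", "buffer_capacity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 3.0 < self.ph < 9.0:
            raise ValueError("initial pH outside (3, 9)")
        for name in ("cl_mM", "hco3_mM", "co2_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def sa_over_v(self) -> float:
        return self.surface_area_um2 / self.volume_fl


@dataclass
class BathState:
    """Composition of the medium the Golgi membrane faces.

    For intact cells this is the cytosol; after permeabilization it is the
    experimental bath solution.
    """

    ph: float = 7.2
    atp_mM: float = 0.0
    cl_mM: float = 0.0
    hco3_mM: float = 0.0
    co2_mM: float = 0.0
    cma_present: bool = False

    def __post_init__(self) -> None:
        for name in ("atp_mM", "cl_mM", "hco3_mM", "co2_mM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def h_mM(self) -> float:
        return 10.0 ** (3.0 - self.ph)


@dataclass
class TransporterParams:
    """Rate constants of the flux terms.  All non-negative."""

    pump_vmax: float = 60.0  # mM/min of H+ at saturating ATP, no back-pressure
    pump_km_atp: float = 0.3  # mM
    pump_ph_floor: float = 4.8  # pH at which pumping stalls
    pump_backpressure_span: float = 2.4  # pH units over which the factor ramps 0 -> 1
    passive_h_permeability: float = 1900.0  # min^-1 acting on [H+] difference in mM
    cl_channel_rate: float = 100.0  # min^-1
    ae2_density: float = 1.0  # relative expression level, 1.0 = control
    ae2_turnover: float = 430.0  # mM/min per unit density at saturation
    ae2_km_hco3: float = 10.0  # mM, saturation scale of the antiport
    ae2_km_cl: float = 10.0  # mM
    ae2_ph_gate_midpoint: float = 5.0
    ae2_ph_gate_steepness: float = 4.0  # decades of gating per pH unit
    co2_permeability: float = 0.8333  # min^-1 at the reference surface/volume
    buffer_pka: float = 6.4
    buffer_forward_rate: float = 1.0e6  # mM^-1 min^-1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


_ACTIONS = frozenset({"permeabilize", "set_bath", "add_atp", "add_cma", "wash_atp"})


@dataclass
class Protocol:
    """Ordered timed events applied to the bath during a simulation.

    Each event is ``(time_min, action, payload)`` with action one of
    ``permeabilize`` / ``set_bath`` (payload: :class:`BathState`),
    ``add_atp`` (payload: mM), ``add_cma`` and ``wash_atp`` (no payload).
    Times must be strictly increasing and any ATP addition must follow
    permeabilization (ATP cannot be delivered across an intact membrane).
    """

    events: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [ev[0] for ev in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        permeabilized = False
        for ev in self.events:
            action = ev[1]
            if action not in _ACTIONS:
                raise ValueError(f"unknown protocol action {action!r}")
            if action in ("permeabilize", "set_bath"):
                if len(ev) != 3 or not isinstance(ev[2], BathState):
                    raise ValueError(f"{action} event requires a BathState payload")
            if action == "permeabilize":
                permeabilized = True
            if action == "add_atp" and not permeabilized:
                raise ValueError("add_atp before permeabilization")

    def apply(self, bath: BathState, event: tuple) -> BathState:
        action = event[1]
        if action in ("permeabilize", "set_bath"):
            return copy.deepcopy(event[2])
        if action == "add_atp":
            return replace(bath, atp_mM=bath.atp_mM + float(event[2]))
        if action == "add_cma":
            return replace(bath, cma_present=True)
        if action == "wash_atp":
            return replace(bath, atp_mM=0.0)
        raise ValueError(action)  # pragma: no cover


@dataclass
class Trajectory:
    """Dense simulation output with per-term flux diagnostics."""

    time_min: np.ndarray
    ph: np.ndarray
    cl_mM: np.ndarray
    hco3_mM: np.ndarray
    co2_mM: np.ndarray
    fluxes: dict[str, np.ndarray]
    events: list[tuple] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.time_min,
                "pH": self.ph,
                "cl_mM": self.cl_mM,
                "hco3_mM": self.hco3_mM,
                "co2_mM": self.co2_mM,
                "j_pump": self.fluxes["j_pump"],
                "j_leak": self.fluxes["j_leak"],
                "j_ae2": self.fluxes["j_ae2"],
                "j_buffer": self.fluxes["j_buffer"],
                "j_co2": self.fluxes["j_co2"],
                "j_cl": self.fluxes["j_cl"],
            }
        )

    def segment(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        """Slice the trajectory to [t_from, t_to], re-zeroing nothing."""
        mask = self.time_min >= t_from - 1e-12
        if t_to is not None:
            mask &= self.time_min <= t_to + 1e-12
        return Trajectory(
            time_min=self.time_min[mask],
            ph=self.ph[mask],
            cl_mM=self.cl_mM[mask],
            hco3_mM=self.hco3_mM[mask],
            co2_mM=self.co2_mM[mask],
            fluxes={k: v[mask] for k, v in self.fluxes.items()},
            events=self.events,
        )


def _gate(ph: float | np.ndarray, params: TransporterParams):
    """Base-10 logistic activation of the exchanger in luminal pH."""
    s = params.ae2_ph_gate_steepness
    return 1.0 / (1.0 + 10.0 ** (-s * (ph - params.ae2_ph_gate_midpoint)))


def step_fluxes(
    state: Sequence[float], bath: BathState, params: TransporterParams,
    compartment: GolgiCompartment | None = None,
) -> dict[str, float]:
    """Evaluate all flux terms at a state ``(pH, Cl, HCO3, CO2)``.

    Returns mM/min of the transported species:
    ``j_pump`` H+ into the lumen; ``j_leak`` H+ out of the lumen (signed);
    ``j_ae2`` HCO3- import (= Cl- export, 1:1); ``j_buffer`` H+ consumed by
    the bicarbonate reaction; ``j_co2`` CO2 escape; ``j_cl`` Cl- influx
    through the counter-ion channel.
    """
    ph, cl, hco3, co2 = state
    if min(cl, hco3, co2) < -1e-6:
        raise ValueError(f"negative luminal concentration in state {state}")
    cl, hco3, co2 = max(cl, 0.0), max(hco3, 0.0), max(co2, 0.0)
    comp = compartment or GolgiCompartment()

    h_lumen = 10.0 ** (3.0 - ph)  # free H+ in mM

    if bath.cma_present or bath.atp_mM <= 0:
        j_pump = 0.0
    else:
        backpressure = (ph - params.pump_ph_floor) / params.pump_backpressure_span
        backpressure = min(max(backpressure, 0.0), 1.0)
        j_pump = (
            params.pump_vmax * bath.atp_mM / (params.pump_km_atp + bath.atp_mM) * backpressure
        )

    j_leak = params.passive_h_permeability * (h_lumen - bath.h_mM)

    drive = bath.hco3_mM * cl - hco3 * bath.cl_mM
    norm = (params.ae2_km_hco3 + bath.hco3_mM + hco3) * (params.ae2_km_cl + bath.cl_mM + cl)
    j_ae2 = params.ae2_turnover * params.ae2_density * _gate(ph, params) * drive / norm

    ka_mM = 10.0 ** (3.0 - params.buffer_pka)  # dissociation constant in mM
    j_buffer = params.buffer_forward_rate * (h_lumen * hco3 - ka_mM * co2)

    k_co2 = params.co2_permeability * comp.sa_over_v / _REFERENCE_SA_OVER_V
    j_co2 = k_co2 * (co2 - bath.co2_mM)

    j_cl = params.cl_channel_rate * (bath.cl_mM - cl)

    return {
        "j_pump": j_pump,
        "j_leak": j_leak,
        "j_ae2": j_ae2,
        "j_buffer": j_buffer,
        "j_co2": j_co2,
        "j_cl": j_cl,
    }


def _rhs(t, y, bath, params, comp):
    j = step_fluxes(y, bath, params, comp)
    dph = (-j["j_pump"] + j["j_leak"] + j["j_buffer"]) / comp.buffer_capacity
    dcl = j["j_cl"] - j["j_ae2"]
    dhco3 = j["j_ae2"] - j["j_buffer"]
    dco2 = j["j_buffer"] - j["j_co2"]
    return [dph, dcl, dhco3, dco2]


def simulate(
    compartment: GolgiCompartment,
    params: TransporterParams,
    protocol: Protocol | None = None,
    t_end: float = 30.0,
    dt_out: float = 0.25,
    initial_bath: BathState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the model, restarting the stiff integrator at each event.

    ``initial_bath`` is the medium before any protocol event fires (the
    cytosol for intact cells); defaults to a resting cytosol with 10 mM ATP.
    """
    protocol = protocol or Protocol([])
    bath = copy.deepcopy(initial_bath) if initial_bath is not None else BathState(
        ph=7.2, atp_mM=10.0, cl_mM=4.0, hco3_mM=12.0, co2_mM=1.9
    )
    y = np.array(
        [compartment.ph, compartment.cl_mM, compartment.hco3_mM, compartment.co2_mM],
        dtype=float,
    )

    breakpoints = [0.0] + [ev[0] for ev in protocol.events if 0.0 < ev[0] < t_end] + [t_end]
    events_by_time: dict[float, list[tuple]] = {}
    for ev in protocol.events:
        events_by_time.setdefault(ev[0], []).append(ev)
    # events at t = 0 apply before integration starts
    for ev in events_by_time.get(0.0, []):
        bath = protocol.apply(bath, ev)

    t_grid = np.arange(0.0, t_end + dt_out / 2, dt_out)
    t_grid[-1] = min(t_grid[-1], t_end)
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []
    bath_segments: list[tuple[float, float, BathState]] = []

    t_now = 0.0
    for t_next in breakpoints[1:]:
        seg_mask = (t_grid >= t_now - 1e-12) & (t_grid <= t_next + 1e-12)
        t_eval = t_grid[seg_mask]
        sol = solve_ivp(
            _rhs,
            (t_now, t_next),
            y,
            method="BDF",
            dense_output=True,
            args=(bath, params, compartment),
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in segment [{t_now}, {t_next}]: {sol.message}",
                last_state=y,
                t=t_now,
            )
        if t_eval.size:
            out_t.append(t_eval)
            out_y.append(sol.sol(t_eval))
        bath_segments.append((t_now, t_next, copy.deepcopy(bath)))
        y = sol.y[:, -1].copy()
        for ev in events_by_time.get(t_next, []):
            bath = protocol.apply(bath, ev)
        t_now = t_next

    t_all = np.concatenate(out_t)
    y_all = np.concatenate(out_y, axis=1)
    t_all, idx = np.unique(t_all, return_index=True)
    y_all = y_all[:, idx]

    # per-term fluxes on the output grid using the bath active at each time
    flux_names = ("j_pump", "j_leak", "j_ae2", "j_buffer", "j_co2", "j_cl")
    fluxes = {k: np.empty_like(t_all) for k in flux_names}
    for i, t in enumerate(t_all):
        seg_bath = bath_segments[-1][2]
        for t0, t1, b in bath_segments:
            if t0 - 1e-12 <= t < t1 - 1e-12 or (t1 == bath_segments[-1][1] and t >= t0):
                seg_bath = b
                break
        j = step_fluxes(y_all[:, i], seg_bath, params, compartment)
        for k in flux_names:
            fluxes[k][i] = j[k]

    ph = y_all[0]
    if np.any((ph <= 3.0) | (ph >= 9.0)):
        raise IntegrationError("luminal pH left the physical range (3, 9)", last_state=y_all[:, -1])

    return Trajectory(
        time_min=t_all,
        ph=ph,
        cl_mM=np.maximum(y_all[1], 0.0),
        hco3_mM=np.maximum(y_all[2], 0.0),
        co2_mM=np.maximum(y_all[3], 0.0),
        fluxes=fluxes,
        events=list(protocol.events),
    )


def resting_pH(
    compartment: GolgiCompartment,
    params: TransporterParams,
    bath: BathState,
    t_max: float = 400.0,
    tol: float = 1e-5,
) -> float:
    """Steady-state luminal pH under a constant bath with ATP and no CMA.

    Found by long integration with a convergence check on the final pH
    drift; raises :class:`IntegrationError` on non-convergence.
    """
    if bath.atp_mM <= 0:
        raise ValueError("resting pH requires ATP in the bath")
    if bath.cma_present:
        raise ValueError("resting pH requires an uninhibited pump")
    traj = simulate(compartment, params, Protocol([]), t_end=t_max, dt_out=t_max / 400,
                    initial_bath=bath)
    tail = traj.ph[-20:]
    drift = abs(tail[-1] - tail[0]) / (traj.time_min[-1] - traj.time_min[-20])
    if drift > tol:
        raise IntegrationError(
            f"resting pH did not converge within t_max={t_max} min (drift {drift:.2e}/min)",
            last_state=np.array([traj.ph[-1], traj.cl_mM[-1], traj.hco3_mM[-1], traj.co2_mM[-1]]),
            t=traj.time_min[-1],
        )
    return float(traj.ph[-1])


def leak_phase(trajectory: Trajectory, t_event: float | None = None):
    """Initial net acid efflux rate (dpH/min) of a post-inhibitor segment.

    ``t_event`` selects the start of the efflux phase (defaults to the last
    ``add_cma`` event in the trajectory's protocol).  Delegates the fit to
    :func:`golgiph.phquant.estimate_initial_rate`.
    """
    from . import phquant

    if t_event is None:
        cma_times = [ev[0] for ev in trajectory.events if ev[1] == "add_cma"]
        if not cma_times:
            raise ValueError("trajectory has no add_cma event; pass t_event explicitly")
        t_event = cma_times[-1]
    seg = trajectory.segment(t_event)
    if seg.time_min.size < 6:
        raise ValueError("post-event segment too short for rate estimation")
    return phquant.estimate_initial_rate(
        np.column_stack([seg.time_min - seg.time_min[0], seg.ph])
    )


# ---------------------------------------------------------------------------
# presets


def available_presets() -> list[str]:
    root = resources.files("golgiph") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> tuple[GolgiCompartment, TransporterParams, BathState]:
    """Load a shipped parameter preset: (compartment, params, cytosol bath)."""
    path = resources.files("golgiph") / "presets" / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}") from None
    return parse_model_config(raw)


def parse_model_config(raw: dict) -> tuple[GolgiCompartment, TransporterParams, BathState]:
    comp = GolgiCompartment(**raw.get("compartment", {}))
    params = TransporterParams(**raw.get("params", {}))
    cytosol = BathState(**raw.get("cytosol", {}))
    return comp, params, cytosol


def permeabilized_bath(kind: str, ph: float = 7.2) -> BathState:
    """Standard permeabilized-cell bath compositions for the three anion conditions.

    ``anion_free``: neither Cl- nor HCO3-.  ``cl_only``: 120 mM Cl- with a
    small carbonic-anhydrase-derived bicarbonate background (2 mM).
    ``cl_hco3``: 120 mM Cl- plus 20 mM HCO3-.  Bath CO2 is set by
    Henderson-Hasselbalch equilibrium at the bath pH.
    """
    def co2_of(hco3: float) -> float:
        return hco3 * 10.0 ** (6.4 - ph)

    if kind == "anion_free":
        return BathState(ph=ph, cl_mM=0.0, hco3_mM=0.0, co2_mM=0.0)
    if kind == "cl_only":
        return BathState(ph=ph, cl_mM=120.0, hco3_mM=2.0, co2_mM=co2_of(2.0))
    if kind == "cl_hco3":
        return BathState(ph=ph, cl_mM=120.0, hco3_mM=20.0, co2_mM=co2_of(20.0))
    raise KeyError(f"unknown bath kind {kind!r}")
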