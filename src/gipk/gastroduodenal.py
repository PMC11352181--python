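"""Stomach and duodenum as a discrete-event continuous system.

Between emptying events both compartments evolve continuously: the stomach
volume grows with the gastric-juice inflow ``Qgj`` while the tablet
dissolves into the fluid; the duodenal volume grows with the pancreatic
inflow ``Qpj`` and carries its drug mass unchanged. Every ``Te`` seconds
an instantaneous event fires: the duodenum first discharges its entire
content into the jejunum as a bolus, then receives 1/20 of the current
stomach volume (at the gastric concentration), the stomach keeping the
remaining 19/20. The emitted bolus train is the input of
:mod:`gipk.intestine`.

The printed "1 s" emptying flow is realized as an instantaneous state
jump: the post-event states coincide and the stiff pulse is avoided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import DrugProperties, PhysiologyParams
from .dissolution import (
    DissolutionState,
    initial_radius,
    ksd_from_properties,
    radius_rate,
    solubility_hh,
)

__all__ = [
    "GastricState",
    "DuodenalState",
    "BolusEmission",
    "GastroduodenalResult",
    "continuous_rhs",
    "apply_emptying_event",
    "run_gastroduodenal",
]


@dataclass
class GastricState:
    """Stomach at time ``t``: volume ``Vs`` (L), concentration ``Cs`` (mg/L),
    meal inflow ``inflow`` (L/s, zero after a single oral administration) at
    meal concentration ``C0``, plus the tablet's dissolution state."""

    t: float
    Vs: float
    Cs: float
    dissolution: DissolutionState
    inflow: float = 0.0
    C0: float = 0.0

    def __post_init__(self) -> None:
        if not self.Vs > 0:
            raise ValueError(f"Vs must be > 0, got {self.Vs}")
        if self.Cs < 0:
            raise ValueError(f"Cs must be >= 0, got {self.Cs}")


@dataclass
class DuodenalState:
    """Duodenum at time ``t``: volume ``Vd`` (L) and concentration ``Cd`` (mg/L)."""

    t: float
    Vd: float
    Cd: float

    def __post_init__(self) -> None:
        if self.Vd < 0 or self.Cd < 0:
            raise ValueError("Vd and Cd must be >= 0")


@dataclass(frozen=True)
class BolusEmission:
    """One duodenal discharge: emission time (s), volume (L), concentration (mg/L)."""

    tk: float
    volume: float
    concentration: float


@dataclass
class GastroduodenalResult:
    """Emissions plus sampled trajectories and the per-event log."""

    emissions: list[BolusEmission]
    times: np.ndarray
    Vs: np.ndarray
    Cs: np.ndarray
    Vd: np.ndarray
    Cd: np.ndarray
    rp: np.ndarray
    dissolved_mass: np.ndarray
    event_log: list[dict] = field(default_factory=list)
    dissolution_capped: bool = False
    stopped_on_volume: bool = False


def continuous_rhs(
    gs: GastricState,
    ds: DuodenalState,
    drug: DrugProperties,
    phys: PhysiologyParams,
    dissolving: bool = True,
) -> tuple[float, float, float, float, float]:
    """Inter-event derivatives of (Vs, Vs*Cs, Vd, Vd*Cd, rp).

    Between events all convective flows are zero; only the secretions and
    the dissolution source act. ``dissolving=False`` switches the source
    off (tablet exhausted or dose cap reached).
    """
    dstate = gs.dissolution
    source = 0.0
    drp = 0.0
    if dissolving and dstate.rp > 0.0:
        source = max(dstate.ksd * (dstate.Ss - gs.Cs), 0.0)
        drp = radius_rate(dstate.rp, dstate.ksd, dstate.Ss, gs.Cs, drug.rho)
    dVs = gs.inflow + phys.Qgj
    dMs = gs.inflow * gs.C0 + source
    dVd = phys.Qpj
    dMd = 0.0
    return dVs, dMs, dVd, dMd, drp


def apply_emptying_event(
    gs: GastricState, ds: DuodenalState, phys: PhysiologyParams
) -> tuple[GastricState, DuodenalState, BolusEmission | None]:
    """Instantaneous gastro-duodenal emptying at ``tk = k*Te``.

    Ordered sequence: (i) the duodenum discharges its full pre-event
    content as a bolus; (ii) the stomach keeps (1 - f) of its volume;
    (iii) the duodenum refills with f times the pre-event stomach volume
    at the gastric concentration, which is continuous across the event.
    Returns ``None`` in place of a zero-volume bolus (nothing to emit).
    """
    tk = gs.t
    if ds.t != tk:
        raise ValueError(f"stomach ({gs.t}) and duodenum ({ds.t}) times differ")
    k = tk / phys.Te
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise ValueError(
            f"emptying event called off-schedule at t={tk} (period {phys.Te})"
        )
    f = phys.emptying_fraction
    emission = (
        BolusEmission(tk=tk, volume=ds.Vd, concentration=ds.Cd) if ds.Vd > 0 else None
    )
    transfer_v = f * gs.Vs
    gs_post = GastricState(
        t=tk,
        Vs=gs.Vs - transfer_v,
        Cs=gs.Cs,
        dissolution=gs.dissolution,
        inflow=gs.inflow,
        C0=gs.C0,
    )
    ds_post = DuodenalState(t=tk, Vd=transfer_v, Cd=gs.Cs)
    return gs_post, ds_post, emission


def _interval_rhs(dissolving: bool, ksd: float, Ss: float, rho: float, Qgj: float, Qpj: float):
    def rhs(t, y):
        Vs, Ms, Vd, Md, rp, mdiss = y
        Cs = Ms / Vs
        if dissolving and rp > 0.0:
            source = max(ksd * (Ss - Cs), 0.0)
            drp = radius_rate(rp, ksd, Ss, Cs, rho)
        else:
            source = 0.0
            drp = 0.0
        return [Qgj, source, Qpj, 0.0, drp, source]

    return rhs


def run_gastroduodenal(
    drug: DrugProperties,
    phys: PhysiologyParams | None = None,
    Vs0: float = 1.0,
    t_max: float = 43200.0,
    dt_traj: float = 60.0,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> GastroduodenalResult:
    """Simulate the gastro-duodenal stage and collect the bolus train.

    The tablet starts undissolved (Cs(0) = 0) with radius from
    :func:`gipk.dissolution.initial_radius`; Vd(0) = 0, so the first
    event emits nothing. Integration proceeds event-to-event with an
    adaptive ODE solver and stops at ``t_max`` or when the stomach volume
    drops below ``V_stop_frac * Vs0``. The dissolution source shuts off
    when the cumulative dissolved mass reaches the dose (hard cap) or the
    radius reaches zero.
    """
    if phys is None:
        phys = PhysiologyParams()
    if drug.dose is None:
        raise ValueError(f"drug {drug.name!r} has no dose set; use with_dose()")
    if not Vs0 > 0:
        raise ValueError("Vs0 must be > 0")
    if not t_max > 0:
        raise ValueError("t_max must be > 0")

    Ss_mgL = solubility_hh(drug.S0, phys.gastric_pH, drug.pKa) * drug.molar_mass * 1000.0
    ksd = ksd_from_properties(drug.D, Ss_mgL, drug.rho)
    rp0 = initial_radius(drug.dose, drug.rho)
    dose = drug.dose

    # state vector y = [Vs, Ms, Vd, Md, rp, dissolved_mass]
    y = np.array([Vs0, 0.0, 0.0, 0.0, rp0, 0.0])
    t = 0.0
    dissolving = True
    capped = False
    stopped_on_volume = False

    emissions: list[BolusEmission] = []
    event_log: list[dict] = []
    traj_t: list[float] = [0.0]
    traj: list[np.ndarray] = [y.copy()]

    def cap_event(tt, yy):
        return dose - yy[5]

    cap_event.terminal = True
    cap_event.direction = -1

    def radius_event(tt, yy):
        return yy[4]

    radius_event.terminal = True
    radius_event.direction = -1

    n_events = math.floor(t_max / phys.Te + 1e-9)
    for k in range(1, n_events + 1):
        tk = k * phys.Te
        # continuous stretch [t, tk], possibly split at a dissolution stop
        while t < tk - 1e-12:
            rhs = _interval_rhs(dissolving, ksd, Ss_mgL, drug.rho, phys.Qgj, phys.Qpj)
            interior = np.arange(
                math.floor(t / dt_traj + 1.0) * dt_traj, tk - 1e-9, dt_traj
            )
            interior = interior[interior > t + 1e-12]
            t_eval = np.append(interior, tk)
            sol = solve_ivp(
                rhs,
                (t, tk),
                y,
                method="LSODA",
                rtol=rtol,
                atol=atol,
                t_eval=t_eval,
                events=[cap_event, radius_event] if dissolving else None,
            )
            if not sol.success:
                raise RuntimeError(f"gastroduodenal integration failed: {sol.message}")
            if sol.t.size:
                traj_t.extend(sol.t.tolist())
                traj.extend(list(sol.y.T))
            if dissolving and sol.status == 1:  # dissolution stop mid-interval
                if sol.t_events[0].size:
                    t_stop = float(sol.t_events[0][0])
                    y = sol.y_events[0][0].copy()
                    y[5] = dose  # land exactly on the cap
                    capped = True
                else:
                    t_stop = float(sol.t_events[1][0])
                    y = sol.y_events[1][0].copy()
                dissolving = False
                t = t_stop
            else:
                y = sol.y[:, -1].copy()
                t = tk
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"non-finite gastroduodenal state at t={t}: {y}")

        # event at tk
        Vs_pre, Ms_pre, Vd_pre, Md_pre = y[0], y[1], y[2], y[3]
        Cs_pre = Ms_pre / Vs_pre
        Cd_pre = Md_pre / Vd_pre if Vd_pre > 0 else 0.0
        f = phys.emptying_fraction
        if Vd_pre > 0:
            emissions.append(BolusEmission(tk=tk, volume=Vd_pre, concentration=Cd_pre))
        transfer_v = f * Vs_pre
        transfer_m = f * Ms_pre
        y[0] = Vs_pre - transfer_v
        y[1] = Ms_pre - transfer_m
        y[2] = transfer_v
        y[3] = transfer_m
        event_log.append(
            {
                "tk": tk,
                "Vs_pre": Vs_pre,
                "Vs_post": y[0],
                "Cs": Cs_pre,
                "bolus_volume": Vd_pre,
                "bolus_concentration": Cd_pre,
            }
        )
        traj_t.append(tk)
        traj.append(y.copy())
        if y[0] < phys.V_stop_frac * Vs0:
            stopped_on_volume = True
            break

    arr = np.array(traj)
    return GastroduodenalResult(
        emissions=emissions,
        times=np.array(traj_t),
        Vs=arr[:, 0],
        Cs=arr[:, 1] / arr[:, 0],
        Vd=arr[:, 2],
        Cd=np.where(arr[:, 2] > 0, arr[:, 3] / np.maximum(arr[:, 2], 1e-300), 0.0),
        rp=arr[:, 4],
        dissolved_mass=arr[:, 5],
        event_log=event_log,
        dissolution_capped=capped,
        stopped_on_volume=stopped_on_volume,
    )
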