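"""Closed-loop eight-compartment hemodynamic network.

Topology (a single ring; valves in parentheses):

    LA →(mitral)→ LV →(aortic)→ SA →R_SA→ SV →R_SV→ RA →(tricuspid)→ RV
       →(pulmonary valve)→ PA →R_AP→ PV →R_PV→ LA

Compartment pressures: V/C for the windkessel vessels (SA, SV, PA, PV; the
systemic-artery compliance is modulated by the balloon pump when enabled),
time-varying elastance P = E(t)·V for the atria, and the constitutive
ventricle law for LV and RV. Dynamics are volume conservation,
dV/dt = inflow − outflow, with Ohmic inter-compartment flows, so total blood
volume is invariant.
"""

from __future__ import annotations

import math

import numpy as np

from . import iabp as iabp_mod
from .calcium import ca_at
from .myofilament import (active_tension, atp_rate, hill_activation,
                          sl_from_volume)
from .params import (COMPARTMENTS, CircParams, IABPConfig, ModelParams,
                     ValveConfig)
from .valves import diode_flow
from .ventricle import chamber_pressure

# state vector layout: 8 compartment volumes + LV and RV cross-bridge fractions
IDX = {name: i for i, name in enumerate(COMPARTMENTS)}
I_LA, I_LV, I_SA, I_SV, I_RA, I_RV, I_PA, I_PV = range(8)
I_XB_LV, I_XB_RV = 8, 9
N_STATE = 10


def atrial_activation(t: float, p: CircParams, bcl: float) -> float:
    """Normalised atrial activation a(t) ∈ [0, 1]: half-sine of
    ``atrial_duration`` starting ``atrial_onset`` into each cycle."""
    u = t % bcl
    if p.atrial_onset <= u < p.atrial_onset + p.atrial_duration:
        return math.sin(math.pi * (u - p.atrial_onset) / p.atrial_duration)
    return 0.0


def atrial_elastance(t: float, which: str, p: CircParams, bcl: float) -> float:
    """Time-varying atrial elastance E(t) = e_min + (e_max − e_min)·a(t),
    kPa/mL, for ``which`` in {'LA', 'RA'}."""
    a = atrial_activation(t, p, bcl)
    if which == "LA":
        return p.e_la_min + (p.e_la_max - p.e_la_min) * a
    if which == "RA":
        return p.e_ra_min + (p.e_ra_max - p.e_ra_min) * a
    raise ValueError("which must be 'LA' or 'RA'")


def ventricular_tensions(y, mp: ModelParams) -> tuple[float, float]:
    """Normalised LV and RV active tension from the current state."""
    sl_lv = sl_from_volume(y[I_LV], mp.myo.sl_ref, mp.lv.v_ref,
                           mp.lv.sl_wall_fraction * mp.lv.wall_volume)
    sl_rv = sl_from_volume(y[I_RV], mp.myo.sl_ref, mp.rv.v_ref,
                           mp.rv.sl_wall_fraction * mp.rv.wall_volume)
    return (active_tension(y[I_XB_LV], sl_lv, mp.myo),
            active_tension(y[I_XB_RV], sl_rv, mp.myo))


def compartment_pressures(t: float, y, mp: ModelParams,
                          iabp_cfg: IABPConfig, bcl: float) -> np.ndarray:
    """Pressure (kPa) of each compartment in COMPARTMENTS order."""
    c = mp.circ
    ten_lv, ten_rv = ventricular_tensions(y, mp)
    c_sa_t = iabp_mod.compliance(t, c.c_sa, iabp_cfg)
    p = np.empty(8)
    p[I_LA] = atrial_elastance(t, "LA", c, bcl) * y[I_LA]
    p[I_RA] = atrial_elastance(t, "RA", c, bcl) * y[I_RA]
    p[I_LV] = chamber_pressure(y[I_LV], ten_lv, mp.lv, mp.failing)
    p[I_RV] = chamber_pressure(y[I_RV], ten_rv, mp.rv, mp.failing)
    p[I_SA] = y[I_SA] / c_sa_t
    p[I_SV] = y[I_SV] / c.c_sv
    p[I_PA] = y[I_PA] / c.c_pa
    p[I_PV] = y[I_PV] / c.c_pv
    return p


def flows(t: float, y, mp: ModelParams, mi_cfg: ValveConfig,
          ao_cfg: ValveConfig, iabp_cfg: IABPConfig,
          bcl: float) -> dict[str, float]:
    """Inter-compartment flows (mL/s) along the ring, keyed by segment."""
    c = mp.circ
    p = compartment_pressures(t, y, mp, iabp_cfg, bcl)
    return {
        "mitral": diode_flow(p[I_LA], p[I_LV], mi_cfg.r_forward,
                             mi_cfg.leak_sf),
        "aortic": diode_flow(p[I_LV], p[I_SA], ao_cfg.r_forward,
                             ao_cfg.leak_sf),
        "systemic": (p[I_SA] - p[I_SV]) / c.r_sa,
        "venous_return": (p[I_SV] - p[I_RA]) / c.r_sv,
        "tricuspid": diode_flow(p[I_RA], p[I_RV], c.r_tri, 0.0),
        "pulmonary_valve": diode_flow(p[I_RV], p[I_PA], c.r_pu, 0.0),
        "pulmonary": (p[I_PA] - p[I_PV]) / c.r_ap,
        "pulmonary_venous": (p[I_PV] - p[I_LA]) / c.r_pv,
    }


def derivatives(t: float, y, mp: ModelParams, mi_cfg: ValveConfig,
                ao_cfg: ValveConfig, iabp_cfg: IABPConfig,
                bcl: float) -> np.ndarray:
    """Right-hand side: dV/dt (mL/ms) for the 8 compartments plus the two
    cross-bridge fractions (1/ms)."""
    if not np.all(np.isfinite(y)) or np.any(y[:8] <= 0.0):
        raise FloatingPointError(
            f"integration failure at t = {t:.3f} ms: nonpositive or "
            f"non-finite volume in state {np.asarray(y)[:8]}")
    q = flows(t, y, mp, mi_cfg, ao_cfg, iabp_cfg, bcl)
    dy = np.empty(N_STATE)
    # flows are mL/s, time is ms
    dy[I_LA] = (q["pulmonary_venous"] - q["mitral"]) * 1e-3
    dy[I_LV] = (q["mitral"] - q["aortic"]) * 1e-3
    dy[I_SA] = (q["aortic"] - q["systemic"]) * 1e-3
    dy[I_SV] = (q["systemic"] - q["venous_return"]) * 1e-3
    dy[I_RA] = (q["venous_return"] - q["tricuspid"]) * 1e-3
    dy[I_RV] = (q["tricuspid"] - q["pulmonary_valve"]) * 1e-3
    dy[I_PA] = (q["pulmonary_valve"] - q["pulmonary"]) * 1e-3
    dy[I_PV] = (q["pulmonary"] - q["pulmonary_venous"]) * 1e-3

    ca = ca_at(t, mp.ca, mp.failing)
    h = hill_activation(ca, mp.myo)
    f, g = mp.myo.f_xb, mp.myo.g_xbT
    dy[I_XB_LV] = f * h * (1.0 - y[I_XB_LV]) - g * y[I_XB_LV]
    dy[I_XB_RV] = f * h * (1.0 - y[I_XB_RV]) - g * y[I_XB_RV]
    return dy


def atp_rates(y, mp: ModelParams) -> tuple[float, float]:
    """Contractile ATP consumption rate (1/ms per unit wall volume) of the LV
    and RV walls in the current state."""
    sl_lv = sl_from_volume(y[I_LV], mp.myo.sl_ref, mp.lv.v_ref,
                           mp.lv.sl_wall_fraction * mp.lv.wall_volume)
    sl_rv = sl_from_volume(y[I_RV], mp.myo.sl_ref, mp.rv.v_ref,
                           mp.rv.sl_wall_fraction * mp.rv.wall_volume)
    return (atp_rate(y[I_XB_LV], sl_lv, mp.myo),
            atp_rate(y[I_XB_RV], sl_rv, mp.myo))
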