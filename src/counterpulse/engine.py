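"""Time integration of the coupled circulation + myofilament + balloon-pump
system, steady-state detection, and beat segmentation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import iabp as iabp_mod
from .calcium import ca_at
from .circulation import I_XB_LV, I_XB_RV, N_STATE
from .myofilament import active_tension, atp_rate, sl_from_volume
from .params import (COMPARTMENTS, ModelParams, SimulationConfig, ValveConfig)
from .valves import diode_flow
from .ventricle import chamber_pressure


class EngineError(RuntimeError):
    """Integration failed (solver breakdown or unphysical state)."""


@dataclass
class BeatSeries:
    """Time-aligned traces for a contiguous stretch of simulation (one beat
    when produced by segment_beats). Pressures kPa, volumes mL, flows mL/s,
    ATP rate 1/ms per unit wall volume."""

    t: np.ndarray                       # ms, absolute simulation time
    volumes: dict[str, np.ndarray]
    pressures: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    tension_lv: np.ndarray
    tension_rv: np.ndarray
    atp_rate_lv: np.ndarray
    atp_rate_rv: np.ndarray
    ca: np.ndarray                      # µM
    params: ModelParams
    config: SimulationConfig

    def __len__(self) -> int:
        return len(self.t)

    def slice(self, i0: int, i1: int) -> "BeatSeries":
        cut = lambda a: a[i0:i1]
        return BeatSeries(
            t=cut(self.t),
            volumes={k: cut(v) for k, v in self.volumes.items()},
            pressures={k: cut(v) for k, v in self.pressures.items()},
            flows={k: cut(v) for k, v in self.flows.items()},
            tension_lv=cut(self.tension_lv), tension_rv=cut(self.tension_rv),
            atp_rate_lv=cut(self.atp_rate_lv),
            atp_rate_rv=cut(self.atp_rate_rv),
            ca=cut(self.ca), params=self.params, config=self.config)


@dataclass
class SimulationResult:
    series: BeatSeries          # full run
    beats: list[BeatSeries]     # complete beats, activation-aligned
    steady_state: bool          # last-two-beat EDV drift < 1%
    edv_drift: float            # relative EDV change between final two beats
    config: SimulationConfig
    params: ModelParams

    @property
    def final_beat(self) -> BeatSeries:
        return self.beats[-1]


def valve_configs(cfg: SimulationConfig,
                  mp: ModelParams) -> tuple[ValveConfig, ValveConfig]:
    """Mitral and aortic valve configs for the protocol condition: the leak
    severity is applied to the regurgitant valve only."""
    mi_sf = cfg.severity if cfg.condition == "MR" else 0.0
    ao_sf = cfg.severity if cfg.condition == "AR" else 0.0
    return (ValveConfig("mitral", mp.circ.r_mi, mi_sf),
            ValveConfig("aortic", mp.circ.r_ao, ao_sf))


def _vector_flows(t, p, mp, mi_cfg, ao_cfg):
    """Vectorised inter-compartment flows from pressure arrays (mL/s)."""
    c = mp.circ

    def diode(dp, r, sf):
        return np.where(dp > 0, dp / r, dp / r * (sf / 100.0))

    return {
        "mitral": diode(p["LA"] - p["LV"], mi_cfg.r_forward, mi_cfg.leak_sf),
        "aortic": diode(p["LV"] - p["SA"], ao_cfg.r_forward, ao_cfg.leak_sf),
        "systemic": (p["SA"] - p["SV"]) / c.r_sa,
        "venous_return": (p["SV"] - p["RA"]) / c.r_sv,
        "tricuspid": diode(p["RA"] - p["RV"], c.r_tri, 0.0),
        "pulmonary_valve": diode(p["RV"] - p["PA"], c.r_pu, 0.0),
        "pulmonary": (p["PA"] - p["PV"]) / c.r_ap,
        "pulmonary_venous": (p["PV"] - p["LA"]) / c.r_pv,
    }


def evaluate_series(t: np.ndarray, y: np.ndarray, mp: ModelParams,
                    mi_cfg: ValveConfig, ao_cfg: ValveConfig,
                    cfg: SimulationConfig) -> BeatSeries:
    """Derive pressures, flows, tension and ATP-rate traces from sampled
    states (t: (n,), y: (n, N_STATE))."""
    c, bcl = mp.circ, cfg.bcl
    vols = {name: y[:, i] for i, name in enumerate(COMPARTMENTS)}

    u = np.mod(t, bcl)
    inside = (u >= c.atrial_onset) & (u < c.atrial_onset + c.atrial_duration)
    act = np.where(inside, np.sin(
        np.pi * (u - c.atrial_onset) / c.atrial_duration), 0.0)

    sl_lv = sl_from_volume(vols["LV"], mp.myo.sl_ref, mp.lv.v_ref,
                           mp.lv.sl_wall_fraction * mp.lv.wall_volume)
    sl_rv = sl_from_volume(vols["RV"], mp.myo.sl_ref, mp.rv.v_ref,
                           mp.rv.sl_wall_fraction * mp.rv.wall_volume)
    ten_lv = active_tension(y[:, I_XB_LV], sl_lv, mp.myo)
    ten_rv = active_tension(y[:, I_XB_RV], sl_rv, mp.myo)

    c_sa_t = iabp_mod.compliance(t, c.c_sa, cfg.iabp)
    pres = {
        "LA": (c.e_la_min + (c.e_la_max - c.e_la_min) * act) * vols["LA"],
        "RA": (c.e_ra_min + (c.e_ra_max - c.e_ra_min) * act) * vols["RA"],
        "LV": chamber_pressure(vols["LV"], ten_lv, mp.lv, mp.failing),
        "RV": chamber_pressure(vols["RV"], ten_rv, mp.rv, mp.failing),
        "SA": vols["SA"] / c_sa_t,
        "SV": vols["SV"] / c.c_sv,
        "PA": vols["PA"] / c.c_pa,
        "PV": vols["PV"] / c.c_pv,
    }
    return BeatSeries(
        t=t, volumes=vols, pressures=pres,
        flows=_vector_flows(t, pres, mp, mi_cfg, ao_cfg),
        tension_lv=ten_lv, tension_rv=ten_rv,
        atp_rate_lv=atp_rate(y[:, I_XB_LV], sl_lv, mp.myo),
        atp_rate_rv=atp_rate(y[:, I_XB_RV], sl_rv, mp.myo),
        ca=ca_at(t, mp.ca, mp.failing), params=mp, config=cfg)


def series_to_frame(series: BeatSeries):
    """Tidy long-format table (time_ms, variable, value) of a series: per-
    compartment pressures (kPa) and volumes (mL), valve/segment flows (mL/s),
    normalised tensions and ATP rates, and the Ca transient."""
    import pandas as pd

    cols: dict[str, np.ndarray] = {}
    for k, v in series.pressures.items():
        cols[f"P_{k}"] = v
    for k, v in series.volumes.items():
        cols[f"V_{k}"] = v
    for k, v in series.flows.items():
        cols[f"Q_{k}"] = v
    cols["tension_LV"] = series.tension_lv
    cols["tension_RV"] = series.tension_rv
    cols["atp_rate_LV"] = series.atp_rate_lv
    cols["atp_rate_RV"] = series.atp_rate_rv
    cols["ca"] = series.ca
    frames = [pd.DataFrame({"time_ms": series.t, "variable": name,
                            "value": arr}) for name, arr in cols.items()]
    return pd.concat(frames, ignore_index=True)


def segment_beats(series: BeatSeries, bcl: float) -> list[BeatSeries]:
    """Split a series into complete beats aligned to activation onsets
    (t = k·bcl); a leading partial beat is discarded. Each beat includes both
    endpoints, so it spans exactly one bcl."""
    t = series.t
    if t[-1] - t[0] < bcl:
        raise EngineError("series shorter than one beat")
    k0 = int(np.ceil(t[0] / bcl - 1e-9))
    beats = []
    while (k0 + 1) * bcl <= t[-1] + 1e-9:
        i0 = int(np.searchsorted(t, k0 * bcl - 1e-9))
        i1 = int(np.searchsorted(t, (k0 + 1) * bcl + 1e-9, side="left"))
        beats.append(series.slice(i0, i1))
        k0 += 1
    return beats


def _make_rhs(mp: ModelParams, mi_cfg: ValveConfig, ao_cfg: ValveConfig,
              cfg: SimulationConfig):
    """Scalar-arithmetic right-hand side, algebraically identical to
    circulation.derivatives but avoiding per-call array/dict construction
    (the integrator calls it ~1e5 times per run)."""
    import math

    c, myo, lv, rv = mp.circ, mp.myo, mp.lv, mp.rv
    ca_cfg, failing = mp.ca, mp.failing
    bcl = cfg.bcl
    mi_sf, ao_sf = mi_cfg.leak_sf / 100.0, ao_cfg.leak_sf / 100.0
    k_stiff = lv.hf_stiffness_factor if failing else 1.0
    k_stiff_rv = rv.hf_stiffness_factor if failing else 1.0
    four_pi_3 = 4.0 * math.pi / 3.0
    amp = (ca_cfg.peak_normal - ca_cfg.diastolic_level) * (
        ca_cfg.hf_peak_fraction if failing else 1.0)
    tail = math.exp(-(bcl - ca_cfg.time_to_peak) / ca_cfg.decay_tau)
    iabp_on = cfg.iabp.enabled
    sf, phase = cfg.iabp.sf, cfg.iabp.phase
    ca50n = myo.ca50 ** myo.hill_n

    def ventricle_p(v, xb, vp, k):
        base = k * vp.passive_scale * math.expm1(
            vp.passive_exponent * (v - vp.v0))
        p_pas = base if v >= vp.v0 else 0.1 * base
        voff = vp.sl_wall_fraction * vp.wall_volume
        sl = myo.sl_ref * ((v + voff) / (vp.v_ref + voff)) ** (1.0 / 3.0)
        up = (sl - myo.sl_zero_low) / (myo.sl_min_overlap - myo.sl_zero_low)
        down = (myo.sl_zero_high - sl) / (myo.sl_zero_high - myo.sl_max_overlap)
        sovf = min(up, down, 1.0)
        sovf = 0.0 if sovf < 0.0 else sovf
        r = (v / four_pi_3) ** (1.0 / 3.0)
        h = ((v + vp.wall_volume) / four_pi_3) ** (1.0 / 3.0) - r
        return p_pas + 2.0 * vp.t_max * xb * sovf * h / r

    def rhs(t, y):
        (v_la, v_lv, v_sa, v_sv, v_ra, v_rv, v_pa, v_pv,
         xb_lv, xb_rv) = y
        if v_la <= 0 or v_lv <= 0 or v_sa <= 0 or v_sv <= 0 or v_ra <= 0 \
                or v_rv <= 0 or v_pa <= 0 or v_pv <= 0:
            raise FloatingPointError(
                f"integration failure at t = {t:.3f} ms: nonpositive volume")
        u = t % bcl
        if c.atrial_onset <= u < c.atrial_onset + c.atrial_duration:
            act = math.sin(math.pi * (u - c.atrial_onset) / c.atrial_duration)
        else:
            act = 0.0
        p_la = (c.e_la_min + (c.e_la_max - c.e_la_min) * act) * v_la
        p_ra = (c.e_ra_min + (c.e_ra_max - c.e_ra_min) * act) * v_ra
        p_lv = ventricle_p(v_lv, xb_lv, lv, k_stiff)
        p_rv = ventricle_p(v_rv, xb_rv, rv, k_stiff_rv)
        if iabp_on:
            c_sa_t = c.c_sa * ((1.0 - sf) + sf * math.cos(
                2.0 * math.pi * (t - 0.5 * bcl) / bcl - phase))
        else:
            c_sa_t = c.c_sa
        p_sa = v_sa / c_sa_t
        p_sv = v_sv / c.c_sv
        p_pa = v_pa / c.c_pa
        p_pv = v_pv / c.c_pv

        dp = p_la - p_lv
        q_mi = dp / c.r_mi if dp > 0 else dp / c.r_mi * mi_sf
        dp = p_lv - p_sa
        q_ao = dp / c.r_ao if dp > 0 else dp / c.r_ao * ao_sf
        q_sys = (p_sa - p_sv) / c.r_sa
        q_ven = (p_sv - p_ra) / c.r_sv
        dp = p_ra - p_rv
        q_tri = dp / c.r_tri if dp > 0 else 0.0
        dp = p_rv - p_pa
        q_pu = dp / c.r_pu if dp > 0 else 0.0
        q_pul = (p_pa - p_pv) / c.r_ap
        q_pven = (p_pv - p_la) / c.r_pv

        # ca transient (continuous periodic template)
        uca = (t - ca_cfg.activation_delay) % bcl
        if t < ca_cfg.activation_delay:
            ca = ca_cfg.diastolic_level
        elif uca < ca_cfg.time_to_peak:
            ca = ca_cfg.diastolic_level + amp * 0.5 * (
                1.0 - math.cos(math.pi * uca / ca_cfg.time_to_peak))
        else:
            ca = ca_cfg.diastolic_level + amp * (
                math.exp(-(uca - ca_cfg.time_to_peak) / ca_cfg.decay_tau)
                - tail) / (1.0 - tail)
        can = ca ** myo.hill_n
        h_act = can / (can + ca50n)

        return (
            (q_pven - q_mi) * 1e-3,
            (q_mi - q_ao) * 1e-3,
            (q_ao - q_sys) * 1e-3,
            (q_sys - q_ven) * 1e-3,
            (q_ven - q_tri) * 1e-3,
            (q_tri - q_pu) * 1e-3,
            (q_pu - q_pul) * 1e-3,
            (q_pul - q_pven) * 1e-3,
            myo.f_xb * h_act * (1.0 - xb_lv) - myo.g_xbT * xb_lv,
            myo.f_xb * h_act * (1.0 - xb_rv) - myo.g_xbT * xb_rv,
        )

    return rhs


def run(cfg: SimulationConfig,
        params: ModelParams | None = None) -> SimulationResult:
    """Integrate the full system from the tabulated initial volumes and zero
    cross-bridge occupancy, sample on a uniform grid, and segment beats.

    Deterministic: there is no randomness in the default pipeline, so
    identical configs give identical outputs at fixed solver settings.
    """
    mp = params if params is not None else ModelParams()
    mi_cfg, ao_cfg = valve_configs(cfg, mp)

    y0 = np.zeros(N_STATE)
    y0[:8] = mp.circ.initial_volumes

    rhs = _make_rhs(mp, mi_cfg, ao_cfg, cfg)

    t_eval = np.arange(0.0, cfg.duration + 0.5 * cfg.sample_dt, cfg.sample_dt)
    try:
        sol = solve_ivp(rhs, (0.0, cfg.duration), y0, method="LSODA",
                        t_eval=t_eval, rtol=cfg.rtol, atol=cfg.atol,
                        max_step=2.0)
    except FloatingPointError as exc:
        raise EngineError(str(exc)) from exc
    if not sol.success:
        raise EngineError(f"solver failed: {sol.message}")

    series = evaluate_series(sol.t, sol.y.T, mp, mi_cfg, ao_cfg, cfg)
    beats = segment_beats(series, cfg.bcl)
    edv = [float(np.max(b.volumes["LV"])) for b in beats[-2:]]
    drift = abs(edv[-1] - edv[-2]) / edv[-2]
    return SimulationResult(series=series, beats=beats,
                            steady_state=drift < 0.01, edv_drift=drift,
                            config=cfg, params=mp)
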