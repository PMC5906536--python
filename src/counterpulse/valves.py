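"""Mitral and aortic valves as static one-way check valves with a leak branch.

Each valve has a forward diode of resistance R and a backward (leak) diode of
resistance R/(SF/100), where SF is the regurgitation severity in percent:

    Q = (P_up − P_down)/R            when P_up > P_down   (forward)
    Q = (P_up − P_down)/R · SF/100   when P_up ≤ P_down   (leak, Q ≤ 0)

SF = 0 seals the valve in reverse; both branches vanish at equal pressures,
so flow is continuous at the switching point.
"""

from __future__ import annotations

from .params import ValveConfig


def diode_flow(p_up: float, p_down: float, r: float, leak_sf: float) -> float:
    """Flow (mL/s) through a forward/leak diode pair; negative = regurgitant."""
    dp = p_up - p_down
    if dp > 0.0:
        return dp / r
    return dp / r * (leak_sf / 100.0)


def mitral_flow(p_la: float, p_lv: float, cfg: ValveConfig) -> float:
    """Mitral flow (mL/s), LA → LV positive."""
    if cfg.which != "mitral":
        raise ValueError("cfg.which must be 'mitral'")
    return diode_flow(p_la, p_lv, cfg.r_forward, cfg.leak_sf)


def aortic_flow(p_lv: float, p_ao: float, cfg: ValveConfig) -> float:
    """Aortic flow (mL/s), LV → systemic artery positive."""
    if cfg.which != "aortic":
        raise ValueError("cfg.which must be 'aortic'")
    return diode_flow(p_lv, p_ao, cfg.r_forward, cfg.leak_sf)
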