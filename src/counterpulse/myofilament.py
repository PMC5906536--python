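"""Reduced cross-bridge cycling model.

A two-state (detached / strongly bound) scheme: Ca2+ binds cooperatively
(Hill activation H(Ca)) and recruits cross-bridges at rate f_xb·H·(1−xb);
bridges detach — consuming one ATP each — at rate g_xbT·xb. Contractile ATP
turnover per unit wall volume is the detachment flux weighted by the
single-overlap fraction of the thick filament, SOVF_Thick(sl):

    ATP rate = g_xbT · SOVF_Thick(sl) · xb

(occupancy xb = 1 recovers the bare product g_xbT·SOVF_Thick). Normalised
active tension is xb·SOVF_Thick(sl), which ties force and energy consumption
to sarcomere length and hence, through the volume→length mapping, to chamber
filling (Frank–Starling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import MyofilamentParams


@dataclass
class MyofilamentState:
    xb_fraction: float  # strongly bound cross-bridge fraction, 0..1
    sl: float           # sarcomere length, µm

    def __post_init__(self) -> None:
        if not (0.0 <= self.xb_fraction <= 1.0):
            raise ValueError("xb_fraction must lie in [0, 1]")


def sovf_thick(sl, p: MyofilamentParams):
    """Single-overlap fraction of the thick filament at sarcomere length ``sl``.

    Symmetric trapezoid: 1 on the plateau [sl_min_overlap, sl_max_overlap],
    falling linearly to 0 at sl_zero_low / sl_zero_high, clamped outside.
    """
    sl = np.asarray(sl, dtype=float)
    if np.any(sl <= 0):
        raise ValueError("sarcomere length must be positive")
    up = (sl - p.sl_zero_low) / (p.sl_min_overlap - p.sl_zero_low)
    down = (p.sl_zero_high - sl) / (p.sl_zero_high - p.sl_max_overlap)
    out = np.clip(np.minimum(np.minimum(up, down), 1.0), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def hill_activation(ca, p: MyofilamentParams):
    """Cooperative Ca2+ activation H(Ca) = Ca^n / (Ca^n + Ca50^n)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca concentration must be nonnegative")
    can = np.power(ca, p.hill_n)
    out = can / (can + p.ca50 ** p.hill_n)
    return float(out) if out.ndim == 0 else out


def xb_derivative(xb: float, ca: float, p: MyofilamentParams) -> float:
    """d(xb)/dt (1/ms) of the two-state scheme.

    The attachment term vanishes at xb = 1 and the detachment term at xb = 0,
    so trajectories cannot leave [0, 1].
    """
    h = hill_activation(ca, p)
    return p.f_xb * h * (1.0 - xb) - p.g_xbT * xb


def xb_steady_state(ca: float, p: MyofilamentParams) -> float:
    """Closed-form fixed point of the two-state scheme at constant Ca."""
    fh = p.f_xb * hill_activation(ca, p)
    return fh / (fh + p.g_xbT)


def active_tension(xb, sl, p: MyofilamentParams):
    """Normalised active tension xb·SOVF_Thick(sl), in [0, 1]."""
    return xb * sovf_thick(sl, p)


def atp_rate(xb, sl, p: MyofilamentParams):
    """Contractile ATP consumption rate (1/ms per unit wall volume):
    g_xbT · SOVF_Thick(sl) · xb."""
    return p.g_xbT * sovf_thick(sl, p) * xb


def sl_from_volume(v, sl_ref: float, v_ref: float, v_offset: float = 0.0):
    """Sarcomere length from chamber volume:

        sl = sl_ref · ((V + V_off) / (V_ref + V_off))^(1/3)

    Isotropic scaling of the chamber maps a volume ratio onto a linear
    stretch of the wall, coupling filling to overlap (Frank–Starling).
    ``v_offset`` is half the wall volume, so the stretch follows the midwall
    radius rather than the cavity radius: cavity-volume scaling alone
    overstates fibre excursion for large stroke volumes, pushing end-systolic
    lengths below the overlap range.
    """
    v = np.asarray(v, dtype=float)
    return sl_ref * np.cbrt((v + v_offset) / (v_ref + v_offset))
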