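"""Per-beat hemodynamic and energetic endpoints.

Stroke volume is reported two ways: EDV−ESV measures ventricular excursion,
while the *practical* stroke volume — the net aortic-valve flow integral over
one beat — is the volume actually delivered to the artery; the two differ
under regurgitation. Stroke work is the area of the LV pressure-volume loop
(positive when traversed counter-clockwise). Contractile ATP consumption per
beat integrates the cross-bridge detachment flux g_xbT·SOVF_Thick·xb over the
beat, scaled by wall volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .engine import BeatSeries
from .params import KPA_TO_MMHG


@dataclass(frozen=True)
class BeatMetrics:
    edv: float                   # mL
    esv: float                   # mL
    sv_practical: float          # mL, net aortic flow integral
    ef: float                    # fraction, sv_practical / edv
    regurgitant_volume: float    # mL, magnitude of backward valve flow
    regurgitant_fraction: float  # fraction of total ejected volume
    stroke_work: float           # mL·kPa
    stroke_work_mmhg: float      # mL·mmHg
    atp_per_beat: float          # normalized units (wall-volume-scaled)
    lv_peak_pressure: float      # kPa
    arterial_pulse_pressure: float  # kPa


def _flow_integral(t: np.ndarray, q: np.ndarray) -> float:
    """∫ q dt with q in mL/s and t in ms → mL."""
    return float(np.trapezoid(q, t)) * 1e-3


def practical_sv(beat: BeatSeries) -> float:
    """Net aortic-valve flow integral (forward minus leak) over the beat, mL."""
    return _flow_integral(beat.t, beat.flows["aortic"])


def forward_ejected_volume(beat: BeatSeries) -> float:
    """Forward (positive) aortic flow integral over the beat, mL."""
    return _flow_integral(beat.t, np.maximum(beat.flows["aortic"], 0.0))


def regurgitant_volume(beat: BeatSeries, valve: str) -> float:
    """Backward volume (mL, magnitude) through ``valve`` ('aortic' or
    'mitral') over the beat."""
    if valve not in ("aortic", "mitral"):
        raise ValueError("valve must be 'aortic' or 'mitral'")
    return -_flow_integral(beat.t, np.minimum(beat.flows[valve], 0.0))


def stroke_work(beat: BeatSeries, close_tol: float = 1.0) -> float:
    """Signed shoelace area of the LV pressure-volume loop, mL·kPa, positive
    counter-clockwise. An open loop (endpoint gap > ``close_tol`` mL in volume)
    is closed by a straight segment with a warning."""
    v = np.asarray(beat.volumes["LV"], dtype=float)
    p = np.asarray(beat.pressures["LV"], dtype=float)
    if abs(v[-1] - v[0]) > close_tol:
        warnings.warn("PV loop endpoints differ by more than the closure "
                      "tolerance; closing with a straight segment",
                      stacklevel=2)
    # shoelace over the closed polygon (last vertex joined back to first)
    area = 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))
    return area


def atp_per_beat(beat: BeatSeries, chamber: str = "LV") -> float:
    """Contractile ATP consumption over the beat: ∫ g_xbT·SOVF·xb dt scaled
    by wall volume (normalized units)."""
    if chamber == "LV":
        rate, wall = beat.atp_rate_lv, beat.params.lv.wall_volume
    elif chamber == "RV":
        rate, wall = beat.atp_rate_rv, beat.params.rv.wall_volume
    else:
        raise ValueError("chamber must be 'LV' or 'RV'")
    return float(np.trapezoid(rate, beat.t)) * wall


def ef(beat: BeatSeries) -> float:
    """Ejection fraction: practical stroke volume over end-diastolic volume."""
    edv = float(np.max(beat.volumes["LV"]))
    if edv <= 0:
        raise ValueError("edv must be positive")
    return practical_sv(beat) / edv


def compute_beat_metrics(beat: BeatSeries) -> BeatMetrics:
    """All endpoints for one steady-state beat. The regurgitant volume is the
    protocol valve's backflow (aortic under AR, mitral under MR, and the
    larger of the two — numerically zero — at baseline)."""
    v_lv = beat.volumes["LV"]
    edv, esv = float(np.max(v_lv)), float(np.min(v_lv))
    sv = practical_sv(beat)
    cond = beat.config.condition
    if cond == "AR":
        rv = regurgitant_volume(beat, "aortic")
    elif cond == "MR":
        rv = regurgitant_volume(beat, "mitral")
    else:
        rv = max(regurgitant_volume(beat, "aortic"),
                 regurgitant_volume(beat, "mitral"))
    fwd = forward_ejected_volume(beat)
    rf = rv / (rv + fwd) if (rv + fwd) > 0 else 0.0
    sw = stroke_work(beat)
    p_sa = beat.pressures["SA"]
    return BeatMetrics(
        edv=edv, esv=esv, sv_practical=sv, ef=ef(beat),
        regurgitant_volume=rv, regurgitant_fraction=rf,
        stroke_work=sw, stroke_work_mmhg=sw * KPA_TO_MMHG,
        atp_per_beat=atp_per_beat(beat, "LV"),
        lv_peak_pressure=float(np.max(beat.pressures["LV"])),
        arterial_pulse_pressure=float(np.max(p_sa) - np.min(p_sa)))
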