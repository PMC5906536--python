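"""Lumped constitutive law of a ventricle: exponential passive filling plus a
thin-walled-sphere Laplace active term driven by normalised myofilament
tension. Replaces a finite-element mechanics model with the minimal pressure-
volume behaviour needed by a closed-loop circulation."""

from __future__ import annotations

import math

import numpy as np

from .params import VentricleParams

_FOUR_PI_3 = 4.0 * math.pi / 3.0


def passive_pressure(v, p: VentricleParams, failing: bool = True):
    """Passive (end-diastolic) pressure, kPa.

    P = k·S·(exp(E·(v−v0)) − 1) for v ≥ v0 with k = hf_stiffness_factor when
    failing; below v0 the same form scaled ×0.1 gives a gently negative
    suction branch. Monotonically increasing in v.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    k = p.hf_stiffness_factor if failing else 1.0
    base = k * p.passive_scale * np.expm1(p.passive_exponent * (v - p.v0))
    out = np.where(v >= p.v0, base, 0.1 * base)
    return float(out) if out.ndim == 0 else out


def wall_thickness(v, p: VentricleParams):
    """Thickness h (cm, with mL ≡ cm³) of an incompressible spherical shell of
    volume ``wall_volume`` wrapped around cavity volume ``v``."""
    v = np.asarray(v, dtype=float)
    r = np.cbrt(v / _FOUR_PI_3)
    return np.cbrt((v + p.wall_volume) / _FOUR_PI_3) - r


def active_pressure(v, tension, p: VentricleParams):
    """Active cavity pressure by Laplace's law for a thin-walled sphere:
    P = 2·σ·h/r with wall stress σ = t_max·tension. Linear in tension."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    r = np.cbrt(v / _FOUR_PI_3)
    out = 2.0 * p.t_max * np.asarray(tension) * wall_thickness(v, p) / r
    return float(out) if out.ndim == 0 else out


def chamber_pressure(v, tension, p: VentricleParams, failing: bool = True):
    """Total cavity pressure: passive + active, kPa."""
    return passive_pressure(v, p, failing) + active_pressure(v, tension, p)
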