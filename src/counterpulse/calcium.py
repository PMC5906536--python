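"""Synthetic periodic Ca2+ transient.

Stand-in for the output of a 3D electrophysiological simulation: a single
representative intracellular Ca2+ waveform per cycle, with the heart-failure
remodeling of peak Ca2+ to 70% of the healthy amplitude. The waveform is a
raised half-sine upstroke followed by an exponential relaxation normalised to
return exactly to the diastolic level at the end of the cycle, so the
transient is continuous and exactly periodic.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CaTransientConfig


def effective_peak(cfg: CaTransientConfig, failing: bool) -> float:
    """Peak Ca2+ concentration (µM) for the selected phenotype."""
    amp = cfg.peak_normal - cfg.diastolic_level
    if failing:
        amp *= cfg.hf_peak_fraction
    return cfg.diastolic_level + amp


def ca_at(t, cfg: CaTransientConfig, failing: bool = True):
    """Intracellular Ca2+ concentration (µM) at time ``t`` (ms).

    Accepts a scalar or ndarray; before the first activation
    (t < activation_delay) the diastolic level is returned.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    amp = effective_peak(cfg, failing) - cfg.diastolic_level
    u = np.mod(t - cfg.activation_delay, cfg.bcl)
    ttp, tau = cfg.time_to_peak, cfg.decay_tau

    rising = u < ttp
    shape = np.empty_like(u)
    shape[rising] = 0.5 * (1.0 - np.cos(math.pi * u[rising] / ttp))
    # exponential decay, renormalised to hit 0 exactly at u = bcl
    tail = math.exp(-(cfg.bcl - ttp) / tau)
    dec = (np.exp(-(u[~rising] - ttp) / tau) - tail) / (1.0 - tail)
    shape[~rising] = dec

    out = cfg.diastolic_level + amp * shape
    out = np.where(t < cfg.activation_delay, cfg.diastolic_level, out)
    return float(out) if out.ndim == 0 else out
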