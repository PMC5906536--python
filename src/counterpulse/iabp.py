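"""Intra-aortic balloon pump as harmonic time-varying arterial compliance.

Balloon inflation displaces volume inside the aorta, which a 0D network sees
as a drop in effective systemic-artery compliance; deflation restores it.
The inflation/deflation cycle is idealised as a cosine:

    C_SA,IABP(t) = C_SA · SF_IABP(t)
    SF_IABP(t)   = (1 − sf) + sf · cos(2πt/BCL − φ)

so compliance oscillates between (1 − 2·sf)·C_SA and C_SA once per beat.

Clock convention: simulation time t = 0 is ventricular activation onset
(end-diastole). The pump's cosine is referenced to a clock offset half a
cycle from the activation clock; under that convention the stated phase
φ = 3.66 rad (a 350 ms shift at BCL = 600 ms) places balloon inflation — the
compliance minimum — 350 ms after end-diastole, i.e. in diastole (diastolic
pressure augmentation), and deflation in systole (systolic unloading).
Evaluating the cosine directly on the activation clock would invert the
timing and turn the pump into an afterload amplifier.
"""

from __future__ import annotations

import math

import numpy as np

from .params import IABPConfig, ConfigurationError


def scale_factor(t, cfg: IABPConfig):
    """SF_IABP(t): dimensionless compliance multiplier in [1 − 2·sf, 1]."""
    t = np.asarray(t, dtype=float)
    out = (1.0 - cfg.sf) + cfg.sf * np.cos(
        2.0 * math.pi * t / cfg.bcl - cfg.phase)
    return float(out) if out.ndim == 0 else out


def compliance(t, c_sa: float, cfg: IABPConfig):
    """Effective systemic-artery compliance (mL/kPa) at time t (ms)."""
    if c_sa <= 0:
        raise ConfigurationError("c_sa must be positive")
    if not cfg.enabled:
        return c_sa if np.isscalar(t) else np.full(np.shape(t), c_sa)
    if cfg.sf > 0.5:
        raise ConfigurationError("sf > 0.5 would zero or negate compliance")
    # half-cycle reference shift: the pump clock's zero sits mid-cycle on the
    # activation clock, so inflation lands phase·BCL/2π after end-diastole
    return c_sa * scale_factor(np.asarray(t, dtype=float) - 0.5 * cfg.bcl, cfg)


def phase_from_delay(delay: float, bcl: float) -> float:
    """Convert a time shift (ms) into a pumping phase (rad), wrapped to
    [0, 2π): 350 ms at BCL 600 ms gives 3.665… ≈ 3.66 rad."""
    if bcl <= 0:
        raise ConfigurationError("bcl must be positive")
    return (2.0 * math.pi * delay / bcl) % (2.0 * math.pi)
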