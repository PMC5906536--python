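"""Parameter containers for the closed-loop circulation and its surrogate ventricles.

Internal unit system: pressures in kPa, volumes in mL, time in ms.
Resistances are kPa·s/mL (so pressure/resistance is a flow in mL/s);
volume derivatives are converted to mL/ms inside the integrator.
Pressures are additionally reported in mmHg (1 kPa = 7.50062 mmHg) because
clinical pressure traces are conventionally read in mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import yaml

KPA_TO_MMHG = 7.50062

#: Compartment ordering used throughout the state vector.
COMPARTMENTS = ("LA", "LV", "SA", "SV", "RA", "RV", "PA", "PV")


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class CaTransientConfig:
    """Shape of the periodic intracellular Ca2+ transient driving contraction.

    The transient rises from ``diastolic_level`` to ``peak_normal`` as a raised
    half-sine over ``time_to_peak`` and relaxes back along a single exponential
    with time constant ``decay_tau``, normalised so one period is continuous.
    In the failing myocyte the peak amplitude above diastole is scaled by
    ``hf_peak_fraction`` (systolic dysfunction).
    """

    diastolic_level: float = 0.1   # µM
    peak_normal: float = 1.1       # µM
    hf_peak_fraction: float = 0.7  # failing peak amplitude / healthy amplitude
    time_to_peak: float = 50.0     # ms
    decay_tau: float = 150.0       # ms
    bcl: float = 600.0             # ms, basic cycle length
    activation_delay: float = 0.0  # ms

    def __post_init__(self) -> None:
        if self.bcl <= 0 or self.decay_tau <= 0:
            raise ConfigurationError("bcl and decay_tau must be positive")
        if not (0.0 < self.hf_peak_fraction <= 1.0):
            raise ConfigurationError("hf_peak_fraction must lie in (0, 1]")
        if not (self.peak_normal > self.diastolic_level > 0.0):
            raise ConfigurationError("need peak_normal > diastolic_level > 0")
        if not (self.bcl > self.time_to_peak > 0.0):
            raise ConfigurationError("need bcl > time_to_peak > 0")
        if self.activation_delay < 0.0:
            raise ConfigurationError("activation_delay must be >= 0")


@dataclass(frozen=True)
class MyofilamentParams:
    """Two-state cross-bridge scheme with Hill-type Ca activation.

    Attachment flux f_xb·H(Ca)·(1−xb) competes with ATP-consuming detachment
    g_xbT·xb; contractile ATP turnover is the detachment flux weighted by the
    single-overlap fraction of the thick filament (SOVF_Thick).
    """

    ca50: float = 0.5       # µM, half-activation
    hill_n: float = 4.0     # cooperativity
    f_xb: float = 0.016     # 1/ms, attachment rate
    g_xbT: float = 0.008    # 1/ms, ATP-consuming detachment rate
    sl_ref: float = 2.0     # µm, sarcomere length at reference volume
    # single-overlap trapezoid: zero outside [sl_zero_low, sl_zero_high],
    # full overlap on the plateau [sl_min_overlap, sl_max_overlap]
    sl_min_overlap: float = 2.0   # µm
    sl_max_overlap: float = 2.2   # µm
    sl_zero_low: float = 1.4      # µm
    sl_zero_high: float = 2.8     # µm

    def __post_init__(self) -> None:
        if min(self.f_xb, self.g_xbT, self.ca50) <= 0:
            raise ConfigurationError("rates and ca50 must be positive")
        if self.hill_n < 1:
            raise ConfigurationError("hill_n must be >= 1")
        if not (self.sl_zero_low < self.sl_min_overlap
                < self.sl_max_overlap < self.sl_zero_high):
            raise ConfigurationError("overlap lengths must be ordered")


@dataclass(frozen=True)
class VentricleParams:
    """Lumped constitutive law of one ventricle.

    Passive filling follows an exponential end-diastolic pressure-volume
    relation (scaled ``hf_stiffness_factor``-fold when failing); active
    pressure is a thin-walled-sphere Laplace term linear in normalised
    myofilament tension, with wall thickness from an incompressible shell of
    constant ``wall_volume``.
    """

    chamber: Literal["LV", "RV"] = "LV"
    v0: float = 20.0                 # mL, zero-pressure volume
    passive_scale: float = 0.087     # kPa
    passive_exponent: float = 0.03   # 1/mL
    hf_stiffness_factor: float = 5.0
    wall_volume: float = 100.0       # mL
    t_max: float = 78.0              # kPa, tension-to-wall-stress scale
    v_ref: float = 100.0             # mL, volume at which sl = sl_ref
    sl_wall_fraction: float = 0.0    # sl maps from V + frac·wall_volume

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.wall_volume <= 0 or self.v_ref <= 0:
            raise ConfigurationError("v0, wall_volume, v_ref must be positive")
        if self.t_max < 0:
            raise ConfigurationError("t_max must be >= 0")
        if self.hf_stiffness_factor < 1:
            raise ConfigurationError("hf_stiffness_factor must be >= 1")


@dataclass(frozen=True)
class ValveConfig:
    """Forward-diode plus leak-diode valve.

    ``leak_sf`` is the regurgitation severity in percent: the leak branch
    resistance is the forward resistance divided by leak_sf/100, so severity 0
    seals the valve and larger severities leak more.
    """

    which: Literal["mitral", "aortic"]
    r_forward: float         # kPa·s/mL
    leak_sf: float = 0.0     # percent, 0..100

    def __post_init__(self) -> None:
        if self.r_forward <= 0:
            raise ConfigurationError("r_forward must be positive")
        if not (0.0 <= self.leak_sf <= 100.0):
            raise ConfigurationError("leak_sf must be in [0, 100]")


@dataclass(frozen=True)
class IABPConfig:
    """Counterpulsation as harmonic modulation of systemic-artery compliance.

    C_SA,IABP(t) = C_SA·[(1−sf) + sf·cos(2πt/BCL − phase)]; the compliance
    floor is (1−2·sf)·C_SA, so sf is capped at 0.5 to keep it positive.
    """

    enabled: bool = False
    sf: float = 0.2        # scale-factor level
    phase: float = 3.66    # rad
    bcl: float = 600.0     # ms

    def __post_init__(self) -> None:
        if self.bcl <= 0:
            raise ConfigurationError("bcl must be positive")
        if self.enabled and not (0.0 < self.sf <= 0.5):
            raise ConfigurationError(
                "sf must lie in (0, 0.5] when the pump is enabled")


@dataclass(frozen=True)
class CircParams:
    """Resistances, compliances, atrial elastances and initial volumes of the
    eight-compartment closed loop (canine failing-heart parameter set)."""

    r_ao: float = 0.007      # kPa·s/mL, aortic valve impedance
    r_sa: float = 0.247      # systemic artery + capillary
    r_sv: float = 0.0514     # systemic venous return
    r_pv: float = 5.05e-3    # pulmonic venous return
    r_ap: float = 5.05e-3    # pulmonic artery + capillary
    r_pu: float = 0.004      # pulmonary valve impedance
    r_mi: float = 5e-4       # mitral valve
    r_tri: float = 5e-4      # tricuspid valve
    c_sa: float = 32.6       # mL/kPa
    c_sv: float = 433.0
    c_pv: float = 50.0
    c_pa: float = 41.7
    e_la_max: float = 0.0782  # kPa/mL
    e_la_min: float = 0.0711
    e_ra_max: float = 0.03
    e_ra_min: float = 0.0273
    # atrial activation: half-sine of atrial_duration starting atrial_onset
    # into the cycle (atrial kick just before ventricular activation at wrap)
    atrial_onset: float = 480.0     # ms
    atrial_duration: float = 120.0  # ms
    initial_volumes: tuple[float, ...] = (
        28.9575,   # LA
        49.7366,   # LV
        114.629,   # SA
        1427.75,   # SV
        29.8093,   # RA
        37.8823,   # RV
        73.3862,   # PA
        79.9216,   # PV
    )

    def __post_init__(self) -> None:
        positive = (self.r_ao, self.r_sa, self.r_sv, self.r_pv, self.r_ap,
                    self.r_pu, self.r_mi, self.r_tri, self.c_sa, self.c_sv,
                    self.c_pv, self.c_pa, self.e_la_max, self.e_la_min,
                    self.e_ra_max, self.e_ra_min)
        if any(x <= 0 for x in positive):
            raise ConfigurationError(
                "resistances, compliances and elastances must be positive")
        if self.e_la_max < self.e_la_min or self.e_ra_max < self.e_ra_min:
            raise ConfigurationError("atrial e_max must be >= e_min")
        if len(self.initial_volumes) != len(COMPARTMENTS):
            raise ConfigurationError("need one initial volume per compartment")

    @property
    def total_volume(self) -> float:
        return float(sum(self.initial_volumes))


def default_rv_params() -> VentricleParams:
    """RV constitutive defaults: thinner wall and lower wall-stress scale than
    the LV, giving a physiological RV/LV systolic pressure ratio."""
    lv = VentricleParams(chamber="LV")
    return replace(lv, chamber="RV", t_max=0.35 * lv.t_max,
                   wall_volume=0.5 * lv.wall_volume, v0=18.0, v_ref=92.0,
                   passive_scale=0.8 * lv.passive_scale)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter bundle for one simulation."""

    circ: CircParams = field(default_factory=CircParams)
    lv: VentricleParams = field(default_factory=VentricleParams)
    rv: VentricleParams = field(default_factory=default_rv_params)
    myo: MyofilamentParams = field(default_factory=MyofilamentParams)
    ca: CaTransientConfig = field(default_factory=CaTransientConfig)
    failing: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    """Protocol settings for a single run."""

    bcl: float = 600.0          # ms
    duration: float = 20000.0   # ms
    condition: Literal["none", "AR", "MR"] = "none"
    severity: float = 0.0       # percent leak
    iabp: IABPConfig = field(default_factory=IABPConfig)
    rtol: float = 1e-7
    atol: float = 1e-7
    sample_dt: float = 1.0      # ms, output grid
    seed: int = 0               # kept for optional perturbation studies

    def __post_init__(self) -> None:
        if self.duration < 2 * self.bcl:
            raise ConfigurationError("duration must cover at least two beats")
        if self.condition not in ("none", "AR", "MR"):
            raise ConfigurationError("condition must be none, AR or MR")
        if not (0.0 <= self.severity <= 100.0):
            raise ConfigurationError("severity must be in [0, 100]")
        if self.condition == "none" and self.severity != 0.0:
            raise ConfigurationError("condition 'none' implies severity 0")


def to_dict(params: ModelParams) -> dict:
    d = asdict(params)
    d["circ"]["initial_volumes"] = list(params.circ.initial_volumes)
    return d


def save_yaml(params: ModelParams, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False)


def load_yaml(path: str) -> ModelParams:
    """Load a full parameter bundle from a YAML file written by save_yaml
    (missing sections fall back to the packaged defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    circ_raw = dict(raw.get("circ", {}))
    if "initial_volumes" in circ_raw:
        circ_raw["initial_volumes"] = tuple(circ_raw["initial_volumes"])
    return ModelParams(
        circ=CircParams(**circ_raw),
        lv=VentricleParams(**raw.get("lv", {})),
        rv=VentricleParams(**raw.get("rv", {})) if "rv" in raw
        else default_rv_params(),
        myo=MyofilamentParams(**raw.get("myo", {})),
        ca=CaTransientConfig(**raw.get("ca", {})),
        failing=bool(raw.get("failing", True)),
    )
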