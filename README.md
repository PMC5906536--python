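# counterpulse

Closed-loop, zero-dimensional hemodynamics of **intra-aortic balloon pump
(IABP) therapy** in the failing heart under **aortic (AR) and mitral (MR)
valve regurgitation** — for cardiovascular modellers who want the
counterpulsation/regurgitation interaction, including its energetic cost,
without a 3D electromechanical stack.

The IABP is clinically contraindicated in significant AR: diastolic balloon
inflation, which normally boosts coronary perfusion pressure and unloads the
ventricle, instead drives blood backwards through the incompetent aortic
valve. This package reproduces that mechanism in a lumped model and
quantifies it through pressure–volume loops, stroke work, regurgitant
volumes, and contractile ATP consumption.

## Model

An eight-compartment closed loop (LA → LV → systemic arteries → veins →
RA → RV → pulmonary arteries → veins), volume-conserving with Ohmic flows
`Q = ΔP/R`. Atria are time-varying elastances `P = E(t)·V`; vessels are
windkessels `P = V/C`; the ventricles are a constitutive surrogate —
exponential passive filling (5× stiffened in heart failure) plus a
thin-walled-sphere Laplace active term driven by a two-state cross-bridge
model with Hill-type Ca²⁺ activation:

    dxb/dt = f_xb·H(Ca)·(1 − xb) − g_xbT·xb,   H(Ca) = Ca^n/(Ca^n + Ca50^n)

A synthetic periodic Ca²⁺ transient (peak scaled to 70% of healthy in the
failing phenotype) drives contraction. Leaky valves follow a forward/leak
diode pair, the leak resistance scaled by the severity `SF` in percent.
The pump is a harmonic modulation of systemic arterial compliance,

    C_SA,IABP(t) = C_SA·[(1 − sf) + sf·cos(2πt/BCL − φ)],

inflating (compliance floor `1 − 2·sf`) in diastole and deflating in
systole. Contractile energetics follow the cross-bridge detachment flux:
ATP rate = `g_xbT · SOVF_Thick(sl) · xb`, with `SOVF_Thick` the
sarcomere-length-dependent single-overlap fraction. See
[docs/methods.md](docs/methods.md) for the full formulation, units and
calibration.

## Worked example

```python
from counterpulse import IABPConfig, SimulationConfig, run, compute_beat_metrics

for pump in (False, True):
    cfg = SimulationConfig(condition="AR", severity=10.0,
                           iabp=IABPConfig(enabled=pump))
    res = run(cfg)                      # 20 s, 33 beats, steady by design
    m = compute_beat_metrics(res.final_beat)
    print(f"pump={pump}: EDV {m.edv:.1f} mL  ESV {m.esv:.1f} mL  "
          f"regurg {m.regurgitant_volume:.1f} mL  "
          f"stroke work {m.stroke_work:.0f} mL*kPa  ATP {m.atp_per_beat:.1f}")
```

prints

```
pump=False: EDV 75.0 mL  ESV 43.0 mL  regurg 19.9 mL  stroke work 230 mL*kPa  ATP 30.4
pump=True: EDV 76.2 mL  ESV 41.5 mL  regurg 22.8 mL  stroke work 202 mL*kPa  ATP 29.1
```

Under 10% AR the pump *increases* the regurgitant volume (19.9 → 22.8 mL)
and widens the PV loop (EDV up, ESV down) — the ventricular-distension
problem behind the clinical contraindication — even as it lowers stroke
work and ATP use. Under MR the same pump *decreases* regurgitation.

The full study is driven by the numbered scripts:

```bash
python analysis/01_compliance_profiles.py   # pump compliance family, sf 0.05..0.30
python analysis/02_baseline_steady_state.py # convergence + counterpulsation signature
python analysis/03_protocol_grid.py         # 22-cell grid -> results/grid_metrics.csv
python analysis/04_iabp_effects.py          # paired pump effects and ATP ordering
```

or interactively via the CLI (`counterpulse simulate|grid|profiles|report`,
with `--config` for a YAML parameter file; `counterpulse write-config`
exports the packaged defaults).

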