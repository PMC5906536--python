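# Methods

`counterpulse` is a zero-dimensional (lumped-parameter) model of intra-aortic
balloon pump (IABP) therapy in a failing canine heart with aortic (AR) or
mitral (MR) valve regurgitation. It reduces a multiscale electromechanical
description to the minimal closed-loop system that still expresses the
interplay the problem turns on: counterpulsation timing, leaky-valve flow,
Frank–Starling length dependence, and cross-bridge ATP turnover.

## The closed loop

Eight compartments form a single ring — left atrium (LA), left ventricle
(LV), systemic arteries (SA), systemic veins (SV), right atrium (RA), right
ventricle (RV), pulmonary arteries (PA), pulmonary veins (PV) — exchanging
volume through Ohmic segments, `Q = ΔP/R`. The state is the eight volumes
plus two cross-bridge occupancies; dynamics are pure volume conservation
(`dV/dt = inflow − outflow`), so total blood volume (1842.07 mL, the sum of
the tabulated initial volumes) is invariant to solver precision.

Compartment pressures:

- windkessel vessels: `P = V/C` with fixed compliances for SV, PA, PV and a
  pump-modulated compliance for SA;
- atria: time-varying elastance `P = E(t)·V`, with `E(t)` sweeping a
  half-sine between the tabulated minimum and maximum. The activation window
  (120 ms starting 480 ms into the 600 ms cycle — an atrial kick just before
  ventricular activation at the cycle wrap) is this model's choice; only the
  elastance bounds are tabulated data;
- ventricles: the constitutive surrogate below.

Mitral and aortic valves are static forward/leak diode pairs: forward flow
`(P_up − P_down)/R` when the gradient is positive, otherwise a leak flow
scaled by `SF/100` where `SF` is the regurgitation severity in percent
(severity 0 seals the valve; both branches vanish at equal pressures, so the
flow law is continuous). Tricuspid and pulmonary valves are ideal diodes.
Units are kPa, mL, ms internally (flows in mL/s; resistances in kPa·s/mL);
pressures are also reported in mmHg (×7.50062).

## Balloon pump

Balloon inflation occupies aortic volume, which a 0D network sees as reduced
effective arterial compliance:

    C_SA,IABP(t) = C_SA · [(1 − sf) + sf·cos(2πt/BCL − φ)]

with `sf = 0.2` (compliance floor 60% of baseline) and `φ = 3.66` rad at
BCL = 600 ms. The cosine is referenced to a pump clock offset half a cycle
from the ventricular-activation clock; under that convention the stated
phase places the compliance minimum (inflation) 350 ms after end-diastole —
mid-diastole — and the maximum (deflation) in systole. This is the timing
that produces counterpulsation (diastolic arterial augmentation, systolic
unloading); evaluating the same cosine directly on the activation clock
would invert it and turn the pump into an afterload amplifier. `sf` is
capped at 0.5 so compliance stays positive; the protocol uses ≤ 0.3.

## Ventricular surrogate

Chamber pressure is passive + active:

- Passive: `P_pas = k·S·(exp(E·(V − V₀)) − 1)`, with `k = 5` in the failing
  phenotype (the 5× stiffening of the passive scaling constant); below `V₀`
  the same form scaled ×0.1 gives a gentle suction branch.
- Active: thin-walled-sphere Laplace law `P_act = 2·σ·h/r` with wall stress
  `σ = T_max · tension`, cavity radius `r = (3V/4π)^{1/3}`, and thickness `h`
  from an incompressible shell of fixed wall volume.

Sarcomere length maps from cavity volume as `sl = sl_ref·(V/V_ref)^{1/3}`
(an optional wall-volume offset moves the mapping to the midwall radius;
the shipped default uses the cavity form). The RV uses the same law with
`T_max` ×0.35 and wall volume ×0.5 — a physiological RV/LV pressure ratio;
no RV constitutive data exist to fit.

A note on monotonicity: the Laplace factor `h/r` falls with volume, so at a
*fixed* tension the active pressure always has a negative slope that, at
high tension and small volume, no physiologic passive curve can overcome.
The meaningful stiffness statement — tested as such — is monotonicity at
fixed cross-bridge occupancy with length-dependent recruitment
(`tension = xb·SOVF(sl(V))`): along that curve total pressure rises with
volume throughout the traversed operating envelope (ascending overlap limb;
at near-maximal occupancy, volumes past the overlap plateau would dip before
the exponential passive curve takes over, but such states are never reached
in the protocol).

## Calcium drive and cross-bridge model

A single representative Ca²⁺ transient per cycle stands in for the spatial
output of a 3D electrophysiology model: raised-half-sine upstroke (50 ms to
peak), exponential relaxation (τ = 150 ms) renormalised to return exactly to
the diastolic level at the cycle end (continuous and exactly periodic);
diastolic 0.1 µM, healthy peak 1.1 µM. Heart failure scales the peak
amplitude to 70% of healthy. A configurable activation delay exists but
defaults to zero; the conduction slowing of the failing heart has no
meaningful 0D analogue and is not emulated.

Contraction is a two-state cross-bridge scheme with cooperative activation:

    H(Ca)   = Ca^n / (Ca^n + Ca50^n),            Ca50 = 0.5 µM, n = 4
    dxb/dt  = f_xb·H(Ca)·(1 − xb) − g_xbT·xb

Normalised tension is `xb·SOVF_Thick(sl)`, where `SOVF_Thick` is the
single-overlap fraction of the thick filament: a symmetric trapezoid with
plateau 2.0–2.2 µm, zero at 1.4 and 2.8 µm. Contractile ATP consumption per
unit wall volume is the ATP-consuming detachment flux weighted by overlap:

    ATP rate = g_xbT · SOVF_Thick(sl) · xb

The occupancy factor is a deliberate physical completion of the bare product
`g_xbT·SOVF_Thick` (to which it reduces at occupancy 1): detachment can only
consume ATP where bridges are attached. Only contractile ATP is counted — no
SERCA/PMCA/Na-pump terms — and `g_xbT` has no published value here, so all
energetic endpoints are meaningful in absolute model units only as ratios
between conditions, which is how they are reported.

## Calibration

The surrogate's free constants were fixed once, by a documented sweep,
against hemodynamic plausibility targets only: the failing baseline should
sit at canine scale (EDV/ESV of tens of mL; the tabulated initial LV volume
is ~50 mL) with LV peak pressure ~10–13 kPa. The shipped defaults —
`V₀ = 20 mL`, `S = 0.087 kPa`, `E = 0.03 /mL`, wall volume 100 mL,
`T_max = 78 kPa`, `V_ref = 100 mL`, `f_xb = 0.016 /ms`, `g_xbT = 0.008 /ms`
— give a baseline failing heart of EDV 61 mL, ESV 45 mL, EF 0.26, LV peak
11.1 kPa (83 mmHg).

Two calibration choices carry scientific weight:

- `V_ref = 100 mL` keeps the whole operating volume range on the *ascending*
  limb of the overlap function. With a smaller reference volume the
  end-diastolic volumes of the regurgitant conditions map past the plateau
  onto the descending limb, inverting Frank–Starling exactly where the AR
  mechanism (pump-driven diastolic backfill → higher EDV → more tension and
  ATP) depends on it.
- Cross-bridge rates of order 0.01/ms make tension build over ~100 ms, so
  ejection spreads through mid-systole. With much faster kinetics ejection
  completes before the occupancy peak, the ATP integral is then dominated by
  end-systolic volume, and the pump's energetic effect degenerates to pure
  ESV unloading — identical across conditions and unable to express the
  preload-mediated ordering of the three conditions.

## Protocol and numerics

Each run integrates 20 s (33 beats) at BCL 600 ms from the tabulated initial
volumes and zero occupancy, with LSODA (rtol = atol = 1e−7, max step 2 ms —
the diode kinks are handled by step control, without event detection), and
1 ms output sampling. The final activation-aligned beat supplies the
endpoints; "steady state" is defined here as < 1% beat-to-beat change in
EDV (the baseline converges to ~0.1%/beat). The study grid is baseline plus
{AR, MR} × {2, 4, 6, 8, 10%} × {pump off, on} = 22 cells (~1 s per cell).
The pipeline is deterministic; the seed parameter exists only for optional
perturbation studies. Halving solver tolerances moves final-beat EDV/ESV/SV
by < 0.1%.

Per-beat endpoints: EDV/ESV are the extrema of the LV volume trace;
*practical* stroke volume is the net aortic-flow integral (equal to
EDV − ESV only without leaks); EF = practical SV / EDV; regurgitant volume
is the backward-flow integral of the leaking valve, and the regurgitant
fraction divides it by itself plus the forward aortic volume; stroke work is
the signed shoelace area of the LV pressure–volume loop (positive
counter-clockwise); ATP per beat integrates the rate above over the beat,
scaled by wall volume.

## What the model reproduces, and what it does not

With the pump on, the model reproduces, cell by cell across the grid: the
counterpulsation pressure signature; reduced LV stroke work in every
condition and severity; increased aortic but decreased mitral regurgitant
volume; the horizontally widened AR pressure–volume loop (EDV up, ESV down);
rising arterial pulse pressure with AR severity; and pump ATP savings
ordered no-regurgitation > MR > AR, all positive (the computed reductions
are ~11.3%, ~5.2% and ~4.5%; `scripts/acceptance.py` recomputes them).

The MR magnitude is the known structural shortfall of this reduction: in a
full myofilament treatment the pump's benefit under MR acts partly through
load- and velocity-dependent detachment, pathways a volume-only ATP
surrogate cannot see; here the MR cell's volumes barely move with the pump,
so its reduction saturates near the AR level instead of sitting well above
it. Relatedly, ATP rises with severity strictly under AR but
shows a shallow dip at mild MR, and MR ATP sits below baseline (pressure
unloading with a downward-widened loop), where the 3D model has
regurgitation raising ATP in both conditions. Coronary circulation, valve
inertia and leaflet dynamics, baroreflexes, and all spatial
(transmural/regional) quantities are out of scope; the synthetic Ca²⁺
transient has no beat-to-beat variability, alternans, or spatial
heterogeneity, so passing tests say nothing about those features of real
data.
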