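# Methods

## Model structure

The simulator couples three stages.

**Gastro-duodenal stage (discrete-event continuous system).** Between
events the stomach obeys `dVs/dt = Qgj` and
`d(Vs·Cs)/dt = ksd (Ss − Cs)` while the tablet radius follows
`drp/dt = −4πρ rp² ksd (Ss − Cs)`; the duodenum obeys `dVd/dt = Qpj`
with constant drug mass. At every multiple of the emptying period `Te`
an instantaneous event fires in a fixed order: the duodenum discharges
its entire content as a bolus, the stomach keeps `1 − f` of its volume
(`f = 1/20`), and the duodenum refills with `f·Vs` at the gastric
concentration, which is continuous across the event. The event is a state
jump rather than a 1 s flow pulse; the post-event states are identical and
a stiff transient is avoided. The single oral administration enters as the
initial condition (full dose in the tablet, `Cs(0) = 0`, `Vd(0) = 0`), so
the meal inflow is zero throughout and the first event emits nothing when
pancreatic secretion is off.

**Dissolution bookkeeping.** The radius ODE and the solution source term
are written as published and are not exact mass complements of each other.
Both run in parallel; dissolution terminates when the cumulative dissolved
mass reaches the dose (hard cap, logged on the result as
`dissolution_capped`) or the radius reaches zero. Since `drp/dt ∝ −rp²`
gives hyperbolic decay, the radius never reaches zero in finite time and
the cap is the operative stop. Supersaturation cannot arise from the
dynamics; the radius rate is nevertheless clamped at zero defensively.

**Units.** Internal computations use mg, L, s, m. Fixture solubilities
(mol/L) are converted to mg/L through the per-drug molar mass at load
time; the density enters the dissolution formulas in g/mL exactly as
tabulated. The dissolution relations are dimensionally implicit; evaluated
in this unit system the solution source `ksd(Ss − Cs)` lands in mg/s with
dissolution timescales of minutes to hours for the packaged drugs, which
is the physiologically sensible reading. The molar mass is the one field
the upstream parameter set does not contain; the fit is insensitive to it
because the objective normalizes both curves by their maxima.

**Intestinal stage.** Bolus positions are purely kinematic
(`x = u (t − t_entry)`; a bolus deactivates at `x ≥ Lj + Li + Lc`, its
residual drug mass recorded as excreted). The countercurrent blood chain
is algebraic and is solved by forward recursion inside the ODE right-hand
side, making the coupled system an explicit delay-ODE in the bolus
concentrations and the peripheral concentration. The chain contacts the
most distal (oldest) bolus first, matching countercurrent flow; a
`chain_order="proximal-first"` switch exists for sensitivity analysis and
changes the output by well under a percent at physiological transfer
ratios (K ≈ 10⁻⁴). The absorption coefficient α is re-evaluated at the
bolus's current position at every step (`alpha_mode="moving"`); an
`"entry"` mode freezing α at the inlet value is provided for comparison.
The ileum–colon Cauchy peak is placed in the segment-local coordinate
(1.5 m past the jejunum outlet): a global 1.5 m would fall inside the
jejunum, whereas the tail of the ileum–colon profile is meant to cover the
colon. The truncated Cauchy profile is used verbatim, without
renormalization over the finite segment.

**Capacity.** The maximum simultaneous bolus counts are
`Nmax_ic = ⌊(Li+Lc)·fe/u⌋ = 33` and `Nmax = ⌊(Lj+Li+Lc)·fe/u⌋ = 45` at
defaults (count = segment length divided by the inter-bolus spacing
`u/fe`; a 1e-9 tolerance inside the floor absorbs exact-integer ratios).
With the default physiology the emission cadence and transit time make
overflow impossible (45 × 600 s is exactly the 27000 s transit); denser
user-supplied emission trains retire the oldest bolus early, with a
warning, its residual mass logged as excreted.

**Peripheral delay.** The peripheral history is stored on the integration
grid and interpolated linearly at `t − δ`; the step is capped at `δ/3`, so
the needed history always predates the current step. `δ = 0` disables the
delay (the current state value is used), which is the configuration the
dense-ODE cross-check runs in.

## Numerical scheme

The gastro-duodenal stage is integrated event-to-event with LSODA
(rtol 1e-8, atol 1e-12) and terminal events for the dissolution cap. The
intestinal stage uses a fixed-step classical RK4 kernel whose step divides
`Te` (default 10 s, further capped at `δ/3` and at `1/α_max` for
stability), so boluses enter and leave exactly on step boundaries and the
active set is frozen within a step. The kernel is written as plain loops
and jitted with numba; a pure-Python fallback runs when numba is absent.
Against an independently coded dense-ODE reference (single bolus, zero
delay, LSODA at rtol 1e-11) the kernel agrees to ~2.5e-9 relative at a
1 s step. The per-contact flux identity — blood gain
`π rbol²(u+vb)(Cb^i − Cb^{i−1})` equals bolus loss `Vbol α_i (C_i − Cb^{i−1})`
— holds by construction of K and is asserted numerically each step when
`audit=True` (observed residual ≈ 5e-16).

## Estimation

`fit_parameters` minimizes the normalized residuals with
`scipy.optimize.least_squares` (trf) in log10-parameter space, bounds
λ ∈ [1e-4, 500] on the tabulated scale and kd ∈ [1e-7, 1e-3] 1/s
(spanning all published fits with wide margins), from `n_starts = 8`
log-uniform starts drawn from the given seed. The landscape has genuine
local minima — in recovery experiments a minority of starts terminate at
φ ≈ 1e-6 with a wrong λic while the global minimum is φ = 0 — which is why
the multistart count defaults to 8; results are deterministic for a fixed
seed. The gastro-duodenal emission train does not depend on the fitted
parameters and is computed once per fit. Simulated curves are interpolated
to the observation instants by monotone cubic (PCHIP) interpolation, and
the normalization maxima are taken over those instants, not the dense
grid. Ordinary (unweighted) least squares is used deliberately; it weights
the peak region most and is the match for peak-time-focused screening.

## Synthetic observations

The generator runs the forward model at known "true" parameters and
multiplies each sample by `1 + ε`, `ε ~ N(0, cv)` clamped at zero —
assay error in plasma concentration measurements scales with
concentration, hence multiplicative rather than additive noise
(default cv = 0.05). Sampling follows a typical clinical schedule
(0.5–24 h, denser early). Doses use the published values where stated
(80/125 mg aprepitant, 200–800 mg ketokenazole, 125 mg griseofulvin) and
a 100 mg default elsewhere. What the generator does *not* emulate:
inter-subject variability, absorption-window or food effects, first-pass
extraction, and assay detection limits. Passing recovery tests therefore
demonstrates identifiability and optimizer correctness under the model's
own dynamics, not fidelity to any particular clinical dataset.

## Problem sizes and defaults

Forward simulations run 24 h at a 10 s internal step and 60 s output
sampling (~0.1 s warm); the recovery study uses five random truths drawn
from λ ∈ [1, ~32], kd ∈ [1e-5, 2e-4] 1/s — the magnitude range of the
published fits — observed noise-free at 15 instants over 24 h. The
gastric pH defaults to 2.0 (fasted), the initial stomach volume to 1 L
(meal plus water), secretion rates to `Qgj = 2.3e-5` L/s (~2 L/day) and
`Qpj = 1.2e-5` L/s (~1 L/day); all are configurable, and setting the
secretions to zero recovers a pure-emptying stomach whose volume decays
exactly geometrically (19/20 per event, below 1% of the initial volume
after 90 events).

## Known limitations

- The acid-form Henderson–Hasselbalch correction is applied to every
  drug, including bases, as published upstream.
- The splanchnic-to-peripheral coupling uses the bulk flow `Qb` while the
  per-contact exchange uses the contact flow `π rbol²(u+vb)`; the two
  differ, so bolus-side and peripheral-side mass ledgers are tracked
  separately rather than forced into a single closed balance.
- One published parameter triple (irbesartan) has no physicochemical
  record in the upstream tables; it is available from `table4_fixture`
  but cannot be forward-simulated without user-supplied drug properties.
- No hepatic first pass, upper-GI absorption, food composition effects,
  or population variability.
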