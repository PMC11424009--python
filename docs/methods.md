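# Methods

## Scope and model

`gaitmet` estimates the metabolic energetics of walking from one leg's gait
mechanics.  Its pipeline has four stages:

1. **Muscle-tendon states.** Joint kinematics, inverse-dynamics moments,
   muscle-tendon lengths, and moment arms are prescribed; muscle excitations
   and states are found by solving the muscle redundancy problem as an
   optimal control problem (OCP) over one gait cycle.
2. **Metabolic rates.** Six published metabolic energy models map the
   states to per-muscle rate trajectories
   `Edot = Wdot_CE + Hdot_A + Hdot_M + Hdot_SL`.
3. **Aggregation.** Rates are integrated over the cycle, doubled for two
   legs, normalized by body mass and offset by a basal rate; biarticular
   muscles' rates are split across joints by the instantaneous
   absolute-moment-arm ratio; stance/swing shares use the contact and
   toe-off events.
4. **Statistics.** Repeated-measures correlation, 1-D sign-flip permutation
   tests on time-normalized curves, Wilcoxon signed-rank, and rmse/Pearson
   agreement metrics.

### Muscle-tendon mechanics

Each actuator is a Hill-type fiber in series with an elastic tendon.
Normalized curves: a three-Gaussian active force-length curve (first
Gaussian center nudged by −0.01 so the summed curve peaks at normalized
length 1), a log-hyperbolic force-velocity curve affinely renormalized so
`f_v(0) = 1` and `f_v(−1) = 0` exactly, the exponential passive curve
`f_pas = (exp(k_pe (l − s0)/s_m) − 1)/(exp(k_pe) − 1)` (clamped at zero
below onset in the public API; used unclamped inside the OCP, where the
small negative tail keeps the algebra smooth), and an exponential tendon
curve `f_t = c1 exp(k_t (l_T − c2)) − c3` whose personalized variants are
shifted so the value at slack-normalized length 1 is unchanged.  Pennation
follows the fixed-height assumption.  A damping term (0.01 of maximum
isometric force per unit of maximum shortening velocity) regularizes the
fiber-tendon equilibrium.

Defaults: `k_pe = 4`, `s0 = 1`, `s_m = 0.6`, generic `k_t = 35`,
activation/deactivation time constants 15/60 ms (smooth tanh blend),
`vmax = 10 l_opt/s`.

### Redundancy OCP

Transcription is backward-Euler direct collocation on a uniform mesh
(default 50 intervals; 30 in the shipped experiments — chosen as the
package's desk-scale study size after checking mesh-refinement stability).
States are activations and normalized fiber lengths; controls are
excitations, normalized fiber velocities (implicit contraction dynamics),
and per-dof reserve moments.  Constraints: fiber-tendon force equilibrium,
activation and fiber-length dynamics, per-dof moment balance
`sum(r F_T) + tau_res = tau_ID`, and periodic states.  The objective is the
integral of summed squared activations plus `w_res = 1000` times squared
reserves normalized by each dof's peak moment, plus a tiny velocity
regularizer (1e-4).  The NLP is solved by `scipy.optimize.minimize`
(trust-constr) with analytic sparse constraint Jacobians, a constant sparse
objective Hessian, and a zero constraint-Hessian (Gauss-Newton model);
initialization is a deterministic rigid-tendon static-optimization warm
start followed by per-node compliant-equilibrium solves.  A run is accepted
when the maximum constraint violation is below 1e-6; the objective tail
beyond ~300 iterations changes by under half a percent, so the iteration
cap defaults to 300.

Workflows: **GEN**/**PAS** are minimal-effort (they differ only in the
passive parameters supplied), **TEN** adds one tendon-stiffness factor per
named tendon group (Achilles: soleus+gastrocnemius; quadriceps:
vasti+rectus femoris; bounds 15–45) shared across all supplied cycles, and
**EMG** constrains tracked excitations to a hard ±0.01 corridor around
gain-scaled envelopes, with one free gain per channel (bounds 0.05–5)
shared across cycles.  In the EMG workflow the activation-effort term is
weighted at 0.01: tracking fidelity and moment balance then dominate, which
is what makes the tendon-stiffness identification consistent — with equal
weighting, the effort term exploits the corridor/gain slack and biases the
recovered stiffness upward.  The two objective terms being deliberately
unequal is part of the workflow's design.

### Metabolic energy models

`UM03`, `UM10`, `UC16` share the mass-specific Umberger-family structure:
combined activation+maintenance heat `(128 f_fast + 25) A^0.6` W/kg (scaled
by `0.4 + 0.6 f_l` above optimal length), shortening heat coefficients
`alpha_S(slow) = 100 / vmax_slow` (with `vmax_slow = vmax/2.5`) and
`alpha_S(fast) = 153 / vmax` applied with `A^2`, lengthening coefficient
`4 alpha_S(slow)` with `A^1`, and an aerobic scale of 1.5.  `UM10` counts
only concentric contractile work and zeroes the lengthening heat; `UC16`
keeps full work accounting but replaces the fixed fiber-type ratio with an
orderly-recruitment ramp and clamps the total rate at zero.  `BH04` uses
separate activation (40/133 W/kg) and maintenance (74/111 W/kg) heats with
sin/(1−cos) recruitment curves, a piecewise fiber-length scaling, and
force-based shortening/lengthening heat (0.16 F_iso + 0.18 F_CE
shortening, 0.157 F_CE lengthening — negative during lengthening, as in
the original formulation).  `LW07` is mass-free, with heats in units of
`F_max l_opt`: maintenance `0.06 a f_l vmax`, shortening heat
`0.25 F_iso |v|`, and half of eccentric contractile work dissipated as
heat (so net negative rates are a model output).  `HO06` is this package's
Hill-initial-heat style transcription — maintenance `66 a f_l (vmax/10)`
W/kg, shortening heat `0.16 F_iso |v|`, zero eccentric heat — all
coefficients isolated in `data/metabolic_constants.yaml` so they can be
audited or swapped.

A heat floor of 1 W/kg (Umberger family and BH04; folded into the
maintenance term so the four-component decomposition stays exact) keeps
resting muscle from being energetically free.  Wherever the total rate of
BH04, HO06, or UM03 would be negative, the shortening/lengthening heat is
replaced by `−Wdot_CE − Hdot_AM`, forcing the total to zero; UC16's clamp
uses the same mechanism.  The contractile work rate uses the contractile
element force only (`a f_l f_v F_max`), positive during shortening.

Note on scaling: the Umberger-family heats are mass-specific throughout
(doubling muscle mass doubles them); BH04/HO06 activation and maintenance
heats scale with mass, while their shortening/lengthening heats scale with
force (hence with `F_max`), as in the original formulations.

The qualitative orderings of the six models (shortening
LW07 > BH04 > HO06 > UC16 with UM03 = UM10; isometric LW07 > BH04 >
UM03 = UM10 > UC16 > HO06; lengthening zero except UM10 positive and LW07
negative) are asserted at submaximal activations 0.25/0.5/0.75: at full
activation UC16's recruitment ramp coincides with UM03's fixed ratio by
construction, so the strict UC16 < UM03 separation is a submaximal
property.

### Aggregation

Brockway coefficients 16.58 and 4.51 J/mL (configurable), basal rate
1.2 W/kg (configurable), trapezoidal time integration, whole-body rate
`(2 / T / m) * integral(sum Edot) + basal`.  Representative gas-exchange
values average the final 3 minutes of a trial.  Biarticular attribution
uses instantaneous absolute moment arms with a cycle-average fallback
(flagged) where all spanned arms vanish.  Maximum isometric forces come
from the whole-limb volume regression `V[cm^3] = 47 (m h) + 1285`,
per-muscle volume fractions, PCSA = volume / optimal fiber length, a
specific tension of 35 N/cm^2, and muscle density 1059.7 kg/m^3.

### Statistics

`rmcorr` computes the common within-subject slope from within-subject
centered sums (identical to the ANCOVA with a subject factor), with
`df = N_obs − N_subjects − 1`; subjects with one observation are dropped
with a warning.  `snpm_paired_1d` forms the pointwise paired t-curve,
builds the null by sign-flipping subject difference curves (full
enumeration when `2^n ≤ 4096`, else 10,000 seeded draws), takes the
family-wise threshold from the (1−α) quantile of the maximum |t|
distribution, and assigns cluster p-values from the max-cluster-extent
distribution.  Curve statistics resample to 101 points (0–100% cycle) by
linear interpolation.  Wilcoxon signed-rank delegates to scipy (exact for
n ≤ 12, zero differences dropped).

## Synthetic subject

The generator emulates the data streams of a gait-lab + spiroergometry
experiment on a virtual subject (default 71.3 kg, 1.74 m): three sagittal
dofs (hip, knee, ankle), nine lumped muscle-tendon units including the
biarticular hamstrings, rectus femoris, and gastrocnemius.  Moment arms are
per-dof linear polynomials with seeded ±10–15% jitter; muscle-tendon length
is constructed as the negative integral of the arms, so arm = −∂l/∂q holds
exactly.  Kinematics are truncated Fourier templates whose amplitude and
cycle duration scale with walking speed (0.5–2.2 m/s); toe-off sits near
60% of the cycle at 1.25 m/s and shifts earlier at faster speeds.
Ground-truth excitations are smooth periodic bump trains with
physiologically placed bursts; activations follow the activation ODE; fiber
states are computed on the equilibrium manifold by a velocity-consistent
fixed point (per-node equilibrium solves iterated with finite-difference
velocity estimates — the lightly damped fiber ODE is numerically stiff, and
at gait time scales the fiber tracks its equilibrium).  Joint moments are
then computed forward from the tendon forces, so the redundancy truth has
zero reserves by construction.  In `minimal` mode the trial is re-solved
with the minimal-effort OCP and the solution becomes the stored truth,
guaranteeing that recovery experiments have a recoverable target.

EMG envelopes are gain-scaled copies of the true excitations (gains
log-uniform in [0.3, 3], drawn per subject so they are shared across a
subject's trials) plus smoothed additive noise; the EMG processing chain is
a zero-lag 4th-order Butterworth band-pass (20–400 Hz), full-wave
rectification, and a 6 Hz zero-lag low-pass.  Gas exchange is breath-by-
breath VO2/VCO2 at a fixed respiratory exchange ratio of 0.85 whose
noiseless Brockway power equals the prescribed whole-body rate exactly.

What the generator does **not** emulate: soft-tissue artifact and marker
noise, non-sagittal dofs (hip ab/adduction and rotation groups are absent,
so group-share numbers are not comparable to studies with frontal-plane
muscles), fatigue or history dependence, EMG crosstalk, and breath-by-
breath physiological drift.  Passing recovery tests therefore shows the
estimators are consistent under the model's own assumptions, not that the
pipeline is robust to real-world artifacts.

## Study sizes in the shipped experiments

Tests and the acceptance script use: 9 muscles × 3 dofs, 30 mesh intervals
per cycle, 301-sample trials, 3 trials (0.8/1.25/1.7 m/s) for
tendon-stiffness personalization, 25-point passive moment targets per
joint with 2% noise and 20 Monte-Carlo replicates, 1000-replicate null
simulations for rmcorr, and exhaustive sign-flip enumeration for the
permutation oracle at n = 5.  These sizes are the package's reference
desk-scale configuration; all are parameters.

## Numerical choices and edge cases

- Equilibrium root-finds are safeguarded Brent iterations with a widened
  fallback bracket; tolerance 1e-9 relative to `F_max`.
- The OCP accepts slightly negative raw tendon/passive multipliers (slack
  states) rather than clamping, keeping derivatives smooth; public curve
  evaluators clamp at zero.
- Zero-energy cycles return NaN phase shares (no defined split) rather
  than an error; zero-duration phases are an error.
- Reserve moments are reported against each dof's peak moment and flagged
  above 5%.
- Degenerate biarticular attribution instants (all arms < 1e-6 m) fall
  back to the cycle-average ratio and are flagged.
- All generator randomness derives from numpy Generators seeded per
  component (`(seed, stream)` tuples), so trials, envelopes, and gas series
  are reproducible bit-for-bit.

## Known limitations

- The OCP is a local solver on a nonconvex problem; the deterministic
  warm start makes runs reproducible but global optimality is not
  guaranteed.
- Backward-Euler collocation is first-order; mesh-refinement stability is
  tested, but very sharp force transients would need a finer mesh.
- Tendon-stiffness identification relies on the EMG corridor: with few
  tracked channels or noisy envelopes the stiffness of lightly loaded
  tendon groups (quadriceps in particular) is weakly identified.
- The HO06 coefficient block is a structural transcription, not a
  digit-for-digit copy of the original publication's table; its constants
  are isolated in the shipped YAML for auditability.
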