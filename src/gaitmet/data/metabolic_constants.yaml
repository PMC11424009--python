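# Coefficient sets of the six metabolic energy models.
#
# Every model computes  Edot = Wdot_CE + Hdot_A + Hdot_M + Hdot_SL  per
# muscle.  Units: mass-specific heat coefficients are W/kg of muscle;
# force-based heat coefficients are dimensionless multipliers of force times
# fiber velocity; velocity coefficients are per (optimal fiber length / s).
#
# Provenance notes (per coefficient block):
# - UM03/UM10: activation+maintenance 128*f_fast + 25 W/kg with A(t)^0.6
#   scaling, shortening coefficients alpha_S(slow) = 4*25 / vmax_slow and
#   alpha_S(fast) = 153 / vmax_fast (vmax_slow = vmax/2.5), lengthening
#   alpha_L = 4*alpha_S(slow), aerobic scale S = 1.5: the Umberger-family
#   treadmill-walking parameterization.
# - UC16: same family; orderly fiber recruitment replaces the fixed
#   fiber-type ratio and the total rate is clamped non-negative.
# - BH04: activation heat 40 (slow) / 133 (fast) W/kg, maintenance heat
#   74 (slow) / 111 (fast) W/kg with sin/(1-cos) recruitment curves and a
#   piecewise fiber-length scaling; shortening heat 0.16*F_iso + 0.18*F_CE,
#   lengthening 0.157*F_CE (with the sign convention that makes eccentric
#   heat negative, as in the original).
# - LW07: mass-free Hill-type heat in units of F_max*l_opt: maintenance
#   coefficient per unit vmax, shortening heat coefficient (Hill a/P0-like),
#   and the half-of-eccentric-work-dissipated-as-heat rule.
# - HO06: Hill-initial-heat style transcription chosen for this package (the
#   original's full coefficient table is in its source publication);
#   maintenance 66 W/kg at full activation and vmax = 10 l_opt/s, shortening
#   heat 0.16 * F_iso * shortening velocity, zero eccentric heat.
#
# heat_floor: minimum total heat rate (W/kg of muscle), applied before the
# negative-rate modification; 0 disables it.

UM03:
  family: umberger
  combined_activation_maintenance: true
  mass_dependent: true
  h_am_fast: 128.0        # W/kg, multiplies fast-twitch fraction
  h_am_base: 25.0         # W/kg
  activation_exponent_am: 0.6
  activation_exponent_short: 2.0
  activation_exponent_length: 1.0
  alpha_short_slow_numerator: 100.0   # alpha_S(slow) = 100 / vmax_slow
  alpha_short_fast_numerator: 153.0   # alpha_S(fast) = 153 / vmax_fast
  vmax_slow_divisor: 2.5
  alpha_length_factor: 4.0            # alpha_L = 4 * alpha_S(slow)
  aerobic_scale: 1.5
  heat_floor: 1.0
  concentric_work_only: false
  lengthening_heat: true
  orderly_recruitment: false
  negative_rate_modification: true

UM10:
  family: umberger
  combined_activation_maintenance: true
  mass_dependent: true
  h_am_fast: 128.0
  h_am_base: 25.0
  activation_exponent_am: 0.6
  activation_exponent_short: 2.0
  activation_exponent_length: 1.0
  alpha_short_slow_numerator: 100.0
  alpha_short_fast_numerator: 153.0
  vmax_slow_divisor: 2.5
  alpha_length_factor: 4.0
  aerobic_scale: 1.5
  heat_floor: 1.0
  concentric_work_only: true          # negative CE work excluded
  lengthening_heat: false             # eccentric heat set to zero
  orderly_recruitment: false
  negative_rate_modification: false   # cannot go negative by construction

UC16:
  family: umberger
  combined_activation_maintenance: true
  mass_dependent: true
  h_am_fast: 128.0
  h_am_base: 25.0
  activation_exponent_am: 0.6
  activation_exponent_short: 2.0
  activation_exponent_length: 1.0
  alpha_short_slow_numerator: 100.0
  alpha_short_fast_numerator: 153.0
  vmax_slow_divisor: 2.5
  alpha_length_factor: 4.0
  aerobic_scale: 1.5
  heat_floor: 1.0
  concentric_work_only: false         # full work accounting, clamped below
  lengthening_heat: true
  orderly_recruitment: true           # ramp recruitment of fiber types
  negative_rate_modification: true    # the model's own non-negativity clamp

BH04:
  family: bhargava
  combined_activation_maintenance: false
  mass_dependent: true
  activation_heat_slow: 40.0    # W/kg
  activation_heat_fast: 133.0   # W/kg
  maintenance_heat_slow: 74.0   # W/kg
  maintenance_heat_fast: 111.0  # W/kg
  shortening_iso_coef: 0.16     # * F_iso(a, l)
  shortening_ce_coef: 0.18      # * F_CE
  lengthening_ce_coef: 0.157    # * F_CE, yields negative eccentric heat
  heat_floor: 1.0
  negative_rate_modification: true

HO06:
  family: houdijk
  combined_activation_maintenance: false
  mass_dependent: true
  maintenance_coef: 66.0        # W/kg at a=1, f_l=1, vmax=10 l_opt/s
  maintenance_vmax_ref: 10.0
  shortening_iso_coef: 0.16     # * F_iso(a, l) * shortening velocity
  lengthening_heat: false       # eccentric heat assumed zero
  heat_floor: 0.0
  negative_rate_modification: true

LW07:
  family: lichtwark
  combined_activation_maintenance: false
  mass_dependent: false
  maintenance_coef: 0.06        # * a * f_l * F_max * l_opt * vmax[1/s]
  shortening_coef: 0.25         # * F_iso(a, l) * shortening velocity
  eccentric_heat_work_fraction: 0.5   # half of eccentric CE work -> heat
  heat_floor: 0.0
  negative_rate_modification: false   # net negative rates are a model output
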