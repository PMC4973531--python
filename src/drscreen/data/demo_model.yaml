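# Illustrative cohort model for demonstrations and smoke tests.
#
# The transition probabilities, utilities and state costs below are NOT
# estimates from any study -- they are plausible placeholder values chosen so
# that detection slows progression to blindness.  Substantive analyses must
# replace them with literature-derived values (progression meta-analysis,
# published utility weights).
#
# Disease states come in undetected / treated pairs; `detects_to` names the
# treated counterpart that screening moves mass into, and `healthy: true`
# marks states whose occupants can test false-positive.

states:
  - {name: no_dr, utility: 0.92, cost: 0, healthy: true}
  - {name: mild_dr_undetected, utility: 0.85, cost: 0, detects_to: mild_dr_treated}
  - {name: mild_dr_treated, utility: 0.85, cost: 350}
  - {name: stdr_undetected, utility: 0.75, cost: 0, detects_to: stdr_treated}
  - {name: stdr_treated, utility: 0.75, cost: 2800}
  - {name: blind, utility: 0.50, cost: 1200}
  - {name: dead, utility: 0.0, cost: 0}

transitions:
  no_dr: {no_dr: 0.92, mild_dr_undetected: 0.08}
  mild_dr_undetected: {mild_dr_undetected: 0.82, stdr_undetected: 0.15, blind: 0.03}
  mild_dr_treated: {mild_dr_treated: 0.93, stdr_treated: 0.06, blind: 0.01}
  stdr_undetected: {stdr_undetected: 0.75, blind: 0.25}
  stdr_treated: {stdr_treated: 0.92, blind: 0.08}
  blind: {blind: 1.0}
  dead: {dead: 1.0}

initial: {no_dr: 1.0}

# One diagnostic visit charged to false positives.
fp_workup_cost: 100.51

# Candidate (annual) vs current (2.5-yearly) screening policy.
strategy_hi: {interval: 1.0, sensitivity: 0.902, specificity: 0.986, episode_cost: 40.43}
strategy_lo: {interval: 2.5, sensitivity: 0.902, specificity: 0.986, episode_cost: 40.43}

discount: {rate: 0.03}
horizon: 17
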