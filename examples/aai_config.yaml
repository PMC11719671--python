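# Scoring configuration for `angioring aai measurements.csv -c aai_config.yaml`.
# Omitted keys keep their defaults; unknown keys are rejected.

# Predictive-importance factors. Parameters judged especially informative for
# angiogenic activity (a complex vascular architecture rather than sheer
# length) may be weighted 2; everything not listed here has weight 1.
# Uncomment and adjust to declare your factor-2 parameters:
weights: {}
#  loop_count: 2
#  junctions_per_vessel: 2
#  branch_count: 2

# Per-parameter orientation (+1/-1). All parameters default to +1; the AAI's
# ratio-of-differences already scores "more change than control" as positive
# even for parameters that decrease (e.g. vessel_structure falls as branching
# proceeds), so flip a sign only if you deliberately want the opposite
# reading.
orientation: {}
#  vessel_structure: -1

day_early: 4
day_late: 7
control_group: control

# literal: (1/n) * sum(w_i * AAI_i)  -- weights can push a subindex past 1
# normalized: sum(w_i * AAI_i) / sum(w_i)
subindex_mode: literal

# per_donor: score each donor against its own control rings, then average;
# pooled: group means over all rings first
aggregation: per_donor

# What to do when the control did not change between the scoring days:
# error (default), epsilon (divide by `epsilon` instead), or drop (exclude
# the parameter with a warning). With degenerate_rel_tol > 0, a control
# change smaller than that fraction of the control level is degenerate too.
degenerate_policy: error
degenerate_rel_tol: 0.0
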