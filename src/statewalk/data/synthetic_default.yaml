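# Default parameters of the two-regime synthetic trajectory generator.
#
# The generator alternates 'straight' (fast, directionally persistent) and
# 'area_restricted' (slow, strongly turning) segments.  Turn increments are
# von Mises; step lengths follow a positive-truncated Gaussian random walk
# with a shared innovation SD.  These numerals are calibrated defaults chosen
# to match the qualitative regime description (see docs/methods.md); edit or
# replace this file to change the study conditions.
regimes:
  straight:
    mu_turn: 0.0        # rad; mean turn ~ 0: directional persistence
    kappa_turn: 10.0    # highly peaked turn distribution
    step_sd: 0.1        # innovation SD of the step-length random walk
    step_init: 2.0      # initial step length of each straight segment
  area_restricted:
    mu_turn: 3.141592653589793   # rad; mean turn ~ pi: back-and-forth motion
    kappa_turn: 1.0              # broad turn distribution
    step_sd: 0.1
    step_init: 0.5               # slower movement while area-restricted
seg_len_min: 20
seg_len_max: 100
target_points: 487
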