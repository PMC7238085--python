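"""From a paranoia-scale change to QALYs.

The effect on the GPTS is standardized by the control arm's baseline SD
(an SMD), converted to a utility difference with a published factor of
0.1835 per SMD unit, and multiplied by the half-year trial horizon.
"""

from trialcea import compute_smd, icer, map_smd_to_qaly

# group-level changes: intervention improves 18 points, control 2 points,
# against a control-arm baseline SD of 31
smd = compute_smd(change_treat=-18.0, change_ctrl=-2.0, sd_ctrl_baseline=31.0)
qaly = map_smd_to_qaly(smd)
print(f"SMD:        {smd:.3f}")
print(f"QALY gain:  {qaly:.3f}  (= SMD x 0.1835 x 0.5 years)")

# combine with an incremental societal cost for the cost-utility ratio
delta_cost = 2343.0
print(f"ICER:       EUR {icer(delta_cost, qaly):,.0f} per QALY")
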