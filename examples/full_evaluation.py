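"""The whole pipeline in one call: simulate, impute, estimate, bootstrap.

run_evaluation() chains costing, responder/QALY construction, chained-
equation imputation of dropout, SUR estimation of incremental cost and
effect, and the bootstrap CE-plane/CEAC machinery, and returns every
table it would write to disk.  Sizes are kept small here so the example
runs in seconds; raise m and B for real use.
"""

from trialcea import RunConfig, TrialConfig, run_evaluation

config = RunConfig(
    trial=TrialConfig(seed=3),   # calibrated defaults incl. dropout
    outcomes=("momentary_paranoia", "qaly"),
    m=5,                         # imputations
    B=500,                       # bootstrap draws
    seed=2024,
)
bundle = run_evaluation(config)

print("incremental estimates (pooled over imputations):")
cols = ["outcome", "delta_cost", "delta_effect", "icer"]
print(bundle.tables["estimates"][cols].round(3).to_string(index=False))

print("\nCE-plane quadrant proportions:")
print(bundle.tables["quadrants"].round(3).to_string(index=False))

print("\nwillingness-to-pay ceiling reaching 80% certainty:")
for outcome, wtp in bundle.manifest["wtp_at_certainty"].items():
    print(f"  {outcome}: {'EUR %.0f' % wtp if wtp is not None else 'not reached'}")
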