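"""Generate a synthetic two-arm trial and look at what came out.

The generator's defaults are calibrated to a 58-per-arm psychosis trial:
paranoia (GPTS) improves by about 16 points more in the intervention arm,
a small admission-driven subgroup carries most of the baseline costs, and
8 then 12 participants drop out monotonically over the two follow-ups.
"""

from trialcea import TrialConfig, apply_missingness, generate_trial

config = TrialConfig(seed=7)  # defaults: 58 per arm, calibrated effects
trial = generate_trial(config)
trial = apply_missingness(trial, config)

print(f"participants: {len(trial)}  per arm: {trial.n_per_arm()}")

baseline = trial.df[trial.df["period"] == "baseline"]
print("\nbaseline GPTS by arm:")
print(baseline.groupby("arm")["gpts"].agg(["mean", "std"]).round(1))

followup = trial.df[trial.df["period"] == "followup"]
complete = followup[followup["missing"] == 0]
print(f"\ncomplete at 6-month follow-up: {len(complete)} of {len(trial)}")
print("follow-up GPTS by arm (completers):")
print(complete.groupby("arm")["gpts"].mean().round(1))
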