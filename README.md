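# trialcea

Trial-based cost-effectiveness analysis from a societal perspective, built
around the design of a two-arm randomized psychosis trial: per-participant
costing (health care, travel, productivity losses), responder and
QALY outcome construction from symptom scales, multiple imputation of
dropout, seemingly-unrelated-regression (SUR) estimation of incremental
costs and effects, and bootstrap inference on the cost-effectiveness
plane (ICERs, quadrant proportions, acceptability curves). A calibrated
synthetic trial generator makes the whole pipeline testable end to end.

## Worked example

From a group-level symptom change to a cost-utility ratio
(`examples/qaly_mapping.py`):

```python
from trialcea import compute_smd, icer, map_smd_to_qaly

smd = compute_smd(change_treat=-18.0, change_ctrl=-2.0, sd_ctrl_baseline=31.0)
qaly = map_smd_to_qaly(smd)
print(f"SMD:        {smd:.3f}")
print(f"QALY gain:  {qaly:.3f}  (= SMD x 0.1835 x 0.5 years)")
print(f"ICER:       EUR {icer(2343.0, qaly):,.0f} per QALY")
```

prints

```
SMD:        0.516
QALY gain:  0.047  (= SMD x 0.1835 x 0.5 years)
ICER:       EUR 49,478 per QALY
```

The full pipeline is one call (`examples/full_evaluation.py`):

```python
from trialcea import RunConfig, TrialConfig, run_evaluation

bundle = run_evaluation(RunConfig(
    trial=TrialConfig(seed=3),               # calibrated defaults incl. dropout
    outcomes=("momentary_paranoia", "qaly"),
    m=5, B=500, seed=2024,
))
print(bundle.tables["estimates"][["outcome", "delta_cost", "delta_effect", "icer"]]
      .round(3).to_string(index=False))
```

prints

```
           outcome  delta_cost  delta_effect      icer
momentary_paranoia    2605.968         0.217 11995.726
              qaly    2605.968         0.034 75851.326
```

The returned bundle also holds the Table-style period/arm cost summary,
quadrant proportions, CEAC tables, bootstrap draws, a sensitivity table,
and a JSON-able run manifest; `RunConfig(outdir=...)` writes everything
to CSV/JSON (plus optional CE-plane and CEAC figures).

## Command line

A thin CLI wraps the library:

```bash
trialcea simulate --n-per-arm 58 --seed 7 --out trial.csv
trialcea cost     --trial trial.csv --out costs.csv
trialcea evaluate --trial trial.csv --m 10 --b 1000 --outdir results/
trialcea report   --trial trial.csv --outdir results/   # adds figures
trialcea ceac     --draws results/draws_qaly.csv --out ceac.csv
```

## Reproducing results

All randomness descends from explicit integer seeds; the same seed yields
byte-identical tables, manifests, and bootstrap draws. The headline
quantities (worked-example arithmetic plus an end-to-end synthetic run)
can be regenerated with:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, assumptions, and parameter defaults,
and `examples/` for short narrative scripts covering simulation, costing,
the QALY mapping, and the full evaluation.
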