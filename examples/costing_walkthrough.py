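"""Cost one participant-period by hand, then a whole trial.

Societal costs are the cent-exact sum of three components: health care
(service contacts, medication with dispensing fees, the per-course
VR-equipment cost), travel (2 x 7 km per care visit at EUR 0.21/km), and
productivity losses valued by the human-capital approach.
"""

from trialcea import (
    Prescription,
    ResourceUse,
    TrialConfig,
    UnitCostTable,
    cost_period,
    generate_trial,
    societal_costs,
)

prices = UnitCostTable()  # Dutch reference prices, CPI-indexed

# one quarter of resource use for a hypothetical participant
use = ResourceUse(
    service_contacts={"hospital_day": 3, "psychiatrist_visit": 2, "nurse_visit": 4},
    prescriptions=[Prescription("antipsychotic", daily_dose_price=1.50, days=90)],
    health_visits=6,                 # return trips to a care provider
    sick_leave_days=4,
    contract_hours_per_week=32.0,
)
breakdown = cost_period(use, gender="female", prices=prices)
print("single period (EUR):")
print(f"  health care:   {breakdown.health_care:9.2f}")
print(f"  travel:        {breakdown.travel:9.2f}")
print(f"  productivity:  {breakdown.productivity:9.2f}")
print(f"  societal:      {breakdown.total_societal:9.2f}")

# the same machinery over a generated trial, per participant
trial = generate_trial(
    TrialConfig(n_per_arm=5, seed=1, dropout_post=0, dropout_followup=0)
)
participant = next(trial.participants())
costs = societal_costs(participant, prices)
print(f"\nparticipant {participant.id} ({participant.arm}):")
for period in ("baseline", "post", "followup", "cumulative"):
    print(f"  {period:10s} total EUR {costs[period].total_societal:9.2f}")
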