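"""Generate a synthetic claims cohort with known ground truth.

Builds a 500-patient new-user cohort: monthly dispensings of the drug of
interest, covariates (age, sex, disease severity), routine-care contacts,
and first-occurrence event streams for a catalog of candidate codes — one
acute-effect code, one delayed/cumulative code, one severity-confounded
null and twenty pure nulls.
"""

import wcescreen as ws

config = ws.SimConfig(
    n_patients=500,
    study_months=60,
    event_codes=ws.default_truth_catalog(window=24, n_null=20),
    seed=1,
)
claims, demographics, truth = ws.simulate_cohort(config)

print(f"claims rows           : {len(claims)}")
print(f"patients              : {demographics.shape[0]}")
print(f"candidate codes       : {truth.shape[0]}")
print(f"severe patients       : {int(demographics['severity'].sum())}")
print("\nfirst claims records:")
print(claims.head(8).to_string(index=False))
print(
    "\nEach row is one reimbursement record; the screen sees only these "
    "tables, while `truth` records which codes truly depend on exposure."
)
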