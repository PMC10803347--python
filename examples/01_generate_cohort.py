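"""Generate a synthetic ICU cohort and inspect its ground truth.

The generator emulates a long-format EHR extract: stay metadata, irregular
vitals/labs, antibiotic doses and culture draws. Septic stays carry a latent
infection time tau; the ground-truth table records tau and the true first
antibiotic/culture times so later stages can be verified.
"""

from sepsikit import CohortConfig, generate_cohort

tables = generate_cohort(CohortConfig(n_patients=100, septic_fraction=0.3, seed=1))

print(f"stays:        {len(tables.stays)} rows")
print(f"observations: {len(tables.observations)} rows, "
      f"{tables.observations['variable'].nunique()} variables")
print(f"dose events:  {len(tables.doses)}, culture events: {len(tables.cultures)}")

gt = tables.ground_truth
septic = gt[gt["is_septic"]]
print(f"\nseptic stays: {len(septic)} of {len(gt)} "
      f"({len(septic[septic['rule_conforming']])} rule-conforming)")
print("\nfirst three septic stays (hours since ICU admission):")
print(septic[["stay_id", "tau_infection", "true_first_abx",
              "true_first_culture"]].head(3).to_string(index=False))
# tau is the latent infection time; antibiotics and cultures follow it by the
# configured recognition delay, so min(abx, culture) is the recoverable
# suspicion time for rule-conforming stays.
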