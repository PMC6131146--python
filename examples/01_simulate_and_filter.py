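"""Simulate a complex-genome sarcoma patient and run the ESV filter cascade.

Generates a primary tumor, a local recurrence at 60 months and a metastasis
at 120 months, emits tumor/normal call records per lesion, filters them
(depths, base quality, MAF, orientation, cross-sample rescue), and checks the
kept trunk against the simulator's ground truth.
"""

from sarclone import (FilterThresholds, SimConfig, classify_trunk,
                      filter_patient_variants, kept_sets,
                      lesion_variant_union, simulate_patient)

cfg = SimConfig.for_mode("complex", seed=7)
patient = simulate_patient(cfg)

records = [r for lesion in patient.lesions
           for recs in lesion.variants.values() for r in recs]
print(f"simulated {len(records)} call records across "
      f"{len(patient.lesions)} lesions")

kept = kept_sets(filter_patient_variants(records, FilterThresholds()))
sample_to_lesion = {sid: l.lesion_id for l in patient.lesions
                    for sid in l.sample_ids}
per_lesion = lesion_variant_union(kept, sample_to_lesion)
for lesion in patient.lesions:
    print(f"  {lesion.lesion_id:<5s} ({lesion.months:>3.0f} months): "
          f"{len(per_lesion[lesion.lesion_id])} ESV kept")

classes = classify_trunk(per_lesion)
n_trunk = sum(1 for c in classes.values() if c == "trunk")
true_trunk = patient.truth.trunk_variants
recovered = {k for k, c in classes.items() if c == "trunk"} & true_trunk
print(f"trunk variants: {n_trunk} called, "
      f"{len(recovered)}/{len(true_trunk)} true trunk recovered")
# A variant kept in every lesion is 'trunk': the mutations the relapses
# inherited from the founding clone. Sequencing noise should all be gone.
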