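"""Descriptive statistics of the study cohorts from the packaged metadata.

Loads the packaged table of 20 leukodystrophy patients (10 with the
eIF2B-related disorder, ERD; 10 with other leukodystrophies, OL) and prints
mean +/- SD of onset age and disease duration per cohort.
"""

from specifex import synthetic

table = synthetic.load_cohort_fixture()
print(f"{len(table)} patients: "
      f"{(table.group == 'ERD').sum()} eIF2B-mutated, {(table.group == 'OL').sum()} OL")

for group, field in [("ERD", "onset_age"), ("ERD", "duration"), ("OL", "onset_age")]:
    s = synthetic.summarize_cohort(table, group, field)
    print(f"{group:4s} {field:10s}: {s.mean:.1f} +/- {s.sd:.1f} y "
          f"(range {s.min:.2f}-{s.max:.2f}, n={s.n})")

# The eIF2B cohort is the severe early-infantile form: onset ~1.2 y with
# rapid progression (~1.7 y to death or loss of motor/cognitive abilities);
# the OL onset mean is computed over 9 patients (one onset age unknown).
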