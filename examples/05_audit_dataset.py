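"""Deploy a certified detective to audit datasets for hidden shortcuts.

A clean cohort should come back unflagged; a cohort whose positive
class was (unknowingly) acquired with different sharpness should be
flagged: its AUC deviates from 0.5 with a CI excluding 0.5.
"""

from shortcutscope import (AdaSpec, PhantomParams, audit_dataset,
                           generate_labeled_cohorts, run_desk_certification)

run = run_desk_certification("S", seed=1, pool_size=400, cohort_size=150)
detectives = [(run.ensemble, run.report.passed)]

clean = generate_labeled_cohorts(150, 150, PhantomParams(side=64, seed=200),
                                 name="clean-cohort")
spec = AdaSpec.from_config(run.report.provenance["ada_spec"])
biased = generate_labeled_cohorts(150, 150, PhantomParams(side=64, seed=201),
                                  shortcut=(spec, "positive"),
                                  name="biased-cohort")

for dataset in (clean, biased):
    for report in audit_dataset(dataset, detectives, seed=5):
        print(report.summary())
# The clean cohort sits at chance; the biased one is flagged because the
# detective separates its classes almost perfectly.
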