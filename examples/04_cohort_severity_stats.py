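"""Cohort-level severity assessment on a graded phantom cohort.

Generates 40 graded phantoms, runs the cascade with intensity-band
backends, and prints the tables a reader of the clinical literature will
recognize: volumetry by grade, ROC/Youden severity discrimination, and
automated-vs-reference agreement.
"""

from hepavol import PipelineConfig, ThresholdSegmenter, generate_cohort, run_cohort
from hepavol.pipeline import CohortCase

cases = generate_cohort(40, [0.2] * 5, seed=12)
cohort = [
    CohortCase(ct=c.ct, liver_reference=c.truth.liver_mask,
               trauma_reference=c.truth.trauma_mask, grade=c.record.aast_grade,
               reference_volumetry=c.record.reference_volumetry)
    for c in cases
]

rep = run_cohort(cohort, ThresholdSegmenter(45.0, 400.0),
                 ThresholdSegmenter(45.0, 90.0),
                 PipelineConfig(equalize=False, invert=False))

print("=== automated volumetry by pseudo-grade (mean/SD and median/IQR) ===")
print(rep.volumetry_by_grade[["n", "lpdi_pct_mean", "lpdi_pct_sd",
                              "lpdi_pct_median", "lpdi_pct_iqr"]].round(2))
print("\n=== severity discrimination (low = grades I-II vs high = III-V) ===")
print(rep.severity.round(3))
print("\n=== automated vs reference agreement ===")
print(rep.agreement.round(4))
# Expected picture: LPDI rises monotonically with grade; both indexes
# discriminate low from high severity with AUC near 1 on this synthetic
# cohort (the pseudo-grade bands are separated by construction); the Youden
# LPDI cutoff falls between the grade-II and grade-III burden bands.
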