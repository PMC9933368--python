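"""Discriminate synthetic disease from health with regional strain.

Simulates 15 healthy and 15 basal-free-wall-hypokinetic phantoms
(0.5 mm tracking jitter), runs the full pipeline per subject, and
summarizes group differences and ROC AUCs per metric.  Basal metrics and
strain rates separate the groups best -- the ordering the method is
designed to expose.  (A 25 vs 25 cohort sharpens the same picture; 15
per group keeps this example quick.)
"""

from cmrstrain import compare_cohort, simulate_cohort

table = simulate_cohort(n_healthy=15, n_diseased=15, seed=7,
                        noise_sigma_mm=0.5)
metrics = [c for c in table.columns if c not in ("subject_id", "group")]
summary = compare_cohort(table, metrics)
print(summary[["metric", "test_used", "p", "auc", "ci_low", "ci_high"]]
      .to_string(index=False, float_format=lambda v: f"{v:6.3f}"))
print("\nAUC ~ 0.5 means no discrimination, 1.0 perfect; basal peak and")
print("strain-rate metrics carry the disease signal, apical ones do not.")
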