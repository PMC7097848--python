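"""Score a synthetic whole-blood cohort with the IFN and IL-36 signatures.

Generates a 9-case / 7-control cohort with a planted 4-fold interferon
program, computes both composite scores against an automatically chosen
control calibrator, and compares case vs control scores with a t test.
"""

import numpy as np
from scipy import stats

import ifnsig

matrix, samples, truth = ifnsig.generate_cohort(ifnsig.CohortConfig(), seed=42)
controls = samples.ids_with_label("control")
cases = samples.ids_with_label("case")

for name in ("ifn", "il36"):
    res = ifnsig.composite_score(
        matrix, ifnsig.default_signature(name), control_ids=controls
    )
    case_scores = [res.scores[s] for s in cases]
    ctrl_scores = [res.scores[s] for s in controls]
    t = stats.ttest_ind(case_scores, ctrl_scores, equal_var=True)
    print(f"{name.upper()} score (calibrator {res.calibrator_sample}):")
    print(f"  mean case score    {np.mean(case_scores):6.2f}  (fold over controls)")
    print(f"  mean control score {np.mean(ctrl_scores):6.2f}  (~1 by construction)")
    print(f"  t-test p = {t.pvalue:.4g}")

# the scores of coupled programs correlate across samples
ifn = ifnsig.composite_score(matrix, ifnsig.default_signature("ifn"),
                             control_ids=controls)
il36 = ifnsig.composite_score(matrix, ifnsig.default_signature("il36"),
                              control_ids=controls)
rho, p = ifnsig.spearman(
    [ifn.scores[s] for s in matrix.sample_ids],
    [il36.scores[s] for s in matrix.sample_ids],
)
print(f"Spearman(IFN, IL-36) = {rho:.2f}, p = {p:.4g} "
      "(programs planted with rho = 0.9)")
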