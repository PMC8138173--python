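"""Cell-composition confounding and its correction.

Whole-blood methylation reflects leukocyte proportions.  If cell
composition drifts with BMI, naive per-probe correlations inflate; an OLS
fit of M on the covariate plus cell proportions restores calibration.
"""

import numpy as np

from dmcpg.association import CovariateSpec, call_dm_for_covariate
from dmcpg.simulate import confounded_config, generate_cohort

cohort = generate_cohort(confounded_config(seed=1, n_probes=4000))
results = call_dm_for_covariate(
    cohort.dataset_fs, CovariateSpec.bmi(), adjust_cells=True
)

unadjusted = np.mean([r.p < 0.05 for r in results])
adjusted = np.mean([r.p_cell_adjusted < 0.05 for r in results])
print(f"unadjusted rejection rate: {100 * unadjusted:.1f}%")
print(f"cell-adjusted rejection rate: {100 * adjusted:.1f}%")
print(
    "\nNo probe here has a true BMI effect: the unadjusted rate far above\n"
    "the nominal 5% is pure cell-composition confounding, and the adjusted\n"
    "rate near 5% shows the linear-model correction removes it."
)
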