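"""Fasting-vs-postprandial paired dmCpG calling within each BMI class.

The paperlike preset plants a postprandial beta shift only in overweight
subjects, so the paired comparison should light up in Ow and stay near
zero in N and Ob — the class-specific prandial dynamicity pattern.
"""

import warnings

from dmcpg.paired import call_paired_dm
from dmcpg.simulate import generate_cohort, paperlike_config

cohort = generate_cohort(paperlike_config(seed=1, n_probes=3000))

counts = {}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # n=4 Wilcoxon floor warning, expected here
    for cls in ("N", "Ow", "Ob"):
        res = call_paired_dm(cohort.dataset_fs, cohort.dataset_ps, cls)
        counts[cls] = sum(r.is_dmcpg for r in res)

for cls, n in counts.items():
    print(f"{cls:>2}: {n} paired dmCpG")
ratio = counts["Ow"] / max(counts["N"], counts["Ob"], 1)
print(f"Ow / max(N, Ob) = {ratio:.1f}x")
print(
    "\nThe overweight class dominates because the postprandial shift was\n"
    "planted there only; N and Ob counts are nominal false positives."
)
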