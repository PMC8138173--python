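"""CpG-island geography and genomic-context distribution of a dmCpG set.

Probes are classified as island / shore (2 kb flanks) / shelf (next 2 kb) /
open sea, and a called set's context counts are compared to the probe
universe with a chi-square goodness-of-fit test.
"""

import warnings

from dmcpg.comparative import DmSet, annotate_islands, context_distribution
from dmcpg.paired import call_paired_dm
from dmcpg.simulate import generate_cohort, paperlike_config

cohort = generate_cohort(paperlike_config(seed=1, n_probes=3000))
ann = annotate_islands(cohort.annotation, cohort.islands)
print("probe universe by island relation:")
print(ann.island_relation.value_counts().to_string())

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = call_paired_dm(cohort.dataset_fs, cohort.dataset_ps, "Ow")
ow_set = DmSet.from_results("Ow", res)
dist = context_distribution(ow_set, ann["island_relation"], cohort.dataset_fs.probe_ids)
print(f"\nOw paired dmCpG (n={len(ow_set)}) context counts:")
for cat, obs, bg in zip(dist.categories, dist.counts, dist.background_counts):
    print(f"  {cat:>9}: {int(obs):4d} (universe {int(bg)})")
print(f"chi2 = {dist.chi2:.1f}, p = {dist.p:.3g}")
print(
    "\nA small p indicates the called set is not drawn proportionally from\n"
    "the universe: the planted postprandial hypermethylation prefers\n"
    "low-methylation island/promoter probes, enriching islands."
)
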