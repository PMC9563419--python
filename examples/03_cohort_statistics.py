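"""Group-level statistics on a synthetic cohort.

Draws per-subject vibrating fractions from the built-in group
distributions (normophonic / benign / malignant), computes each
subject's SAI at mask level, and runs pairwise exact Mann-Whitney
tests.
"""
from laryngotopo import compare_groups
from laryngotopo.synthetic import sample_cohort_sai

groups = sample_cohort_sai(n_per_group=(10, 10, 11), seed=1)
comp = compare_groups(groups)

print(comp.summary_table().to_string(index=False))
print()
for (a, b), p in comp.p_values.items():
    verdict = "different" if p < 0.05 else "indistinguishable"
    print(f"{a:12s} vs {b:12s}: p = {p:.4f}  ({verdict})")
# Malignant cohorts (large stiff areas, SAI ~ 0.65) separate sharply from
# both other groups; benign lesions overlap the normophonic range, so the
# benign-vs-normophonic comparison is usually nonsignificant.
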