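"""The selection funnel: normalize, Welch-screen, build the low-correlation
graph and enumerate cliques of mutually weakly-correlated features.

Features pass the screen when a two-sided Welch test between one propensity
group and controls has p < 0.3; pairs stay connected when |Pearson r| <= 0.3;
candidate feature sets are maximal cliques with at least 8 members.
"""

from actipheno import (CohortSpec, Group, extract_cohort_features, iter_cohort,
                       select_combinations, standard_normalize)

spec = CohortSpec(days_per_subject=3, seed=3)  # default 25/22/22 cohort
table, _ = extract_cohort_features(iter_cohort(spec))
normalized, flagged = standard_normalize(table)

for task in (Group.CTF, Group.PSF):
    combos, counts = select_combinations(normalized, task, seed=0,
                                         n_combinations=16)
    print(f"{task.value} vs C: {counts['features_in']} features -> "
          f"{counts['welch_kept']} past Welch -> {counts['cliques']} cliques "
          f">= 8 -> {counts['combinations']} sampled combinations")
    if combos:
        print("  first combination:", ", ".join(combos[0].features))
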