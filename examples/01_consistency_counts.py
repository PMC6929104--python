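"""Count the datasets in which a microRNA changes consistently.

One mature microRNA is measured in two human naive-vs-primed comparisons
(log2FC + adjusted p each) and three mouse studies (log2FC; 0.0 = not
observed).  The human pair counts as ONE dataset and is consistent iff both
comparisons are significant with the same sign; each mouse study is
consistent iff |log2FC| >= log2(1.5) with that same sign.
"""

from mirconcord import count_consistent_datasets

EXAMPLES = [
    # miR-143-3p: up in both human comparisons, >=1.5-fold up in all three
    # mouse studies -> consistent in all 4 datasets.
    ("hsa-miR-143-3p", (4.10, 2.932e-3, 7.50, 1.163e-7),
     {"Jouneau": 2.16, "Gu": 1.70, "Moradi": 0.79}),
    # miR-200c-3p: down in human, but one mouse study moves the other way.
    ("hsa-miR-200c-3p", (-6.60, 8.956e-96, -8.97, 5.294e-93),
     {"Jouneau": 6.44, "Gu": -1.03, "Moradi": -0.88}),
]

for name, human, mouse in EXAMPLES:
    count = count_consistent_datasets(name, human, mouse,
                                      fc_threshold=1.5, alpha=0.05)
    print(f"{name}: consistent in {count.n_consistent}/4 datasets "
          f"(direction: {count.direction} in the naive state)")
    for dataset, verdict in count.verdicts:
        print(f"  {dataset:>8}: {verdict}")

# The per-dataset verdicts show exactly which studies support the call and
# why the others do not (below the 1.5-fold bar, opposite sign, or absent).
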