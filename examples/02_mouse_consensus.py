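"""Arm-combining consensus across three mouse microRNA studies.

Mouse profiling studies disagree about which mature arm (-3p/-5p) they
report, so evidence is pooled per hairpin stem: a stem is consistently
changing if either arm clears the 1.5-fold bar in two studies with one
sign, or the two arms clear it in different studies with the same sign.
"""

from mirconcord import DERecord, build_arm_profiles, call_mouse_consensus, parse_mirna_name


def rec(name, lfc, study):
    return DERecord(feature=parse_mirna_name(name), log2fc=lfc, padj=1e-4,
                    study=study, species="mouse")


records = [
    # mir-143: the -3p arm is up >= 1.5-fold in all three studies (criterion 1)
    rec("mmu-miR-143-3p", 2.16, "Jouneau"),
    rec("mmu-miR-143-3p", 1.70, "Gu"),
    rec("mmu-miR-143-3p", 0.79, "Moradi"),
    # mir-290: the -3p arm passes in one study, the -5p arm in another
    # (criterion 3, the cross-arm rule)
    rec("mmu-miR-290-3p", 1.9, "Jouneau"),
    rec("mmu-miR-290-5p", 2.1, "Gu"),
    # mir-7: below the fold bar everywhere -> no call
    rec("mmu-miR-7-5p", 0.3, "Jouneau"),
    rec("mmu-miR-7-5p", 0.4, "Gu"),
]

profiles = build_arm_profiles(records)
result = call_mouse_consensus(profiles, fc_threshold=1.5, min_studies=2)

print(f"{len(result)} of {len(profiles)} stems called consistent:")
for call in result:
    studies = ", ".join(sorted(call.supporting_studies))
    print(f"  {call.stem}: {call.direction} via {call.criterion} ({studies})")

# mir-143 is called through the -3p two-study rule, mir-290 through the
# cross-arm rule; mir-7 never clears the 1.5-fold bar and is not called.
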