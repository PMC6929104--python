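"""Arm profiles, the three consensus criteria, and consistency counting."""

import math

import numpy as np
import pytest

from mirconcord import (
    build_arm_profiles,
    call_mouse_consensus,
    count_consistent_datasets,
    cross_species_consensus,
)
from mirconcord.consensus import ArmConflictError, ArmProfile
from conftest import MOUSE_STUDIES, mir_record
from oracles import oracle_mouse_consensus


def profile_from(values3=None, values5=None, stem="mir-1"):
    prof = ArmProfile(stem=stem)
    for arm, values in (("3p", values3 or {}), ("5p", values5 or {})):
        for study, v in values.items():
            prof.observation(study).set(arm, v, 1e-4)
    return prof


class TestBuildArmProfiles:
    def test_groups_by_stem_across_studies(self):
        recs = [
            mir_record("mmu-miR-143-3p", 2.16, study="J", species="mouse"),
            mir_record("mmu-miR-143-3p", 1.70, study="G", species="mouse"),
        ]
        profiles = build_arm_profiles(recs)
        assert set(profiles) == {"mir-143"}
        assert len(profiles["mir-143"].by_study) == 2
        assert profiles["mir-143"].by_study["J"].log2fc_3p == 2.16

    def test_empty_input(self):
        assert build_arm_profiles([]) == {}

    def test_zero_log2fc_means_not_observed(self):
        profiles = build_arm_profiles([mir_record("mmu-miR-495-3p", 0.0, study="J")])
        assert "mir-495" not in profiles or not profiles["mir-495"].by_study

    def test_conflicting_duplicates_raise(self):
        recs = [
            mir_record("mmu-miR-1-3p", 2.0, study="J"),
            mir_record("mmu-miR-1-3p", -2.0, study="J"),
        ]
        with pytest.raises(ArmConflictError, match="mir-1"):
            build_arm_profiles(recs)

    def test_hairpin_fallback_only_without_arm_records(self):
        recs = [
            mir_record("mmu-mir-290", 1.5, study="J"),  # hairpin only in J
            mir_record("mmu-mir-290", 9.9, study="G"),  # hairpin, but...
            mir_record("mmu-miR-290-5p", 2.0, study="G"),  # ...arm data wins in G
        ]
        prof = build_arm_profiles(recs)["mir-290"]
        assert prof.by_study["J"].log2fc_3p == prof.by_study["J"].log2fc_5p == 1.5
        assert ("J", "3p") in prof.hairpin_fallback
        assert prof.by_study["G"].log2fc_5p == 2.0
        assert prof.by_study["G"].log2fc_3p is None


class TestCallMouseConsensus:
    def test_three_study_up_call_via_3p(self):
        prof = profile_from(values3={"J": 2.16, "G": 1.70, "M": 0.79})
        result = call_mouse_consensus({"mir-1": prof})
        (call,) = result.calls
        assert call.direction == "up" and call.criterion == "3p_two_studies"
        assert call.supporting_studies == frozenset({"J", "G", "M"})

    def test_below_threshold_no_call(self):
        prof = profile_from(values3={"J": 0.3, "G": 0.3})
        assert not call_mouse_consensus({"mir-1": prof}).calls

    def test_cross_arm_criterion(self):
        prof = profile_from(values3={"A": 2.0}, values5={"B": 1.8})
        (call,) = call_mouse_consensus({"mir-1": prof}).calls
        assert call.criterion == "cross_arm"
        assert call.supporting_studies == frozenset({"A", "B"})

    def test_cross_arm_same_study_does_not_count(self):
        prof = profile_from(values3={"A": 2.0}, values5={"A": 1.8})
        assert not call_mouse_consensus({"mir-1": prof}).calls

    def test_opposite_arms_in_one_study_conflict(self):
        prof = profile_from(values3={"A": 2.0, "B": 2.0}, values5={"A": -2.0})
        result = call_mouse_consensus({"mir-1": prof})
        assert not result.calls and result.conflicted_stems == ["mir-1"]

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            call_mouse_consensus({}, min_studies=1)
        with pytest.raises(ValueError):
            call_mouse_consensus({}, fc_threshold=0.9)

    def test_matches_enumeration_oracle_on_random_profiles(self):
        """Spot equivalence against the literal-criteria oracle (the full
        5-value grid runs in the acceptance suite)."""
        rng = np.random.default_rng(7)
        grid = [-2.0, -0.3, 0.0, 0.3, 2.0]
        for _ in range(300):
            v3 = {s: float(rng.choice(grid)) for s in "ABC"}
            v5 = {s: float(rng.choice(grid)) for s in "ABC"}
            prof = profile_from(
                values3={s: v for s, v in v3.items() if v},
                values5={s: v for s, v in v5.items() if v},
            )
            result = call_mouse_consensus({"mir-1": prof})
            expected = oracle_mouse_consensus(v3, v5)
            if expected is None:
                assert not result.calls
            else:
                (call,) = result.calls
                assert (call.direction, call.criterion) == expected

    def test_threshold_monotonicity(self):
        """Raising the fold threshold never enlarges the call set.

        Holds for direction-consistent profiles; the conflict-exclusion
        rule is itself threshold-sensitive, so mixed-sign profiles can be
        excluded at a low threshold yet called at a higher one.
        """
        rng = np.random.default_rng(11)
        profiles = {}
        for i in range(60):
            sgn = 1 if i % 2 else -1
            prof = profile_from(
                values3={s: sgn * float(abs(rng.normal(0, 1.5))) for s in "ABC"},
                values5={s: sgn * float(abs(rng.normal(0, 1.5))) for s in "AB"},
                stem=f"mir-{i}",
            )
            profiles[prof.stem] = prof
        sizes = [
            len(call_mouse_consensus(profiles, fc_threshold=t))
            for t in (1.2, 1.5, 2.0, 3.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_sign_antisymmetry(self):
        """Negating every log2FC flips all directions, keeps membership."""
        rng = np.random.default_rng(13)
        profiles, flipped = {}, {}
        for i in range(40):
            v3 = {s: float(rng.normal(0, 1.5)) for s in "ABC"}
            v5 = {s: float(rng.normal(0, 1.5)) for s in "AB"}
            profiles[f"mir-{i}"] = profile_from(v3, v5, stem=f"mir-{i}")
            flipped[f"mir-{i}"] = profile_from(
                {s: -v for s, v in v3.items()},
                {s: -v for s, v in v5.items()},
                stem=f"mir-{i}",
            )
        a = call_mouse_consensus(profiles)
        b = call_mouse_consensus(flipped)
        flip = {"up": "down", "down": "up"}
        assert {(c.stem, flip[c.direction], c.criterion) for c in a} == {
            (c.stem, c.direction, c.criterion) for c in b
        }


class TestCountConsistentDatasets:
    def test_reproduces_published_counts(self, published_consistency_rows):
        """All 20 published rows: the printed per-dataset values yield the
        printed consistent-dataset counts under alpha=0.05, fold 1.5."""
        for _, mature, la, lb, pa, pb, j, g, m, expected in published_consistency_rows:
            count = count_consistent_datasets(
                mature,
                (la, pa, lb, pb),
                dict(zip(MOUSE_STUDIES, (j, g, m))),
                fc_threshold=1.5,
                alpha=0.05,
            )
            assert count.n_consistent == expected, mature
            assert count.direction == ("up" if la > 0 else "down")

    def test_boundary_fold_is_inclusive(self):
        """log2FC 0.60 (fold 1.516) counts; 0.48 and 0.30 do not."""
        count = count_consistent_datasets(
            "x", (4.68, 1e-30, 7.47, 1e-19), {"J": 0.0, "G": 0.60, "M": 4.27}
        )
        assert count.n_consistent == 3
        verdicts = dict(count.verdicts)
        assert verdicts["J"] == "not_observed" and verdicts["G"] == "consistent"

    def test_ambiguous_human_signs(self):
        count = count_consistent_datasets("x", (2.0, 1e-3, -2.0, 1e-3), {"J": 2.0})
        assert count.ambiguous and count.direction is None
        assert count.n_consistent == 0
        assert dict(count.verdicts)["J"] == "no_reference"

    def test_nothing_consistent(self):
        count = count_consistent_datasets(
            "x", (1.0, 0.5, 1.0, 0.5), {"J": 0.0, "G": 0.0, "M": 0.0}
        )
        assert count.n_consistent == 0

    def test_sign_antisymmetry(self):
        a = count_consistent_datasets("x", (3.0, 1e-3, 2.0, 1e-4), {"J": 1.0, "G": -2.0})
        b = count_consistent_datasets("x", (-3.0, 1e-3, -2.0, 1e-4), {"J": -1.0, "G": 2.0})
        assert a.n_consistent == b.n_consistent
        assert {a.direction, b.direction} == {"up", "down"}


class TestCrossSpeciesConsensus:
    def _human(self, name, lfc, padj=1e-3):
        return [
            mir_record(name, lfc, padj, study="H1"),
            mir_record(name, lfc * 1.1, padj, study="H2"),
        ]

    def test_emitted_with_mouse_support(self):
        human = self._human("hsa-let-7f-5p", 4.5)
        mouse = [
            mir_record("mmu-let-7f-5p", 1.97, study="Gu", species="mouse"),
            mir_record("mmu-let-7f-5p", 0.78, study="Moradi", species="mouse"),
        ]
        (call,) = cross_species_consensus(human, mouse)
        assert call.mature_key == "let-7f-5p" and call.direction == "up"
        assert call.supporting_mouse_studies == frozenset({"Gu", "Moradi"})

    def test_significant_human_without_mouse_record_not_emitted(self):
        human = self._human("hsa-miR-4517", 3.0)
        mouse = [mir_record("mmu-miR-1-3p", 2.0, study="Gu", species="mouse")]
        with pytest.warns(UserWarning, match="no overlapping"):
            calls = cross_species_consensus(human, mouse)
        assert calls == []

    def test_human_not_significant_in_both_not_emitted(self):
        human = [
            mir_record("hsa-miR-143-3p", 4.0, 1e-3, study="H1"),
            mir_record("hsa-miR-143-3p", 4.0, 0.2, study="H2"),
        ]
        mouse = [mir_record("mmu-miR-143-3p", 2.0, study="Gu", species="mouse")]
        assert cross_species_consensus(human, mouse) == []

    def test_mouse_opposite_direction_not_supporting(self):
        human = self._human("hsa-miR-205-5p", 3.2)
        mouse = [mir_record("mmu-miR-205-5p", -1.28, study="Moradi", species="mouse")]
        assert cross_species_consensus(human, mouse) == []

    def test_locus_suffix_collapse_matches_across_species(self):
        human = [
            mir_record("hsa-let-7f-5p", 4.7, 1e-2, study="H1"),
            mir_record("hsa-let-7f-5p", 4.3, 9e-3, study="H2"),
        ]
        mouse = [mir_record("mmu-let-7f-5p", 1.97, study="Gu", species="mouse")]
        (call,) = cross_species_consensus(human, mouse)
        assert call.mature_key == "let-7f-5p"
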