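"""Cross-study and cross-species consistency rules for microRNAs.

Three devices implemented here:

1. **Arm-combining mouse consensus.**  Older mouse profiling studies did not
   always distinguish the -3p and -5p mature arms, so evidence for a hairpin
   stem is pooled across arms.  A stem is *consistently changing* across a
   study panel if any of three criteria holds at a fold threshold ``T``
   (default 1.5):

   - c1: the -3p arm changes >= T-fold, same direction, in >= ``min_studies``
     studies;
   - c2: likewise for the -5p arm;
   - c3: the -3p arm passes in one study and the -5p arm passes in the same
     direction in a *different* study.

2. **Consistent-dataset counting.**  For a mature microRNA measured in one
   human comparison pair plus several mouse studies, count the datasets in
   which it moves with the human reference direction: the human pair counts
   as ONE dataset (consistent iff both comparisons are significant with the
   same sign), each mouse study counts iff |log2FC| >= log2(T) with the
   reference sign.  A log2FC of exactly 0 means the microRNA was not
   observed in that study and never counts.

3. **Cross-species consensus.**  A mature form is emitted when it is
   significant in every human comparison with one direction, and changes
   >= T-fold in the same direction in at least one mouse study.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .io import DERecord
from .nomenclature import MirnaId

__all__ = [
    "ArmObservation",
    "ArmProfile",
    "ConsensusCall",
    "ConsensusResult",
    "ConsistencyCount",
    "CrossSpeciesCall",
    "ArmConflictError",
    "build_arm_profiles",
    "call_mouse_consensus",
    "count_consistent_datasets",
    "cross_species_consensus",
]

ARMS = ("3p", "5p")


class ArmConflictError(ValueError):
    """Two records for the same (stem, study, arm) disagree on log2FC."""


@dataclass
class ArmObservation:
    """Per-study arm-resolved values for one stem; None = not observed."""

    log2fc_3p: Optional[float] = None
    padj_3p: Optional[float] = None
    log2fc_5p: Optional[float] = None
    padj_5p: Optional[float] = None

    def log2fc(self, arm: str) -> Optional[float]:
        return self.log2fc_3p if arm == "3p" else self.log2fc_5p

    def set(self, arm: str, log2fc: float, padj: Optional[float]) -> None:
        if arm == "3p":
            self.log2fc_3p, self.padj_3p = log2fc, padj
        else:
            self.log2fc_5p, self.padj_5p = log2fc, padj


@dataclass
class ArmProfile:
    """All observations of one hairpin stem across a study panel.

    ``hairpin_fallback`` records (study, arm) slots that were filled from a
    hairpin-level (arm-unspecified) measurement because the study reported
    no arm-resolved value at all for the stem.
    """

    stem: str
    by_study: dict = field(default_factory=dict)  # study -> ArmObservation
    hairpin_fallback: set = field(default_factory=set)

    def observation(self, study: str) -> ArmObservation:
        return self.by_study.setdefault(study, ArmObservation())


def build_arm_profiles(records: Iterable[DERecord]) -> dict:
    """Group microRNA records into per-stem arm profiles.

    Zero log2FC values (the not-observed sentinel) are dropped.  A hairpin
    (arm-unspecified) record is used for both arms of a study only when that
    study has no arm-resolved record for the stem; such fills are flagged in
    ``hairpin_fallback``.  Conflicting duplicates raise
    :class:`ArmConflictError`; identical duplicates merge silently.

    Returns
    -------
    dict mapping stem key -> :class:`ArmProfile`.
    """
    profiles: dict[str, ArmProfile] = {}
    hairpin_only: list[tuple[str, str, float, Optional[float]]] = []
    for rec in records:
        if not isinstance(rec.feature, MirnaId):
            raise TypeError(f"expected MirnaId records, got {rec.feature!r}")
        if not rec.observed:
            continue
        stem = rec.feature.stem_key
        if rec.feature.arm is None:
            hairpin_only.append((stem, rec.study, rec.log2fc, rec.padj))
            profiles.setdefault(stem, ArmProfile(stem=stem))
            continue
        prof = profiles.setdefault(stem, ArmProfile(stem=stem))
        obs = prof.observation(rec.study)
        existing = obs.log2fc(rec.feature.arm)
        if existing is not None and existing != rec.log2fc:
            raise ArmConflictError(
                f"conflicting log2fc for {stem} {rec.feature.arm} in study "
                f"{rec.study!r}: {existing} vs {rec.log2fc}"
            )
        obs.set(rec.feature.arm, rec.log2fc, rec.padj)
    for stem, study, lfc, padj in hairpin_only:
        prof = profiles[stem]
        obs = prof.by_study.get(study)
        if obs is not None and (obs.log2fc_3p is not None or obs.log2fc_5p is not None):
            continue  # arm-resolved data wins; hairpin value unused
        obs = prof.observation(study)
        for arm in ARMS:
            obs.set(arm, lfc, padj)
            prof.hairpin_fallback.add((study, arm))
    return profiles


@dataclass(frozen=True)
class ConsensusCall:
    stem: str
    direction: str  # "up" / "down" (relative to the first condition)
    criterion: str  # "3p_two_studies" | "5p_two_studies" | "cross_arm"
    supporting_studies: frozenset


@dataclass
class ConsensusResult(Sequence):
    """Consensus calls plus the stems excluded for internal conflicts."""

    calls: list
    conflicted_stems: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.calls)

    def __getitem__(self, i):
        return self.calls[i]

    @property
    def by_stem(self) -> dict:
        return {c.stem: c for c in self.calls}


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _passing(
    profile: ArmProfile, arm: str, log_threshold: float
) -> dict:
    """study -> sign, for studies where this arm clears the fold bar."""
    out = {}
    for study, obs in profile.by_study.items():
        v = obs.log2fc(arm)
        if v is not None and abs(v) >= log_threshold:
            out[study] = _sign(v)
    return out


def call_mouse_consensus(
    profiles: Mapping[str, ArmProfile] | Iterable[ArmProfile],
    fc_threshold: float = 1.5,
    min_studies: int = 2,
) -> ConsensusResult:
    """Apply the three arm-combining consistency criteria to each stem.

    Criteria are checked in order c1 (3p), c2 (5p), c3 (cross-arm); the
    first satisfied one is recorded, at most one call per stem.  A stem
    whose two arms pass in the *same* study with opposite signs is excluded
    and listed in ``conflicted_stems``, as is a stem whose qualifying
    directions tie.  When both directions qualify without tying, the one
    with more supporting studies wins (agreement is required only among
    supporting studies).
    """
    if fc_threshold < 1:
        raise ValueError(f"fc_threshold must be >= 1, got {fc_threshold}")
    if min_studies < 2:
        raise ValueError(f"min_studies must be >= 2, got {min_studies}")
    if hasattr(profiles, "values"):
        profiles = list(profiles.values())
    log_t = math.log2(fc_threshold)
    calls: list[ConsensusCall] = []
    conflicted: list[str] = []
    for prof in sorted(profiles, key=lambda p: p.stem):
        pass3 = _passing(prof, "3p", log_t)
        pass5 = _passing(prof, "5p", log_t)
        if any(
            s in pass5 and pass3[s] != pass5[s] for s in pass3
        ):  # same study, opposite passing arms
            conflicted.append(prof.stem)
            continue
        candidates: list[tuple[str, int, frozenset]] = []
        for crit, passing in (("3p_two_studies", pass3), ("5p_two_studies", pass5)):
            for sgn in (1, -1):
                sup = frozenset(s for s, v in passing.items() if v == sgn)
                if len(sup) >= min_studies:
                    candidates.append((crit, sgn, sup))
        for sgn in (1, -1):
            pairs = [
                (a, b)
                for a in sorted(pass3)
                for b in sorted(pass5)
                if a != b and pass3[a] == sgn and pass5[b] == sgn
            ]
            if pairs:
                candidates.append(("cross_arm", sgn, frozenset(pairs[0])))
        if not candidates:
            continue
        directions = {sgn for _, sgn, _ in candidates}
        if len(directions) > 1:
            best = {
                sgn: max(len(sup) for _, s2, sup in candidates if s2 == sgn)
                for sgn in directions
            }
            top = max(best.values())
            winners = [sgn for sgn, n in best.items() if n == top]
            if len(winners) > 1:
                conflicted.append(prof.stem)
                continue
            candidates = [c for c in candidates if c[1] == winners[0]]
        crit, sgn, sup = candidates[0]  # c1 -> c2 -> c3 order preserved
        calls.append(
            ConsensusCall(
                stem=prof.stem,
                direction="up" if sgn > 0 else "down",
                criterion=crit,
                supporting_studies=sup,
            )
        )
    return ConsensusResult(calls=calls, conflicted_stems=conflicted)


@dataclass
class ConsistencyCount:
    """Across-dataset consistency tally for one mature microRNA."""

    mirna: str
    n_consistent: int
    direction: Optional[str]  # "up" / "down" / None when ambiguous
    verdicts: list  # (dataset label, verdict string)
    ambiguous: bool = False


def count_consistent_datasets(
    mirna,
    human: Sequence[float],
    mouse: Mapping[str, Optional[float]],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> ConsistencyCount:
    """Count datasets in which one microRNA moves with the human direction.

    Parameters
    ----------
    mirna : MirnaId or str
        Row identity (label only).
    human : (log2fc_a, padj_a, log2fc_b, padj_b)
        The two human comparisons; together they form ONE dataset,
        consistent iff both padj < ``alpha`` and both log2FC share a sign.
        That shared sign is the reference direction.
    mouse : mapping study -> log2FC or None
        Arm-resolved mouse values for the mature form named in the row.
        ``None`` or 0.0 means not observed.  A study is consistent iff
        |log2FC| >= log2(``fc_threshold``) (inclusive) and the sign matches
        the reference.

    If the two human comparisons disagree in sign there is no reference
    direction: the result is flagged ambiguous with n_consistent = 0 and
    per-dataset verdicts marked non-evaluable.
    """
    lfc_a, padj_a, lfc_b, padj_b = human
    log_t = math.log2(fc_threshold)
    sign_a, sign_b = _sign(lfc_a), _sign(lfc_b)
    if sign_a != sign_b or sign_a == 0:
        verdicts = [("human", "ambiguous")]
        verdicts += [(s, "no_reference") for s in mouse]
        return ConsistencyCount(
            mirna=str(mirna),
            n_consistent=0,
            direction=None,
            verdicts=verdicts,
            ambiguous=True,
        )
    ref = sign_a
    human_ok = (
        padj_a is not None
        and padj_b is not None
        and padj_a < alpha
        and padj_b < alpha
    )
    verdicts = [("human", "consistent" if human_ok else "not_significant")]
    for study, value in mouse.items():
        if value is None or value == 0.0:
            verdicts.append((study, "not_observed"))
        elif _sign(value) != ref:
            verdicts.append((study, "opposite_direction"))
        elif abs(value) >= log_t:
            verdicts.append((study, "consistent"))
        else:
            verdicts.append((study, "below_threshold"))
    n = sum(1 for _, v in verdicts if v == "consistent")
    return ConsistencyCount(
        mirna=str(mirna),
        n_consistent=n,
        direction="up" if ref > 0 else "down",
        verdicts=verdicts,
    )


@dataclass(frozen=True)
class CrossSpeciesCall:
    mature_key: str  # species-free stem(+arm) key
    direction: str  # "up" / "down"
    supporting_mouse_studies: frozenset


def cross_species_consensus(
    human_de: Iterable[DERecord],
    mouse_studies: Iterable[DERecord],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> list:
    """Mature microRNAs changing consistently in both species.

    A mature key qualifies when (1) it is observed in every human comparison
    present in ``human_de`` with padj < ``alpha`` and one shared sign, and
    (2) at least one mouse study shows |log2FC| >= log2(``fc_threshold``)
    with that sign.  Species prefixes and duplicate-locus suffixes are
    dropped before matching; a mouse record with unspecified arm matches any
    arm of its stem.
    """
    log_t = math.log2(fc_threshold)
    # keys are (stem, arm) tuples; arm None = hairpin-level record
    human_by_key: dict[tuple, dict[str, DERecord]] = defaultdict(dict)
    human_study_labels: set[str] = set()
    for rec in human_de:
        if not isinstance(rec.feature, MirnaId):
            raise TypeError("human_de must contain MirnaId records")
        human_study_labels.add(rec.study)
        if rec.observed:
            key = (rec.feature.stem_key, rec.feature.arm)
            human_by_key[key][rec.study] = rec
    mouse_by_key: dict[tuple, list[DERecord]] = defaultdict(list)
    mouse_stems: set[str] = set()
    for rec in mouse_studies:
        if not isinstance(rec.feature, MirnaId):
            raise TypeError("mouse_studies must contain MirnaId records")
        if rec.observed:
            mouse_by_key[(rec.feature.stem_key, rec.feature.arm)].append(rec)
            mouse_stems.add(rec.feature.stem_key)
    human_stems = {stem for stem, _ in human_by_key}
    if human_by_key and mouse_by_key and not (human_stems & mouse_stems):
        warnings.warn("no overlapping microRNA stems between species")
    calls: list[CrossSpeciesCall] = []
    for key in sorted(human_by_key, key=lambda k: (k[0], k[1] or "")):
        stem, arm = key
        per_study = human_by_key[key]
        if set(per_study) != human_study_labels:
            continue
        signs = {_sign(r.log2fc) for r in per_study.values()}
        if len(signs) != 1:
            continue
        ref = signs.pop()
        if any(r.padj is None or r.padj >= alpha for r in per_study.values()):
            continue
        candidates = list(mouse_by_key.get(key, []))
        # hairpin-level mouse records (no arm) back any arm of the stem
        if arm is not None:
            candidates += mouse_by_key.get((stem, None), [])
        support = frozenset(
            r.study
            for r in candidates
            if abs(r.log2fc) >= log_t and _sign(r.log2fc) == ref
        )
        if support:
            calls.append(
                CrossSpeciesCall(
                    mature_key=f"{stem}-{arm}" if arm else stem,
                    direction="up" if ref > 0 else "down",
                    supporting_mouse_studies=support,
                )
            )
    return calls
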