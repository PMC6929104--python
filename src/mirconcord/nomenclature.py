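"""Canonical microRNA and gene identifiers.

microRNA naming is layered: a *hairpin* (precursor) name such as
``hsa-mir-143`` groups the one or two *mature* arms excised from it
(``hsa-miR-143-3p``, ``hsa-miR-143-5p``).  Some families are transcribed from
several genomic loci that yield identical or near-identical mature products;
these carry a numeric locus suffix (``hsa-let-7f-1`` and ``hsa-let-7f-2``
both produce ``hsa-let-7f-5p``).  Different studies report any of these
layers, with inconsistent ``mir``/``miR`` capitalisation, so joining
differential-expression tables across studies (and across species, where only
the three-letter prefix differs) requires a canonical form.

:class:`MirnaId` decomposes a name into species prefix, stem, locus suffix
and arm, and exposes the species-free, locus-free *mature key* used for all
cross-table joins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MirnaId",
    "GeneKey",
    "MirnaParseError",
    "parse_mirna_name",
    "canonical_gene_symbol",
]


class MirnaParseError(ValueError):
    """Raised when a microRNA name has no recognizable structure."""


_CORE_TOKENS = {"mir", "let"}
# stem base: digits optionally followed by letter variants, e.g. 143, 7f, 196a, 466h
_BASE_RE = re.compile(r"^\d+[a-z]*$")
_PREFIX_RE = re.compile(r"^[a-z]{3,4}$")
_ARM_TOKENS = {"3p", "5p"}


@dataclass(frozen=True, order=True)
class MirnaId:
    """A parsed microRNA identity.

    Attributes
    ----------
    species_prefix : str
        Three-letter species code (``hsa``, ``mmu``), or ``""`` when the
        name carried none.
    stem : str
        Lower-cased family stem including the core token, e.g. ``mir-143``
        or ``let-7f``.
    locus_suffix : str
        Numeric duplicate-locus suffix (``"1"``, ``"2"``) or ``""``.
    arm : str or None
        ``"3p"``, ``"5p"``, or ``None`` for a hairpin/unspecified-arm name.
    """

    species_prefix: str = ""
    stem: str = ""
    locus_suffix: str = ""
    arm: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.stem:
            raise MirnaParseError("empty stem")
        if self.arm is not None and self.arm not in _ARM_TOKENS:
            raise MirnaParseError(f"invalid arm token: {self.arm!r}")

    @property
    def mature_key(self) -> str:
        """Species-free, locus-free key for cross-study/cross-species joins.

        Duplicate loci collapse to one mature identity (``let-7f-1`` and
        ``let-7f-2`` both map to ``let-7f-5p`` once the arm is fixed).
        """
        return f"{self.stem}-{self.arm}" if self.arm else self.stem

    @property
    def stem_key(self) -> str:
        """Species-free hairpin stem (no locus, no arm)."""
        return self.stem

    def with_arm(self, arm: Optional[str]) -> "MirnaId":
        return MirnaId(self.species_prefix, self.stem, self.locus_suffix, arm)

    def __str__(self) -> str:
        core, base = self.stem.split("-", 1)
        # miRBase convention: mature names capitalise miR, hairpins use mir;
        # let- stems are invariant.
        if core == "mir":
            core = "miR" if self.arm else "mir"
        parts = []
        if self.species_prefix:
            parts.append(self.species_prefix)
        parts.append(core)
        parts.append(base)
        if self.locus_suffix:
            parts.append(self.locus_suffix)
        if self.arm:
            parts.append(self.arm)
        return "-".join(parts)


def parse_mirna_name(raw: str) -> MirnaId:
    """Parse a microRNA name into a canonical :class:`MirnaId`.

    Accepts hairpin names (``hsa-mir-143``), mature names
    (``hsa-miR-143-3p``), locus-suffixed names (``hsa-let-7f-2``,
    ``hsa-miR-92a-2-5p``) and prefix-free names (``miR-218-5p``), in any
    ``mir``/``miR``/``MIR`` capitalisation.

    Raises
    ------
    MirnaParseError
        If no ``mir``/``let`` core token with a valid stem base is found;
        the message names the offending token.
    """
    if not raw or not raw.strip():
        raise MirnaParseError("empty microRNA name")
    tokens = raw.strip().split("-")
    i = 0
    prefix = ""
    if tokens[0].lower() not in _CORE_TOKENS:
        if len(tokens) >= 2 and tokens[1].lower() in _CORE_TOKENS:
            cand = tokens[0].lower()
            if not _PREFIX_RE.match(cand):
                raise MirnaParseError(
                    f"unrecognizable species prefix {tokens[0]!r} in {raw!r}"
                )
            prefix = cand
            i = 1
        else:
            raise MirnaParseError(
                f"no mir/let core token found at {tokens[0]!r} in {raw!r}"
            )
    core = tokens[i].lower()
    if i + 1 >= len(tokens):
        raise MirnaParseError(f"missing stem base after {tokens[i]!r} in {raw!r}")
    base = tokens[i + 1].lower()
    if not _BASE_RE.match(base):
        raise MirnaParseError(f"unrecognizable stem base {tokens[i + 1]!r} in {raw!r}")
    rest = [t.lower() for t in tokens[i + 2 :]]
    arm: Optional[str] = None
    locus = ""
    if rest and rest[-1] in _ARM_TOKENS:
        arm = rest[-1]
        rest = rest[:-1]
    if rest and rest[-1].isdigit():
        locus = rest[-1]
        rest = rest[:-1]
    if rest:
        raise MirnaParseError(f"unrecognized trailing token {rest[0]!r} in {raw!r}")
    return MirnaId(prefix, f"{core}-{base}", locus, arm)


_SPECIES_CANON = {"human": str.upper, "mouse": str.capitalize}


def canonical_gene_symbol(symbol: str, species: str) -> str:
    """Normalise a gene symbol to its species convention.

    Human symbols are upper-case (``ODC1``); mouse symbols are title-case
    (``Odc1``).  Other species are left as given.  Idempotent.
    """
    fn = _SPECIES_CANON.get(species)
    return fn(symbol) if fn else symbol


@dataclass(frozen=True, order=True)
class GeneKey:
    """A canonicalized gene symbol with its species.

    Cross-species matching uses :attr:`match_key` (case-folded symbol), the
    convention under which human ``ATP13A2`` and mouse ``Atp13a2`` are the
    same gene; an explicit ortholog map can override this upstream.
    """

    symbol: str
    species: str = "human"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty gene symbol")
        object.__setattr__(
            self, "symbol", canonical_gene_symbol(self.symbol.strip(), self.species)
        )

    @property
    def match_key(self) -> str:
        return self.symbol.upper()

    def __str__(self) -> str:
        return self.symbol
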