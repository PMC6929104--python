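"""Anti-correlated microRNA–target networks and tri-omics triplets.

A validated miRNA→gene edge becomes a *consistent connection* when both
endpoints are significantly differentially expressed between the contrasted
conditions and their log2 fold-changes have opposite signs — the expression
pattern expected of a functional repressive interaction (miRNA up, target
down, or vice versa).  Connections are edges, not genes: one miRNA may
oppose many targets and one target may be opposed by many miRNAs, so the
connection count, miRNA count and target count are reported separately.

A *tri-omics triplet* extends this to metabolism: a gene qualifies when it
(1) changes significantly, (2) has at least one opposing significant miRNA
regulator, and (3) is adjacent (substrate / product / transported) to at
least one significantly changing metabolite.  The metabolite's direction
relative to the gene is annotated but never filtered on — transporter
substrates and enzyme products can legitimately move either way.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

from .io import DERecord, MetaboliteRecord, TargetInteraction
from .nomenclature import GeneKey, MirnaId

__all__ = [
    "ConsistentConnection",
    "NetworkSummary",
    "TriOmicsTriplet",
    "find_consistent_connections",
    "gate_consistent_genes",
    "gate_consistent_mirnas",
    "summarize_network",
    "find_triomics_triplets",
]


def _sign(x: float) -> int:
    return (x > 0) - (x < 0)


def _dir(x: float) -> str:
    return "up" if x > 0 else "down"


@dataclass(frozen=True)
class ConsistentConnection:
    """One anti-correlated miRNA→target edge."""

    mirna: MirnaId
    gene: GeneKey
    mirna_log2fc: float
    gene_log2fc: float
    evidence: str = ""

    def __post_init__(self) -> None:
        if _sign(self.mirna_log2fc) == _sign(self.gene_log2fc):
            raise ValueError(
                f"connection {self.mirna}->{self.gene} is not anti-correlated"
            )

    @property
    def mirna_direction(self) -> str:
        return _dir(self.mirna_log2fc)

    @property
    def gene_direction(self) -> str:
        return _dir(self.gene_log2fc)


def _mirna_lfc_map(records: Iterable[DERecord]) -> dict:
    """mature key -> log2FC; conflicting-sign duplicates are dropped."""
    acc: dict[str, list[float]] = defaultdict(list)
    for rec in records:
        if not isinstance(rec.feature, MirnaId):
            raise TypeError("expected MirnaId records")
        if rec.observed:
            acc[rec.feature.mature_key].append(rec.log2fc)
    out = {}
    for key, vals in acc.items():
        if len({_sign(v) for v in vals}) == 1:
            out[key] = sum(vals) / len(vals)
    return out


def _gene_lfc_map(records: Iterable[DERecord]) -> dict:
    acc: dict[str, list[float]] = defaultdict(list)
    for rec in records:
        if not isinstance(rec.feature, GeneKey):
            raise TypeError("expected GeneKey records")
        if rec.observed:
            acc[rec.feature.match_key].append(rec.log2fc)
    return {
        key: sum(vals) / len(vals)
        for key, vals in acc.items()
        if len({_sign(v) for v in vals}) == 1
    }


def find_consistent_connections(
    mirna_de: Iterable[DERecord],
    gene_de: Iterable[DERecord],
    targets: Iterable[TargetInteraction],
) -> list:
    """Connect significant miRNAs to significant targets moving oppositely.

    Both DE collections are expected to be pre-filtered to significant
    features (and, for multi-study gene input, pre-gated with
    :func:`gate_consistent_genes`).  Matching is by species-free mature
    miRNA key and case-folded gene symbol.  Features appearing with
    conflicting signs across records are dropped; same-sign duplicates use
    the mean log2FC.  Output is sorted by (miRNA, gene).
    """
    mirna_lfc = _mirna_lfc_map(mirna_de)
    gene_lfc = _gene_lfc_map(gene_de)
    out: list[ConsistentConnection] = []
    seen: set[tuple] = set()
    for edge in targets:
        mkey = edge.mirna.mature_key
        gkey = edge.gene.match_key
        if mkey not in mirna_lfc or gkey not in gene_lfc:
            continue
        m_lfc, g_lfc = mirna_lfc[mkey], gene_lfc[gkey]
        if _sign(m_lfc) == _sign(g_lfc):
            continue
        dedup = (mkey, gkey)
        if dedup in seen:
            continue
        seen.add(dedup)
        out.append(
            ConsistentConnection(
                mirna=edge.mirna,
                gene=edge.gene,
                mirna_log2fc=m_lfc,
                gene_log2fc=g_lfc,
                evidence=edge.evidence,
            )
        )
    out.sort(key=lambda c: (str(c.mirna), str(c.gene)))
    return out


def gate_consistent_genes(
    per_study_gene_de: Mapping[str, Iterable[DERecord]],
    alpha: float = 0.05,
) -> list:
    """Keep genes significant in every study with one shared direction.

    Returns one consensus :class:`DERecord` per surviving gene carrying the
    mean log2FC, the worst (largest) padj, and a joined study label.  With a
    single study the input's significant genes pass through, with a warning
    that no cross-study gating was possible.
    """
    studies = sorted(per_study_gene_de)
    if len(studies) < 2:
        warnings.warn("gate_consistent_genes: single study supplied; passthrough")
    per_gene: dict[str, dict[str, DERecord]] = defaultdict(dict)
    species = "human"
    for study in studies:
        for rec in per_study_gene_de[study]:
            if not isinstance(rec.feature, GeneKey):
                raise TypeError("expected GeneKey records")
            per_gene[rec.feature.match_key][study] = rec
            species = rec.species
    kept: list[DERecord] = []
    for gkey in sorted(per_gene):
        by_study = per_gene[gkey]
        if set(by_study) != set(studies):
            continue
        recs = [by_study[s] for s in studies]
        if any(r.padj is None or r.padj >= alpha or not r.observed for r in recs):
            continue
        if len({_sign(r.log2fc) for r in recs}) != 1:
            continue
        kept.append(
            DERecord(
                feature=recs[0].feature,
                log2fc=sum(r.log2fc for r in recs) / len(recs),
                padj=max(r.padj for r in recs),
                study="+".join(studies),
                species=species,
            )
        )
    return kept


def gate_consistent_mirnas(
    per_study_mirna_de: Mapping[str, Iterable[DERecord]],
    alpha: float = 0.05,
) -> list:
    """The microRNA analogue of :func:`gate_consistent_genes`.

    Keyed by species-free mature key; a mature form survives when it is
    observed in every study with padj < ``alpha`` and one shared sign.
    Returns one consensus record per surviving mature form.
    """
    studies = sorted(per_study_mirna_de)
    if len(studies) < 2:
        warnings.warn("gate_consistent_mirnas: single study supplied; passthrough")
    per_key: dict[str, dict[str, DERecord]] = defaultdict(dict)
    for study in studies:
        for rec in per_study_mirna_de[study]:
            if not isinstance(rec.feature, MirnaId):
                raise TypeError("expected MirnaId records")
            per_key[rec.feature.mature_key][study] = rec
    kept: list[DERecord] = []
    for key in sorted(per_key):
        by_study = per_key[key]
        if set(by_study) != set(studies):
            continue
        recs = [by_study[s] for s in studies]
        if any(r.padj is None or r.padj >= alpha or not r.observed for r in recs):
            continue
        if len({_sign(r.log2fc) for r in recs}) != 1:
            continue
        kept.append(
            DERecord(
                feature=recs[0].feature,
                log2fc=sum(r.log2fc for r in recs) / len(recs),
                padj=max(r.padj for r in recs),
                study="+".join(studies),
                species=recs[0].species,
            )
        )
    return kept


@dataclass(frozen=True)
class NetworkSummary:
    n_connections: int
    n_mirnas: int
    n_targets: int
    n_targets_up: int
    n_targets_down: int


def summarize_network(connections: Sequence[ConsistentConnection]) -> NetworkSummary:
    """Unique-entity counts for a connection set.

    The up/down split is over unique target genes (by their direction in the
    contrast), so ``n_targets_up + n_targets_down == n_targets``.
    """
    mirnas = {c.mirna.mature_key for c in connections}
    target_dir = {c.gene.match_key: c.gene_direction for c in connections}
    ups = sum(1 for d in target_dir.values() if d == "up")
    return NetworkSummary(
        n_connections=len(connections),
        n_mirnas=len(mirnas),
        n_targets=len(target_dir),
        n_targets_up=ups,
        n_targets_down=len(target_dir) - ups,
    )


@dataclass(frozen=True)
class TriOmicsTriplet:
    """A gene with opposing miRNA regulators and adjacent changing metabolites."""

    gene: GeneKey
    gene_log2fc: float
    opposing_mirnas: frozenset  # mature keys
    linked_metabolites: Tuple  # (name, direction, concordant_with_gene) tuples

    @property
    def gene_direction(self) -> str:
        return _dir(self.gene_log2fc)


def find_triomics_triplets(
    gene_de: Iterable[DERecord],
    connections: Sequence[ConsistentConnection],
    metabolite_de: Iterable[MetaboliteRecord],
    gene_metabolite_map: Optional[Iterable[Tuple[str, str, str]]],
    alpha: float = 0.05,
) -> list:
    """Genes satisfying all three tri-omics criteria.

    ``gene_de`` is the significant gene set; ``connections`` supplies the
    opposing-regulator evidence; ``gene_metabolite_map`` rows are
    (gene symbol, metabolite, relation) with relation in {substrate,
    product, transported}.  A triplet is emitted per significant gene with
    >= 1 opposing miRNA and >= 1 adjacent metabolite significant at
    ``alpha`` (or flagged significant).  The metabolite's concordance with
    the gene's direction is annotated, not filtered.

    With no metabolite map the result is empty and an explicit "no
    metabolite layer" notice is issued.
    """
    adjacency = list(gene_metabolite_map or [])
    if not adjacency:
        warnings.warn("find_triomics_triplets: no metabolite layer supplied")
        return []
    opposing: dict[str, set] = defaultdict(set)
    for conn in connections:
        opposing[conn.gene.match_key].add(conn.mirna.mature_key)
    met_by_name = {m.metabolite.casefold(): m for m in metabolite_de}
    adjacent: dict[str, list] = defaultdict(list)
    for gene_symbol, metabolite, relation in adjacency:
        adjacent[gene_symbol.upper()].append((metabolite, relation))
    triplets: list[TriOmicsTriplet] = []
    for rec in sorted(gene_de, key=lambda r: str(r.feature)):
        if not isinstance(rec.feature, GeneKey):
            raise TypeError("expected GeneKey records")
        gkey = rec.feature.match_key
        if not rec.observed or not opposing.get(gkey):
            continue
        linked = []
        for met_name, _relation in adjacent.get(gkey, []):
            met = met_by_name.get(met_name.casefold())
            if met is None or not met.is_significant(alpha):
                continue
            linked.append(
                (met.metabolite, _dir(met.log2fc), _sign(met.log2fc) == _sign(rec.log2fc))
            )
        if linked:
            triplets.append(
                TriOmicsTriplet(
                    gene=rec.feature,
                    gene_log2fc=rec.log2fc,
                    opposing_mirnas=frozenset(opposing[gkey]),
                    linked_metabolites=tuple(sorted(linked)),
                )
            )
    return triplets
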