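"""Synthetic multi-study DE bundles with planted consistency structure.

The generator emulates the statistical shape of a naive-vs-primed (or
diapause-vs-reactivated) meta-analysis: two human microRNA comparisons,
a panel of mouse microRNA studies, two gene-expression studies, a validated
target database, and a coupled metabolite layer.  A configurable fraction
of microRNA stems is *planted* as consistently changing: they receive a
shared-sign effect of ``effect_size_log2`` (plus Gaussian noise of
``null_sd_log2``) in their supporting studies, while null features draw
pure noise.  Adjusted p-values come from a monotone map of the standardized
effect (two-sided normal tail of |log2FC| / (4 * null_sd_log2)), not from a
count-level model — the pipeline consumes DE tables, so count realism buys
nothing here.

Each planted stem carries one of four arm patterns (3p-only, 5p-only, both
arms, or a cross-arm split across two studies), guaranteeing that all three
arm-combining consensus criteria occur.  A fraction of planted stems is
mirrored into the human tables (significant in both human comparisons, same
direction): these are the planted cross-species stems, and their mature
forms become the planted network regulators.  Every planted regulator owns
a disjoint pool of target genes; each such gene receives the opposite sign
with probability ``anti_correlation_fidelity`` and a random sign otherwise,
so expected connection recall is f + (1-f)/2.  DE null genes are drawn
outside the reserved pools, which keeps connection precision at exactly 1.

Everything is deterministic given (config, seed): identical configs produce
byte-identical written bundles.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import (
    DERecord,
    MetaboliteRecord,
    TargetInteraction,
    write_de_table,
    write_records_tsv,
)
from .nomenclature import GeneKey, MirnaId, parse_mirna_name

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Bundle",
    "RecoveryMetrics",
    "generate_bundle",
    "evaluate_recovery",
]

_ARM_PATTERNS = ("3p", "5p", "both", "cross")
_ARM_PATTERN_PROBS = (0.4, 0.3, 0.15, 0.15)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Defaults are scaled-down analogues of a real multi-study integration:
    two human microRNA comparisons against a reference-epigenome-style
    panel, three mouse microRNA studies, two gene studies, ~20% of stems
    truly consistent with a 4-fold (log2 = 2) effect over weak null noise.
    """

    n_mirnas: int = 80
    n_genes: int = 300
    n_metabolites: int = 30
    human_studies: Tuple[str, ...] = ("HumanA", "HumanB")
    mouse_studies: Tuple[str, ...] = ("MouseJ", "MouseG", "MouseM")
    gene_studies: Tuple[str, ...] = ("GeneA", "GeneB")
    frac_consistent_mirnas: float = 0.2
    effect_size_log2: float = 2.0
    null_sd_log2: float = 0.1
    anti_correlation_fidelity: float = 1.0
    target_degree: float = 4.0
    frac_cross_species: float = 0.6
    frac_triplet_genes: float = 0.3
    frac_null_genes_de: float = 0.15
    frac_null_genes_discordant: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_consistent_mirnas",
            "anti_correlation_fidelity",
            "frac_cross_species",
            "frac_triplet_genes",
            "frac_null_genes_de",
            "frac_null_genes_discordant",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if min(self.n_mirnas, self.n_genes, self.n_metabolites) <= 0:
            raise ValueError("feature counts must be positive")
        if self.effect_size_log2 <= 0 or self.null_sd_log2 <= 0:
            raise ValueError("effect_size_log2 and null_sd_log2 must be positive")
        if len(self.mouse_studies) < 2 or len(self.human_studies) < 1:
            raise ValueError("need >= 2 mouse studies and >= 1 human study")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure, reproducible from (config, seed)."""

    consensus_stems: Mapping[str, str]  # stem -> "up"/"down"
    cross_species_keys: Mapping[str, str]  # mature key -> "up"/"down"
    connections: frozenset  # (mature key, GENE SYMBOL)
    triplets: frozenset  # GENE SYMBOL


@dataclass
class Bundle:
    """An in-memory synthetic bundle plus its ground truth."""

    config: SyntheticConfig
    truth: GroundTruth
    mouse_mirna: dict  # study -> list[DERecord]
    human_mirna: dict  # study -> list[DERecord]
    gene_de: dict  # study -> list[DERecord]
    targets: list  # list[TargetInteraction]
    metabolites: list  # list[MetaboliteRecord]
    gene_metabolite_map: list  # (gene symbol, metabolite, relation)

    def write(self, outdir) -> dict:
        """Write every table in the dialects the readers consume.

        Returns a name -> path mapping.  Deterministic: same bundle, same
        bytes.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for group, tables in (
            ("mouse_mirna", self.mouse_mirna),
            ("human_mirna", self.human_mirna),
            ("gene", self.gene_de),
        ):
            for study, records in tables.items():
                p = outdir / f"{group}_{study}.tsv"
                write_de_table(records, p, params={"study": study})
                paths[f"{group}_{study}"] = p
        p = outdir / "targets.tsv"
        write_records_tsv(
            p,
            ["miRNA", "Target Gene", "Support Type"],
            [(str(t.mirna), t.gene.symbol, t.evidence) for t in self.targets],
        )
        paths["targets"] = p
        p = outdir / "metabolites.tsv"
        write_records_tsv(
            p,
            ["metabolite", "log2fc", "padj"],
            [
                (m.metabolite, repr(m.log2fc), "NA" if m.padj is None else repr(m.padj))
                for m in self.metabolites
            ],
        )
        paths["metabolites"] = p
        p = outdir / "gene_metabolite_map.tsv"
        write_records_tsv(p, ["gene", "metabolite", "relation"], self.gene_metabolite_map)
        paths["gene_metabolite_map"] = p
        p = outdir / "truth.json"
        with open(p, "w") as fh:
            json.dump(
                {
                    "consensus_stems": dict(sorted(self.truth.consensus_stems.items())),
                    "cross_species_keys": dict(
                        sorted(self.truth.cross_species_keys.items())
                    ),
                    "connections": sorted(map(list, self.truth.connections)),
                    "triplets": sorted(self.truth.triplets),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        paths["truth"] = p
        return paths


def _padj_model(log2fc: float, null_sd: float) -> float:
    z = abs(log2fc) / (4.0 * null_sd)
    return float(min(1.0, max(2.0 * stats.norm.sf(z), 1e-300)))


def _pattern_arms(pattern: str) -> Tuple[str, ...]:
    return ("3p",) if pattern == "3p" else ("5p",) if pattern == "5p" else ("3p", "5p")


def generate_bundle(config: SyntheticConfig) -> Bundle:
    """Generate one bundle under ``config`` (deterministic given its seed)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_mirnas
    stems = [f"mir-{100 + i}" for i in range(n)]
    patterns = rng.choice(_ARM_PATTERNS, size=n, p=_ARM_PATTERN_PROBS)
    n_consistent = int(round(cfg.frac_consistent_mirnas * n))
    consistent_idx = sorted(rng.choice(n, size=n_consistent, replace=False))
    directions = {i: int(d) for i, d in zip(consistent_idx, rng.choice([1, -1], size=n_consistent))}
    n_cross = int(round(cfg.frac_cross_species * n_consistent))
    mirrored_idx = sorted(rng.choice(consistent_idx, size=n_cross, replace=False)) if n_consistent else []
    mirrored = set(mirrored_idx)

    def mirna(prefix: str, stem: str, arm: str) -> MirnaId:
        return MirnaId(species_prefix=prefix, stem=stem, arm=arm)

    noise = lambda: float(rng.normal(0.0, cfg.null_sd_log2))

    # --- mouse microRNA tables -------------------------------------------
    mouse_mirna: dict[str, list] = {s: [] for s in cfg.mouse_studies}
    for i, stem in enumerate(stems):
        pattern = patterns[i]
        if pattern == "cross":
            cells = {
                ("3p", cfg.mouse_studies[0]),
                ("5p", cfg.mouse_studies[1]),
            }
        else:
            cells = {
                (arm, s) for arm in _pattern_arms(pattern) for s in cfg.mouse_studies
            }
        for arm in ("3p", "5p"):
            for study in cfg.mouse_studies:
                if (arm, study) not in cells:
                    continue
                if i in directions:
                    lfc = directions[i] * cfg.effect_size_log2 + noise()
                else:
                    lfc = noise()
                mouse_mirna[study].append(
                    DERecord(
                        feature=mirna("mmu", stem, arm),
                        log2fc=lfc,
                        padj=_padj_model(lfc, cfg.null_sd_log2),
                        study=study,
                        species="mouse",
                    )
                )

    # --- human microRNA tables -------------------------------------------
    human_mirna: dict[str, list] = {s: [] for s in cfg.human_studies}
    for i, stem in enumerate(stems):
        for arm in _pattern_arms(patterns[i]):
            for study in cfg.human_studies:
                if i in mirrored:
                    lfc = directions[i] * cfg.effect_size_log2 + noise()
                else:
                    lfc = noise()
                human_mirna[study].append(
                    DERecord(
                        feature=mirna("hsa", stem, arm),
                        log2fc=lfc,
                        padj=_padj_model(lfc, cfg.null_sd_log2),
                        study=study,
                        species="human",
                    )
                )

    # --- genes: reserved pools per planted regulator ---------------------
    gene_names = [f"GN{i:04d}" for i in range(cfg.n_genes)]
    regulators = []  # (mature key, direction, mirna index)
    for i in mirrored_idx:
        for arm in _pattern_arms(patterns[i]):
            regulators.append((f"{stems[i]}-{arm}", directions[i], i))
    degrees = [max(1, int(rng.poisson(cfg.target_degree))) for _ in regulators]
    n_reserved = sum(degrees)
    if n_reserved > cfg.n_genes // 2:
        raise ValueError(
            f"config needs {n_reserved} reserved target genes but only "
            f"{cfg.n_genes // 2} (half of n_genes) are available; increase n_genes"
        )
    perm = list(rng.permutation(cfg.n_genes))
    reserved_slots = perm[:n_reserved]
    free_slots = perm[n_reserved:]

    gene_sign: dict[str, int] = {}
    planted_edges: set[tuple] = set()
    faithful_genes: list[str] = []
    cursor = 0
    for (mature_key, direction, _i), deg in zip(regulators, degrees):
        for slot in reserved_slots[cursor : cursor + deg]:
            gname = gene_names[slot]
            planted_edges.add((mature_key, gname))
            if rng.random() < cfg.anti_correlation_fidelity:
                gene_sign[gname] = -direction
                faithful_genes.append(gname)
            else:
                gene_sign[gname] = int(rng.choice([1, -1]))
        cursor += deg

    n_null_de = int(round(cfg.frac_null_genes_de * len(free_slots)))
    n_discord = int(round(cfg.frac_null_genes_discordant * len(free_slots)))
    null_de = [gene_names[s] for s in free_slots[:n_null_de]]
    discordant = [gene_names[s] for s in free_slots[n_null_de : n_null_de + n_discord]]
    null_plain = [gene_names[s] for s in free_slots[n_null_de + n_discord :]]
    for g in null_de:
        gene_sign[g] = int(rng.choice([1, -1]))

    gene_de: dict[str, list] = {s: [] for s in cfg.gene_studies}
    for gname in gene_names:
        for j, study in enumerate(cfg.gene_studies):
            if gname in gene_sign:  # reserved or concordant null-DE: significant
                lfc = gene_sign[gname] * cfg.effect_size_log2 + noise()
            elif gname in discordant:  # significant but flips sign across studies
                lfc = (1 if j % 2 == 0 else -1) * cfg.effect_size_log2 + noise()
            else:
                lfc = noise()
            gene_de[study].append(
                DERecord(
                    feature=GeneKey(gname, "human"),
                    log2fc=lfc,
                    padj=_padj_model(lfc, cfg.null_sd_log2),
                    study=study,
                    species="human",
                )
            )

    # --- validated target database ---------------------------------------
    targets: list[TargetInteraction] = []
    cursor = 0
    for (mature_key, _direction, i), deg in zip(regulators, degrees):
        mid = parse_mirna_name("hsa-" + mature_key)
        for slot in reserved_slots[cursor : cursor + deg]:
            targets.append(
                TargetInteraction(
                    mirna=mid,
                    gene=GeneKey(gene_names[slot], "human"),
                    evidence="Luciferase reporter assay",
                )
            )
        cursor += deg
    decoy_pool = null_de + null_plain
    for i, stem in enumerate(stems):
        if i in mirrored or not decoy_pool:
            continue
        arm = _pattern_arms(patterns[i])[0]
        deg = max(1, int(rng.poisson(cfg.target_degree)))
        picks = rng.choice(len(decoy_pool), size=min(deg, len(decoy_pool)), replace=False)
        for p in picks:
            targets.append(
                TargetInteraction(
                    mirna=mirna("hsa", stem, arm),
                    gene=GeneKey(decoy_pool[int(p)], "human"),
                    evidence="Western blot",
                )
            )

    # --- metabolite layer -------------------------------------------------
    met_names = [f"met{i:03d}" for i in range(cfg.n_metabolites)]
    uniq_faithful = sorted(set(faithful_genes))
    n_triplet = min(
        int(round(cfg.frac_triplet_genes * len(uniq_faithful))), cfg.n_metabolites
    )
    triplet_genes = (
        sorted(rng.choice(uniq_faithful, size=n_triplet, replace=False))
        if n_triplet
        else []
    )
    metabolites: list[MetaboliteRecord] = []
    gene_met_map: list[tuple] = []
    for j, met in enumerate(met_names):
        if j < len(triplet_genes):
            lfc = int(rng.choice([1, -1])) * cfg.effect_size_log2 + noise()
            gene_met_map.append((triplet_genes[j], met, "substrate"))
        else:
            lfc = noise()
        metabolites.append(
            MetaboliteRecord(
                metabolite=met,
                log2fc=lfc,
                padj=_padj_model(lfc, cfg.null_sd_log2),
                study="metabolomics",
            )
        )
    # negative-case adjacency: remaining faithful genes point at null metabolites
    spare_mets = met_names[len(triplet_genes) :]
    for j, gname in enumerate(g for g in uniq_faithful if g not in set(triplet_genes)):
        if not spare_mets:
            break
        gene_met_map.append((gname, spare_mets[j % len(spare_mets)], "product"))

    truth = GroundTruth(
        consensus_stems={stems[i]: ("up" if directions[i] > 0 else "down") for i in consistent_idx},
        cross_species_keys={
            key: ("up" if d > 0 else "down") for key, d, _ in regulators
        },
        connections=frozenset(planted_edges),
        triplets=frozenset(triplet_genes),
    )
    return Bundle(
        config=cfg,
        truth=truth,
        mouse_mirna=mouse_mirna,
        human_mirna=human_mirna,
        gene_de=gene_de,
        targets=targets,
        metabolites=metabolites,
        gene_metabolite_map=gene_met_map,
    )


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float


def _metrics(predicted: set, truth: set) -> RecoveryMetrics:
    # conventions: precision = 1 with no predictions, recall = 1 with empty truth
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth) if truth else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return RecoveryMetrics(precision=precision, recall=recall, f1=f1)


def evaluate_recovery(
    truth: GroundTruth,
    consensus=None,
    cross_species=None,
    connections=None,
    triplets=None,
) -> dict:
    """Set-overlap precision/recall/F1 per layer against the ground truth.

    Pass any subset of layers; each may be the corresponding pipeline output
    (ConsensusResult / CrossSpeciesCall list / ConsistentConnection list /
    TriOmicsTriplet list).
    """
    out = {}
    if consensus is not None:
        pred = {(c.stem, c.direction) for c in consensus}
        ref = set(truth.consensus_stems.items())
        out["consensus_stems"] = _metrics(pred, ref)
    if cross_species is not None:
        pred = {(c.mature_key, c.direction) for c in cross_species}
        ref = set(truth.cross_species_keys.items())
        out["cross_species"] = _metrics(pred, ref)
    if connections is not None:
        pred = {(c.mirna.mature_key, c.gene.match_key) for c in connections}
        ref = {(k, g.upper()) for k, g in truth.connections}
        out["connections"] = _metrics(pred, ref)
    if triplets is not None:
        pred = {t.gene.match_key for t in triplets}
        ref = {g.upper() for g in truth.triplets}
        out["triplets"] = _metrics(pred, ref)
    return out
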