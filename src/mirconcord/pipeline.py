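"""End-to-end orchestration: ingest -> gate/consensus -> connect -> report.

One :class:`RunConfig` drives a whole run.  Modes share the same machinery
on different inputs:

- ``human`` / ``diapause``: gate microRNAs and genes across the supplied
  per-study tables, build the anti-correlated connection network, optionally
  add tri-omics triplets (metabolite inputs) and enrichment (term map).
- ``mouse``: arm-combining consensus across the mouse study panel first,
  then the same connection machinery.
- ``cross_species``: human significance gate x mouse fold support.
- ``synthetic-demo``: generate a synthetic bundle, write it, run the human
  and mouse analyses on the written files, and score recovery against the
  bundled ground truth.

Every run writes a JSON manifest (tool version, config hash, per-stage row
counts) and a human-readable report.  All TSV outputs are byte-stable under
re-runs; only the manifest timestamp varies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as mio
from .consensus import (
    build_arm_profiles,
    call_mouse_consensus,
    cross_species_consensus,
)
from .enrichment import hypergeom_enrich, read_term_map
from .integration import (
    find_consistent_connections,
    find_triomics_triplets,
    gate_consistent_genes,
    gate_consistent_mirnas,
    summarize_network,
)
from .io import DERecord, DeTableSchema, read_de_table, read_metabolite_table, read_target_db
from .nomenclature import MirnaId
from .synthetic import SyntheticConfig, evaluate_recovery, generate_bundle

__all__ = ["RunConfig", "StageError", "run_pipeline"]

MODES = ("human", "mouse", "cross_species", "diapause", "synthetic-demo")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is stage-labeled."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one run needs.

    ``inputs`` maps logical names to paths / schema dicts:
    ``mirna_tables`` and ``gene_tables`` are lists of
    ``{"path": ..., **schema fields}``; ``target_db``,
    ``metabolite_table``, ``gene_metabolite_map``, ``term_map`` are
    optional single paths; ``mouse_mirna_tables`` mirrors ``mirna_tables``
    for the cross-species mode.
    """

    mode: str = "synthetic-demo"
    out_dir: str = "mirconcord_out"
    seed: int = 0
    alpha: float = 0.05
    fold_threshold: float = 1.5
    min_studies: int = 2
    min_term_size: int = 3
    inputs: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.fold_threshold < 1:
            raise ValueError(f"fold_threshold must be >= 1, got {self.fold_threshold}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self) -> None:
        """Fail before any stage runs if a referenced input is missing."""
        missing = []
        for key in ("target_db", "metabolite_table", "gene_metabolite_map", "term_map"):
            p = self.inputs.get(key)
            if p and not Path(p).exists():
                missing.append(f"{key}: {p}")
        for key in ("mirna_tables", "gene_tables", "mouse_mirna_tables"):
            for entry in self.inputs.get(key, []):
                if not Path(entry["path"]).exists():
                    missing.append(f"{key}: {entry['path']}")
        if missing:
            raise FileNotFoundError("missing input path(s): " + "; ".join(missing))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_tables(entries, default_type: str):
    """entries -> {study: [DERecord]} via per-entry schemas."""
    out = {}
    for entry in entries:
        entry = dict(entry)
        path = entry.pop("path")
        entry.setdefault("feature", "feature")
        entry.setdefault("log2fc", "log2fc")
        entry.setdefault("padj", "padj")
        entry.setdefault("feature_type", default_type)
        schema = DeTableSchema(**entry)
        load = read_de_table(path, schema)
        study = schema.study or Path(path).stem
        out[study] = list(load)
    return out


def _write_connections(path, connections):
    mio.write_records_tsv(
        path,
        [
            "miRNA",
            "gene",
            "miRNA_log2fc",
            "gene_log2fc",
            "miRNA_direction",
            "gene_direction",
            "evidence",
        ],
        [
            (
                str(c.mirna),
                str(c.gene),
                f"{c.mirna_log2fc:.4f}",
                f"{c.gene_log2fc:.4f}",
                c.mirna_direction,
                c.gene_direction,
                c.evidence,
            )
            for c in connections
        ],
    )


def _write_consensus(path, result):
    mio.write_records_tsv(
        path,
        ["stem", "direction", "criterion", "supporting_studies"],
        [
            (c.stem, c.direction, c.criterion, ";".join(sorted(c.supporting_studies)))
            for c in result.calls
        ],
    )


def _write_triplets(path, triplets):
    mio.write_records_tsv(
        path,
        ["gene", "gene_direction", "opposing_mirnas", "linked_metabolites"],
        [
            (
                str(t.gene),
                t.gene_direction,
                ";".join(sorted(t.opposing_mirnas)),
                ";".join(f"{m}({d},{'concordant' if c else 'discordant'})" for m, d, c in t.linked_metabolites),
            )
            for t in triplets
        ],
    )


def _write_enrichment(path, results):
    mio.write_records_tsv(
        path,
        ["term_id", "term_name", "k", "n", "K", "N", "p", "q"],
        [
            (r.term_id, r.term_name, r.k, r.n, r.K, r.N, f"{r.p:.6g}", f"{r.q:.6g}")
            for r in results
        ],
    )


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "tool_version": mio.TOOL_VERSION,
            "config_hash": config.config_hash(),
            "mode": config.mode,
            "stages": {},
            "completed": False,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.report_lines: list[str] = []

    def stage(self, name: str, fn):
        try:
            result = fn()
        except Exception as exc:  # annotate and abort
            self._flush()
            raise StageError(name, exc) from exc
        try:
            n = len(result)
        except TypeError:
            n = 1
        self.manifest["stages"][name] = {"rows": n}
        return result

    def _flush(self):
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
        with open(self.out / "report.txt", "w") as fh:
            fh.write("\n".join(self.report_lines) + "\n")

    def finish(self):
        self.manifest["completed"] = True
        self._flush()
        return self.manifest


def _network_stages(run: _Run, mirna_sig, gene_tables, target_db_path, cfg, species="human"):
    """Shared gate -> connect -> summarize -> (triplets, enrichment) block."""
    gated_genes = run.stage(
        "gene_gate", lambda: gate_consistent_genes(gene_tables, alpha=cfg.alpha)
    )
    targets = run.stage("target_db", lambda: list(read_target_db(target_db_path, species=species)))
    connections = run.stage(
        "connections",
        lambda: find_consistent_connections(mirna_sig, gated_genes, targets),
    )
    summary = summarize_network(connections)
    run.report_lines += [
        f"consistent connections: {summary.n_connections}",
        f"microRNAs connected:    {summary.n_mirnas}",
        f"target genes:           {summary.n_targets} "
        f"({summary.n_targets_up} up, {summary.n_targets_down} down)",
    ]
    _write_connections(run.out / "connections.tsv", connections)
    met_path = cfg.inputs.get("metabolite_table")
    map_path = cfg.inputs.get("gene_metabolite_map")
    triplets = []
    if met_path and map_path:
        import pandas as pd

        mets = list(read_metabolite_table(met_path))
        gm = pd.read_csv(map_path, sep="\t", comment="#")
        gm_rows = [tuple(r) for r in gm.itertuples(index=False)]
        triplets = run.stage(
            "triplets",
            lambda: find_triomics_triplets(
                gated_genes, connections, mets, gm_rows, alpha=cfg.alpha
            ),
        )
        _write_triplets(run.out / "triplets.tsv", triplets)
        run.report_lines.append(f"tri-omics triplets:     {len(triplets)}")
    term_path = cfg.inputs.get("term_map")
    if term_path:
        term_map, term_names = read_term_map(term_path)
        for direction in ("up", "down"):
            background = {
                r.feature.match_key for r in gated_genes
                if (r.log2fc > 0) == (direction == "up")
            }
            study = {
                c.gene.match_key for c in connections if c.gene_direction == direction
            }
            results = run.stage(
                f"enrichment_{direction}",
                lambda: hypergeom_enrich(
                    study, background, term_map,
                    min_term_size=cfg.min_term_size, term_names=term_names,
                ),
            )
            _write_enrichment(run.out / f"enrichment_{direction}.tsv", results)
    return gated_genes, connections, summary, triplets


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns the manifest dict."""
    cfg = config
    run = _Run(cfg)
    if cfg.mode != "synthetic-demo":
        cfg.validate_paths()

    if cfg.mode in ("human", "diapause"):
        mirna_tables = run.stage(
            "ingest_mirna", lambda: _read_tables(cfg.inputs["mirna_tables"], "mirna")
        )
        gene_tables = run.stage(
            "ingest_genes", lambda: _read_tables(cfg.inputs["gene_tables"], "gene")
        )
        if len(mirna_tables) >= 2:
            mirna_sig = run.stage(
                "mirna_gate",
                lambda: gate_consistent_mirnas(mirna_tables, alpha=cfg.alpha),
            )
        else:
            (only,) = mirna_tables.values()
            mirna_sig = [
                r for r in only if r.padj is not None and r.padj < cfg.alpha and r.observed
            ]
            run.manifest["stages"]["mirna_gate"] = {"rows": len(mirna_sig)}
        _network_stages(run, mirna_sig, gene_tables, cfg.inputs["target_db"], cfg)

    elif cfg.mode == "mouse":
        mirna_tables = run.stage(
            "ingest_mirna", lambda: _read_tables(cfg.inputs["mirna_tables"], "mirna")
        )
        all_records = [r for recs in mirna_tables.values() for r in recs]
        profiles = run.stage("arm_profiles", lambda: build_arm_profiles(all_records))
        result = run.stage(
            "consensus",
            lambda: call_mouse_consensus(
                profiles, fc_threshold=cfg.fold_threshold, min_studies=cfg.min_studies
            ),
        )
        _write_consensus(run.out / "consensus.tsv", result)
        run.report_lines.append(f"consensus microRNAs:    {len(result)}")
        mirna_sig = _consensus_records(result, profiles)
        gene_tables = run.stage(
            "ingest_genes", lambda: _read_tables(cfg.inputs["gene_tables"], "gene")
        )
        _network_stages(
            run, mirna_sig, gene_tables, cfg.inputs["target_db"], cfg, species="mouse"
        )

    elif cfg.mode == "cross_species":
        human_tables = run.stage(
            "ingest_human", lambda: _read_tables(cfg.inputs["mirna_tables"], "mirna")
        )
        mouse_tables = run.stage(
            "ingest_mouse",
            lambda: _read_tables(cfg.inputs["mouse_mirna_tables"], "mirna"),
        )
        human_records = [r for recs in human_tables.values() for r in recs]
        mouse_records = [r for recs in mouse_tables.values() for r in recs]
        calls = run.stage(
            "cross_species",
            lambda: cross_species_consensus(
                human_records, mouse_records,
                fc_threshold=cfg.fold_threshold, alpha=cfg.alpha,
            ),
        )
        mio.write_records_tsv(
            run.out / "cross_species.tsv",
            ["mature_key", "direction", "supporting_mouse_studies"],
            [
                (c.mature_key, c.direction, ";".join(sorted(c.supporting_mouse_studies)))
                for c in calls
            ],
        )
        run.report_lines.append(f"cross-species microRNAs: {len(calls)}")

    elif cfg.mode == "synthetic-demo":
        syn_cfg = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic})
        bundle = run.stage("simulate", lambda: _bundle_as_len1(generate_bundle(syn_cfg)))[0]
        bundle_dir = run.out / "bundle"
        paths = bundle.write(bundle_dir)
        # run from the written files, exercising the full I/O path
        human_tables = {
            s: list(read_de_table(paths[f"human_mirna_{s}"], _std_schema("mirna", s, "human")))
            for s in syn_cfg.human_studies
        }
        gene_tables = {
            s: list(read_de_table(paths[f"gene_{s}"], _std_schema("gene", s, "human")))
            for s in syn_cfg.gene_studies
        }
        mouse_tables = {
            s: list(read_de_table(paths[f"mouse_mirna_{s}"], _std_schema("mirna", s, "mouse")))
            for s in syn_cfg.mouse_studies
        }
        mirna_sig = run.stage(
            "mirna_gate", lambda: gate_consistent_mirnas(human_tables, alpha=cfg.alpha)
        )
        cfg.inputs.setdefault("metabolite_table", str(paths["metabolites"]))
        cfg.inputs.setdefault("gene_metabolite_map", str(paths["gene_metabolite_map"]))
        gated, connections, summary, triplets = _network_stages(
            run, mirna_sig, gene_tables, paths["targets"], cfg
        )
        profiles = run.stage(
            "arm_profiles",
            lambda: build_arm_profiles([r for recs in mouse_tables.values() for r in recs]),
        )
        consensus = run.stage(
            "consensus",
            lambda: call_mouse_consensus(
                profiles, fc_threshold=cfg.fold_threshold, min_studies=cfg.min_studies
            ),
        )
        _write_consensus(run.out / "consensus.tsv", consensus)
        xsp = run.stage(
            "cross_species",
            lambda: cross_species_consensus(
                [r for recs in human_tables.values() for r in recs],
                [r for recs in mouse_tables.values() for r in recs],
                fc_threshold=cfg.fold_threshold, alpha=cfg.alpha,
            ),
        )
        metrics = evaluate_recovery(
            bundle.truth,
            consensus=consensus,
            cross_species=xsp,
            connections=connections,
            triplets=triplets,
        )
        run.report_lines.append(f"mouse consensus stems:  {len(consensus)}")
        run.report_lines.append(f"cross-species forms:    {len(xsp)}")
        for layer, m in metrics.items():
            run.report_lines.append(
                f"recovery[{layer}]: precision={m.precision:.3f} recall={m.recall:.3f}"
            )
        run.manifest["recovery"] = {
            layer: {"precision": m.precision, "recall": m.recall, "f1": m.f1}
            for layer, m in metrics.items()
        }

    return run.finish()


def _std_schema(feature_type: str, study: str, species: str) -> DeTableSchema:
    return DeTableSchema(
        feature="feature",
        log2fc="log2fc",
        padj="padj",
        feature_type=feature_type,
        species=species,
        study=study,
    )


def _bundle_as_len1(bundle):
    return [bundle]


def _consensus_records(result, profiles) -> list:
    """Representative DERecords for called stems (for connection building).

    The called arm's mean log2FC over supporting studies stands in for the
    stem's effect; cross-arm calls contribute both arms.
    """
    out: list[DERecord] = []
    for call in result.calls:
        prof = profiles[call.stem]
        arms = (
            ("3p",)
            if call.criterion == "3p_two_studies"
            else ("5p",)
            if call.criterion == "5p_two_studies"
            else ("3p", "5p")
        )
        for arm in arms:
            vals = [
                prof.by_study[s].log2fc(arm)
                for s in call.supporting_studies
                if prof.by_study.get(s) and prof.by_study[s].log2fc(arm) is not None
            ]
            if not vals:
                continue
            out.append(
                DERecord(
                    feature=MirnaId(species_prefix="", stem=call.stem, arm=arm),
                    log2fc=sum(vals) / len(vals),
                    padj=0.0,
                    study="consensus",
                    species="mouse",
                )
            )
    return out
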