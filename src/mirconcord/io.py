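"""Readers and writers for differential-expression, target-interaction and
metabolite tables.

All tables are delimited text with a header.  Column roles (feature, log2
fold-change, adjusted p) are mapped through a :class:`DeTableSchema`, which
also declares the source's species and its fold-change sign convention.
Every stored log2FC follows one convention: positive means higher in the
first condition of the contrast (naive, or diapause); sources reporting the
opposite ratio are sign-flipped on ingest.

A log2FC recorded as exactly 0 is treated downstream as "not observed in
that study" rather than as evidence of no change — public per-study tables
use 0.00 to pad microRNAs absent from a study's list.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .nomenclature import GeneKey, MirnaId, MirnaParseError, parse_mirna_name

__all__ = [
    "DERecord",
    "TargetInteraction",
    "MetaboliteRecord",
    "DeTableSchema",
    "LoadReport",
    "TableLoad",
    "read_de_table",
    "write_de_table",
    "read_target_db",
    "read_metabolite_table",
    "filter_low_expression",
    "write_records_tsv",
]

TOOL_VERSION = "0.1.0"

Feature = Union[MirnaId, GeneKey]


@dataclass(frozen=True)
class DERecord:
    """One feature's differential-expression result in one study."""

    feature: Feature
    log2fc: float
    padj: Optional[float]
    study: str
    species: str = "human"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for {self.feature}")
        if self.padj is not None and not (0.0 <= self.padj <= 1.0):
            raise ValueError(f"padj out of [0,1] for {self.feature}: {self.padj}")

    @property
    def observed(self) -> bool:
        """False when log2FC == 0, the not-observed sentinel."""
        return self.log2fc != 0.0


@dataclass(frozen=True)
class TargetInteraction:
    """One experimentally validated miRNA -> gene edge (mirTarBase-style)."""

    mirna: MirnaId
    gene: GeneKey
    evidence: str = ""
    source_row_id: str = ""


@dataclass(frozen=True)
class MetaboliteRecord:
    """One metabolite's abundance change, same sign convention as DERecord."""

    metabolite: str
    log2fc: float
    padj: Optional[float]
    study: str = ""
    significant_flag: Optional[bool] = None

    def is_significant(self, alpha: float = 0.05) -> bool:
        if self.significant_flag is not None:
            return self.significant_flag
        return self.padj is not None and self.padj < alpha


@dataclass
class LoadReport:
    """Bookkeeping from one table read: totals, skips, and why."""

    path: str = ""
    n_rows: int = 0
    n_loaded: int = 0
    n_skipped: int = 0
    skipped: list = field(default_factory=list)  # (line_number, reason)

    def note_skip(self, line: int, reason: str) -> None:
        self.n_skipped += 1
        self.skipped.append((line, reason))


class TableLoad(Sequence):
    """A loaded table: sequence of records plus its :class:`LoadReport`."""

    def __init__(self, records: list, report: LoadReport):
        self.records = records
        self.report = report

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __repr__(self) -> str:
        return f"TableLoad({len(self.records)} records, {self.report.n_skipped} skipped)"


@dataclass
class DeTableSchema:
    """Column mapping and source conventions for one DE table.

    ``sign_convention`` is ``"first_over_second"`` (stored as-is) or
    ``"second_over_first"`` (log2FC negated on ingest so the stored value is
    always first-condition-over-second).
    """

    feature: str
    log2fc: str
    padj: Optional[str] = None
    feature_type: str = "mirna"  # "mirna" | "gene"
    species: str = "human"
    study: str = ""
    sign_convention: str = "first_over_second"
    delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sign_convention not in ("first_over_second", "second_over_first"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")
        if self.feature_type not in ("mirna", "gene"):
            raise ValueError(f"unknown feature type {self.feature_type!r}")

    @classmethod
    def from_yaml(cls, path) -> "DeTableSchema":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


_NA_TOKENS = {"", "na", "nan", "n/a", "null", "none", "."}


def _parse_float(value, allow_missing: bool) -> Optional[float]:
    if value is None:
        if allow_missing:
            return None
        raise ValueError("missing value")
    s = str(value).strip()
    if s.lower() in _NA_TOKENS:
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(s)


def _sniff_delimiter(path: Path, declared: Optional[str]) -> str:
    if declared:
        return declared
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_frame(path: Path, delimiter: Optional[str]) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=_sniff_delimiter(path, delimiter),
        comment="#",
        dtype=str,
        keep_default_na=False,
    )


def read_de_table(path, schema: DeTableSchema) -> TableLoad:
    """Read one differential-expression table into canonical records.

    Rows whose numeric fields cannot be parsed, or whose feature name cannot
    be canonicalized, are skipped and counted in the load report with their
    line number.  A missing mapped column is a configuration error.
    """
    path = Path(path)
    frame = _read_frame(path, schema.delimiter)
    needed = [schema.feature, schema.log2fc] + ([schema.padj] if schema.padj else [])
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise KeyError(f"{path}: schema maps absent column(s) {missing}")
    flip = schema.sign_convention == "second_over_first"
    report = LoadReport(path=str(path), n_rows=len(frame))
    records: list[DERecord] = []
    study = schema.study or path.stem
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            if schema.feature_type == "mirna":
                feat: Feature = parse_mirna_name(row[schema.feature])
            else:
                feat = GeneKey(row[schema.feature], schema.species)
            lfc = _parse_float(row[schema.log2fc], allow_missing=False)
            padj = (
                _parse_float(row[schema.padj], allow_missing=True)
                if schema.padj
                else None
            )
            records.append(
                DERecord(
                    feature=feat,
                    log2fc=-lfc if flip else lfc,
                    padj=padj,
                    study=study,
                    species=schema.species,
                )
            )
        except (ValueError, MirnaParseError) as exc:
            report.note_skip(idx, str(exc))
    report.n_loaded = len(records)
    return TableLoad(records, report)


def _header_comment(params: Optional[Mapping] = None) -> str:
    line = f"# mirconcord v{TOOL_VERSION}"
    if params:
        line += " | " + " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return line + "\n"


def write_de_table(records: Iterable[DERecord], path, params: Optional[Mapping] = None) -> None:
    """Write records as TSV (stable column order, header comment).

    Round-trips bit-for-bit through :func:`read_de_table` for finite values:
    floats are serialized with :func:`repr`, which is exact for doubles.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        fh.write("feature\tlog2fc\tpadj\tstudy\tspecies\n")
        for r in records:
            padj = "NA" if r.padj is None else repr(r.padj)
            fh.write(f"{r.feature}\t{repr(r.log2fc)}\t{padj}\t{r.study}\t{r.species}\n")


_MIRNA_COLS = {"mirna", "miRNA".lower(), "microrna", "mir"}
_GENE_COLS = {"target gene", "target_gene", "targetgene", "gene", "target", "gene symbol"}
_EVIDENCE_COLS = {"support type", "support_type", "evidence", "experiments"}
_ROWID_COLS = {"mirtarbase id", "mirtarbase_id", "id", "row_id"}


def _find_col(columns, candidates) -> Optional[str]:
    for c in columns:
        if c.strip().lower() in candidates:
            return c
    return None


def read_target_db(path, species: str = "human", delimiter: Optional[str] = None) -> TableLoad:
    """Read a validated miRNA->target table (mirTarBase-export dialect).

    Edges are canonicalized and deduplicated on (miRNA, gene); evidence tags
    from duplicate rows are merged (sorted, ``;``-joined).  Rows whose miRNA
    name cannot be parsed are skipped and counted.  Output is independent of
    input row order.
    """
    path = Path(path)
    frame = _read_frame(path, delimiter)
    report = LoadReport(path=str(path), n_rows=len(frame))
    if frame.empty:
        warnings.warn(f"{path}: empty target database")
        return TableLoad([], report)
    mirna_col = _find_col(frame.columns, _MIRNA_COLS)
    gene_col = _find_col(frame.columns, _GENE_COLS)
    if mirna_col is None or gene_col is None:
        raise KeyError(
            f"{path}: could not locate miRNA/target columns among {list(frame.columns)}"
        )
    ev_col = _find_col(frame.columns, _EVIDENCE_COLS)
    id_col = _find_col(frame.columns, _ROWID_COLS)
    merged: dict[tuple, dict] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            mirna = parse_mirna_name(row[mirna_col])
            gene = GeneKey(row[gene_col], species)
        except (ValueError, MirnaParseError) as exc:
            report.note_skip(idx, str(exc))
            continue
        key = (mirna, gene)
        slot = merged.setdefault(key, {"evidence": set(), "row_id": ""})
        if ev_col and str(row[ev_col]).strip():
            slot["evidence"].add(str(row[ev_col]).strip())
        if id_col and not slot["row_id"]:
            slot["row_id"] = str(row[id_col]).strip()
    edges = [
        TargetInteraction(
            mirna=m,
            gene=g,
            evidence=";".join(sorted(slot["evidence"])),
            source_row_id=slot["row_id"],
        )
        for (m, g), slot in sorted(merged.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    ]
    report.n_loaded = len(edges)
    return TableLoad(edges, report)


def read_metabolite_table(
    path,
    metabolite_col: str = "metabolite",
    log2fc_col: str = "log2fc",
    padj_col: Optional[str] = "padj",
    study: str = "",
    delimiter: Optional[str] = None,
) -> TableLoad:
    """Read a metabolite fold-change table.

    Metabolite names must be unique after case-folding; duplicates raise.
    """
    path = Path(path)
    frame = _read_frame(path, delimiter)
    report = LoadReport(path=str(path), n_rows=len(frame))
    records: list[MetaboliteRecord] = []
    seen: dict[str, str] = {}
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        name = str(row[metabolite_col]).strip()
        folded = name.casefold()
        if folded in seen:
            raise ValueError(
                f"{path}: duplicate metabolite {name!r} (seen as {seen[folded]!r})"
            )
        seen[folded] = name
        try:
            lfc = _parse_float(row[log2fc_col], allow_missing=False)
            padj = (
                _parse_float(row[padj_col], allow_missing=True)
                if padj_col and padj_col in frame.columns
                else None
            )
        except ValueError as exc:
            report.note_skip(idx, str(exc))
            continue
        records.append(
            MetaboliteRecord(metabolite=name, log2fc=lfc, padj=padj, study=study)
        )
    report.n_loaded = len(records)
    return TableLoad(records, report)


def filter_low_expression(counts: pd.DataFrame, quantile_q: float = 0.4) -> pd.Index:
    """Drop genes whose total read count falls below the q-th quantile.

    The quantile of per-gene totals is computed with linear interpolation
    between order statistics (numpy's default convention); genes whose total
    is >= that cutoff survive.  With tied totals the whole tie group shares
    one fate.

    Parameters
    ----------
    counts : DataFrame
        gene x sample nonnegative counts, genes as the index.
    quantile_q : float
        Quantile in (0, 1); 0.4 reproduces a 40th-percentile prefilter.
    """
    if not (0.0 < quantile_q < 1.0):
        raise ValueError(f"quantile_q must be in (0,1), got {quantile_q}")
    if counts.shape[0] < 1 or counts.shape[1] < 1:
        raise ValueError("counts table must have at least one gene and one sample")
    totals = counts.sum(axis=1)
    cutoff = float(np.quantile(totals.to_numpy(dtype=float), quantile_q))
    return counts.index[totals >= cutoff]


def write_records_tsv(path, header: Sequence[str], rows: Iterable[Sequence], params: Optional[Mapping] = None) -> None:
    """Generic stable TSV writer with the standard header comment."""
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
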