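"""Over-representation analysis against a custom background.

Asking "what do the microRNA-opposed targets do?" with the whole genome as
the universe mostly re-discovers that the targets are differentially
expressed.  The informative question restricts the background to all DE
genes: is a process over-represented among the *miRNA-targeted* DE genes
relative to DE genes at large?  The test is the standard upper-tail
hypergeometric (one-sided Fisher) per term, BH-corrected across terms; only
the background choice is non-standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrich",
    "adjust_bh",
    "read_term_map",
]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study-set genes annotated to the term
    n: int  # study-set size
    K: int  # background genes annotated to the term
    N: int  # background size
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(f"inconsistent contingency counts for {self.term_id}")


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving.

    Raises on any input outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    study_set: AbstractSet[str],
    background: AbstractSet[str],
    term_map: Mapping[str, AbstractSet[str]],
    min_term_size: int = 3,
    term_names: Optional[Mapping[str, str]] = None,
) -> list:
    """Upper-tail hypergeometric enrichment of ``study_set`` within ``background``.

    Study-set members outside the background are dropped with a warning and
    counted; term gene sets are intersected with the background before
    testing.  Terms with fewer than ``min_term_size`` background genes are
    skipped.  Results carry BH q-values across the tested terms and are
    sorted by (p, term_id).
    """
    if not background:
        raise ValueError("empty background")
    background = set(background)
    stray = set(study_set) - background
    if stray:
        warnings.warn(
            f"{len(stray)} study-set gene(s) outside the background were dropped"
        )
    study = set(study_set) & background
    n, N = len(study), len(background)
    rows = []
    for term_id in sorted(term_map):
        term_bg = set(term_map[term_id]) & background
        K = len(term_bg)
        if K < min_term_size:
            continue
        k = len(term_bg & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, k, K, min(p, 1.0)))
    if not rows:
        return []
    qvals = adjust_bh([r[3] for r in rows])
    names = term_names or {}
    results = [
        EnrichmentResult(
            term_id=term_id,
            term_name=names.get(term_id, term_id),
            k=k,
            n=n,
            K=K,
            N=N,
            p=p,
            q=float(q),
        )
        for (term_id, k, K, p), q in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def read_term_map(path, delimiter: str = "\t"):
    """Read a flat term map TSV: columns [term_id, term_name, gene].

    Returns (term_map, term_names): term_id -> gene set, term_id -> name.
    """
    import pandas as pd

    frame = pd.read_csv(path, sep=delimiter, comment="#", dtype=str)
    cols = list(frame.columns[:3])
    term_map: dict[str, set] = {}
    term_names: dict[str, str] = {}
    for tid, tname, gene in frame[cols].itertuples(index=False):
        term_map.setdefault(tid, set()).add(str(gene).strip().upper())
        term_names.setdefault(tid, str(tname))
    return term_map, term_names
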