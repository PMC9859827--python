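"""Over-representation analysis with Benjamini-Hochberg FDR.

Tests a query gene set against annotation terms (e.g. GO categories read
from a GMT file) by the upper-tail hypergeometric test, adjusts across
all tested terms with BH, and applies the reporting filter: a term is
reported when its FDR is <= 0.05 and it overlaps the query in two or
more genes (the alternative reading -- term size >= 2 -- is available
via ``min_count_on``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "read_gmt",
    "hypergeometric_enrichment",
    "bh_fdr",
]


@dataclass
class AnnotationSet:
    term_id: str
    term_name: str
    annotated_genes: frozenset[str]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    n_universe: int
    n_term: int
    n_query: int
    n_overlap: int
    p_value: float
    fdr: float
    reported: bool
    overlap_genes: frozenset[str]


def read_gmt(path) -> list[AnnotationSet]:
    """Read GMT: term, description, then tab-separated gene ids."""
    out: list[AnnotationSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: GMT line needs >= 3 fields")
            term, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if term in seen:
                raise ValueError(f"{path}:{line_no}: duplicate term id {term!r}")
            seen.add(term)
            out.append(AnnotationSet(term, name, frozenset(genes)))
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeometric_enrichment(
    query: set[str],
    universe: set[str],
    annotations: list[AnnotationSet],
    *,
    fdr_cut: float = 0.05,
    min_count: int = 2,
    min_count_on: str = "overlap",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of a query set against each term.

    Per term: population = universe size, successes = term genes within
    the universe, draws = query size; p = P(X >= observed overlap). BH
    adjusts across all tested terms; ``reported`` is True when fdr <=
    ``fdr_cut`` and the term clears ``min_count`` genes (counted on the
    query overlap by default, or on the in-universe term size with
    ``min_count_on='term'``).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    stray = set(query) - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)}")
    if min_count_on not in ("overlap", "term"):
        raise ValueError("min_count_on must be 'overlap' or 'term'")
    M = len(universe)
    N = len(query)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for ann in annotations:
        term_genes = ann.annotated_genes & universe
        K = len(term_genes)
        overlap = term_genes & set(query)
        k = len(overlap)
        # P(X >= k) for X ~ Hypergeom(M, K, N); sf(k-1) is that upper tail
        p = float(stats.hypergeom.sf(k - 1, M, K, N)) if K else 1.0
        p = min(p, 1.0)
        pvals.append(p)
        results.append(
            EnrichmentResult(
                ann.term_id, ann.term_name, M, K, N, k, p, np.nan, False,
                frozenset(overlap),
            )
        )
    if results:
        fdrs = bh_fdr(pvals)
        for res, q in zip(results, fdrs):
            res.fdr = float(q)
            count = res.n_overlap if min_count_on == "overlap" else res.n_term
            res.reported = bool(res.fdr <= fdr_cut and count >= min_count)
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Results as a DataFrame sorted by fdr then p."""
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "term_name": [r.term_name for r in results],
            "n_universe": [r.n_universe for r in results],
            "n_term": [r.n_term for r in results],
            "n_query": [r.n_query for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "reported": [r.reported for r in results],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in results],
        }
    )
    return df.sort_values(["fdr", "p_value", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
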