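"""Expression matrix I/O, the expression filter, and DEG set logic.

The container couples a gene x sample table (raw counts and/or TPM) with
per-sample metadata (model-system group, binary focus flag). Filtering
follows the edgeR-style rule: keep a gene when its CPM clears a threshold
in at least n samples, n being the smallest group size. DEG sets apply
strict |LFC| and FDR cuts to externally fitted differential-expression
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DEResultTable",
    "read_expression",
    "write_expression",
    "log1p_tpm",
    "filter_by_expression",
    "read_de_table",
    "deg_sets",
    "overlap_sets",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with sample annotations.

    Parameters
    ----------
    metadata
        DataFrame indexed by sample id with at least columns ``group``
        (model-system label) and ``is_focus`` (bool contrast flag).
    counts, tpm
        Gene x sample DataFrames sharing gene index and sample columns;
        at least one must be present.
    """

    metadata: pd.DataFrame
    counts: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts is None and self.tpm is None:
            raise ValueError("at least one of counts/tpm must be present")
        ref = self.counts if self.counts is not None else self.tpm
        if ref.index.has_duplicates:
            dups = ref.index[ref.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if ref.columns.has_duplicates:
            dups = ref.columns[ref.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample ids: {dups}")
        for name, mat in (("counts", self.counts), ("tpm", self.tpm)):
            if mat is None:
                continue
            if not mat.index.equals(ref.index) or not mat.columns.equals(ref.columns):
                raise ValueError("counts and tpm must share gene index and sample columns")
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"{name} contains negative values")
        if self.counts is not None:
            arr = self.counts.to_numpy()
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
        missing = [s for s in ref.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        extra = [s for s in self.metadata.index if s not in ref.columns]
        if extra:
            raise ValueError(f"metadata samples missing from matrix: {extra}")
        # align metadata rows to matrix column order
        self.metadata = self.metadata.loc[list(ref.columns)]
        for col in ("group", "is_focus"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        self.metadata["is_focus"] = self.metadata["is_focus"].astype(bool)

    @property
    def gene_ids(self) -> list[str]:
        ref = self.counts if self.counts is not None else self.tpm
        return list(ref.index)

    @property
    def sample_ids(self) -> list[str]:
        ref = self.counts if self.counts is not None else self.tpm
        return list(ref.columns)

    def restrict_genes(self, gene_ids) -> "ExpressionMatrix":
        """New matrix restricted to the given genes (order preserved)."""
        gene_ids = list(gene_ids)
        return ExpressionMatrix(
            metadata=self.metadata.copy(),
            counts=None if self.counts is None else self.counts.loc[gene_ids],
            tpm=None if self.tpm is None else self.tpm.loc[gene_ids],
        )


@dataclass
class DEResultTable:
    """Differential-expression results: one row per gene with lfc and fdr."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"gene_id", "lfc", "fdr"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"DE table needs columns {sorted(required)}")
        if self.table["gene_id"].duplicated().any():
            dups = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicated gene ids in DE table: {dups}")
        fdr = self.table["fdr"].dropna()
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValueError("fdr values must lie in [0, 1]")


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell in {path}: gene {row!r}, sample {col!r}"
            )
    return df.apply(pd.to_numeric)


def read_expression(
    matrix_path,
    metadata_path,
    *,
    kind: str = "tpm",
    counts_path=None,
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene_id) plus metadata TSV.

    ``kind`` names what the matrix at ``matrix_path`` holds ("tpm" or
    "counts"); ``counts_path`` optionally supplies a second matrix so both
    layers are populated.
    """
    if kind not in ("tpm", "counts"):
        raise ValueError("kind must be 'tpm' or 'counts'")
    mat = _read_matrix_tsv(matrix_path)
    meta = pd.read_csv(metadata_path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {metadata_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    if "is_focus" in meta.columns and meta["is_focus"].dtype == object:
        meta["is_focus"] = meta["is_focus"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
    layers = {kind: mat}
    if counts_path is not None:
        layers["counts"] = _read_matrix_tsv(counts_path)
    return ExpressionMatrix(
        metadata=meta,
        counts=layers.get("counts"),
        tpm=layers.get("tpm"),
    )


def write_expression(
    m: ExpressionMatrix,
    matrix_path,
    metadata_path=None,
    *,
    kind: str = "tpm",
) -> None:
    """Write one expression layer (and optionally metadata) as TSV."""
    mat = m.tpm if kind == "tpm" else m.counts
    if mat is None:
        raise ValueError(f"matrix has no {kind} layer")
    out = mat.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    if metadata_path is not None:
        meta = m.metadata.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t")


def log1p_tpm(m: ExpressionMatrix) -> pd.DataFrame:
    """Natural-log ``log(TPM + 1)`` transform; zeros stay exactly zero."""
    if m.tpm is None:
        raise ValueError("expression matrix has no TPM layer")
    return np.log1p(m.tpm)


def _cpm(counts: pd.DataFrame) -> pd.DataFrame:
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return counts / libsize * 1e6


def filter_by_expression(
    m: ExpressionMatrix,
    cpm_threshold: float = 10.0,
    *,
    group_column: str = "group",
) -> ExpressionMatrix:
    """Keep genes with CPM >= threshold in at least n samples.

    n is the smallest group sample size (groups taken from
    ``metadata[group_column]``). Samples are unchanged; gene order is
    preserved. Idempotent.
    """
    if m.counts is None:
        raise ValueError("expression filter requires raw counts")
    if m.counts.shape[0] == 0 or m.counts.shape[1] == 0:
        raise ValueError("empty expression matrix")
    groups = m.metadata[group_column]
    sizes = groups.value_counts()
    if sizes.empty:
        raise ValueError("no groups present in metadata")
    n = int(sizes.min())
    cpm = _cpm(m.counts)
    keep = (cpm >= cpm_threshold).sum(axis=1) >= n
    return m.restrict_genes(m.counts.index[keep])


def read_de_table(path) -> DEResultTable:
    """Read a TSV with columns gene_id, lfc, fdr."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    return DEResultTable(df)


def deg_sets(
    t: DEResultTable,
    lfc_cut: float = 0.5,
    fdr_cut: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split genes into up/down DEG sets using strict cuts.

    up: lfc > lfc_cut and fdr < fdr_cut; down: lfc < -lfc_cut and
    fdr < fdr_cut. Rows with missing FDR are treated as non-significant.
    """
    df = t.table
    if df.empty:
        raise ValueError("DE table is empty")
    sig = df["fdr"].notna() & (df["fdr"] < fdr_cut)
    up = set(df.loc[sig & (df["lfc"] > lfc_cut), "gene_id"])
    down = set(df.loc[sig & (df["lfc"] < -lfc_cut), "gene_id"])
    return up, down


def overlap_sets(named_sets: Mapping[str, set]) -> dict[frozenset, set]:
    """Venn-style exclusive regions for >= 2 named gene sets.

    Returns a map from a frozenset of set names S to the genes that are in
    every set of S and in no other set. Region memberships partition the
    union of all sets; empty regions are included with empty membership.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("overlap_sets requires at least 2 sets")
    regions: dict[frozenset, set] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(named_sets[n]) for n in combo))
            outside = set.union(
                set(), *(set(named_sets[n]) for n in names if n not in combo)
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def write_overlap_tsv(regions: dict[frozenset, set], path) -> None:
    rows = []
    for combo in sorted(regions, key=lambda c: (len(c), sorted(c))):
        genes = sorted(regions[combo])
        rows.append(
            {
                "region": "&".join(sorted(combo)),
                "count": len(genes),
                "genes": ",".join(genes),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
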