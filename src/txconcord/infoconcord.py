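"""Information-weighted Pearson correlation and its pseudo-distance.

Sample-to-sample Pearson correlation of log1p expression is weighted by
the information shared between the two samples' presence/absence
patterns: the Jaccard index of presence (shared-present over
present-in-either) and the completeness (fraction of genes with
concordant presence/absence status). The default weight is their
product; 1 - weighted correlation is the pseudo-distance handed to
hierarchical clustering. The pseudo-distance is symmetric with a zero
diagonal but is not guaranteed to satisfy the triangle inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConcordanceMatrix",
    "presence_mask",
    "jaccard",
    "completeness",
    "weighted_pearson",
    "concordance_matrix",
]

COMBINERS = ("product", "jaccard-only", "completeness-only")


@dataclass
class ConcordanceMatrix:
    """All pairwise sample-concordance components.

    Each field is a symmetric sample x sample DataFrame. ``weighted_r`` =
    ``pearson_r`` * ``weight``; ``pseudo_distance`` = 1 - ``weighted_r``.
    ``flags`` marks degenerate pairs (zero-variance or all-absent
    samples) whose Pearson r is undefined and recorded as 0.
    """

    pearson_r: pd.DataFrame
    jaccard: pd.DataFrame
    completeness: pd.DataFrame
    weight: pd.DataFrame
    weighted_r: pd.DataFrame
    pseudo_distance: pd.DataFrame
    combiner: str = "product"
    flags: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.pearson_r.index)


def presence_mask(tpm: pd.DataFrame) -> pd.DataFrame:
    """Boolean mask: a gene is present in a sample iff its TPM > 0."""
    arr = tpm.to_numpy()
    if (arr < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return tpm > 0


def _check_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("masks must have length >= 1")
    return a, b


def jaccard(mask_i, mask_j) -> float:
    """Shared-present over present-in-either; empty union gives 0."""
    a, b = _check_pair(mask_i, mask_j)
    both = int(np.sum(a & b))
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return both / union


def completeness(mask_i, mask_j) -> float:
    """Fraction of genes with concordant presence/absence status."""
    a, b = _check_pair(mask_i, mask_j)
    return float(np.sum(a == b) / a.size)


def _combine(j: float, c: float, combiner: str) -> float:
    if combiner == "product":
        return j * c
    if combiner == "jaccard-only":
        return j
    if combiner == "completeness-only":
        return c
    raise ValueError(f"unknown combiner {combiner!r}; choose from {COMBINERS}")


def weighted_pearson(
    logtpm_i,
    logtpm_j,
    mask_i,
    mask_j,
    *,
    combiner: str = "product",
    copresent_only: bool = False,
) -> tuple[float, float, float]:
    """(pearson_r, weight, weighted_r) for one sample pair.

    Pearson r is computed over ALL entries of the log1p vectors (zeros
    included) unless ``copresent_only`` restricts it to genes present in
    both samples. weight = Jaccard x completeness by default. A
    zero-variance vector leaves r undefined (NaN) and weighted_r = 0.
    """
    x, y = _check_pair(np.asarray(logtpm_i, float), np.asarray(logtpm_j, float))
    if x.size < 3:
        raise ValueError("need at least 3 entries for a correlation")
    a, b = _check_pair(mask_i, mask_j)
    w = _combine(jaccard(a, b), completeness(a, b), combiner)
    if copresent_only:
        sel = a & b
        x, y = x[sel], y[sel]
    if x.size < 2 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan"), w, 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return r, w, r * w


def concordance_matrix(
    logtpm: pd.DataFrame,
    tpm: pd.DataFrame,
    *,
    combiner: str = "product",
    copresent_only: bool = False,
) -> ConcordanceMatrix:
    """All pairwise concordance components over the selected transcripts.

    ``logtpm`` and ``tpm`` are gene x sample (same index/columns); the
    presence masks come from ``tpm`` > 0 while the correlation uses
    ``logtpm``. Degenerate pairs (zero variance, all-absent) are flagged
    and given weighted_r = 0, distance 1 rather than raising, so
    clustering can proceed.
    """
    if logtpm.shape[0] == 0:
        raise ValueError("empty transcript selection")
    if logtpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if not logtpm.index.equals(tpm.index) or not logtpm.columns.equals(tpm.columns):
        raise ValueError("logtpm and tpm must share index and columns")
    if combiner not in COMBINERS:
        raise ValueError(f"unknown combiner {combiner!r}; choose from {COMBINERS}")

    samples = list(logtpm.columns)
    n = len(samples)
    G = logtpm.shape[0]
    M = presence_mask(tpm).to_numpy()  # genes x samples
    Mi = M.astype(np.int64)
    both_present = Mi.T @ Mi
    present = Mi.sum(axis=0)
    union = present[:, None] + present[None, :] - both_present
    both_absent = G - union
    with np.errstate(invalid="ignore"):
        J = np.where(union > 0, both_present / np.maximum(union, 1), 0.0)
    C = (both_present + both_absent) / G
    if combiner == "product":
        W = J * C
    elif combiner == "jaccard-only":
        W = J.copy()
    else:
        W = C.copy()

    X = logtpm.to_numpy(dtype=float)
    sd = X.std(axis=0)
    flags = np.full((n, n), "", dtype=object)
    if copresent_only:
        R = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i, n):
                sel = M[:, i] & M[:, j]
                xi, xj = X[sel, i], X[sel, j]
                if xi.size >= 2 and np.std(xi) > 0 and np.std(xj) > 0:
                    R[i, j] = R[j, i] = np.corrcoef(xi, xj)[0, 1]
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(X.T)
        R = np.asarray(R, dtype=float)
        R[sd == 0, :] = np.nan
        R[:, sd == 0] = np.nan

    WR = np.where(np.isnan(R), 0.0, R) * W
    degenerate = np.isnan(R)
    flags[degenerate] = "degenerate"
    D = 1.0 - WR
    np.fill_diagonal(D, np.where(present > 0, 0.0, D.diagonal()))
    for i in range(n):
        if present[i] > 0:
            WR[i, i] = 1.0
            D[i, i] = 0.0

    def df(arr):
        return pd.DataFrame(arr, index=samples, columns=samples)

    return ConcordanceMatrix(
        pearson_r=df(R),
        jaccard=df(J),
        completeness=df(C),
        weight=df(W),
        weighted_r=df(WR),
        pseudo_distance=df(D),
        combiner=combiner,
        flags=df(flags),
    )
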