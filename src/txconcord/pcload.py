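"""PCA of log-TPM with group ANOVA on scores and empirical-null loading tests.

The decomposition is prcomp-equivalent: samples are observations,
transcripts variables, per-transcript centering, no scaling, SVD of the
centered matrix. Each PC's sample scores are tested for association with
a sample grouping by one-way ANOVA. A transcript's loading on a PC is
assigned an empirical P value against the pool of loadings from all the
other PCs (the cross-PC null): the fraction of same-sign null loadings
that are more extreme than the tested loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCADecomposition",
    "PCAssociation",
    "LoadingSignificance",
    "pca_decompose",
    "pc_group_association",
    "loading_significance",
    "select_significant",
]


@dataclass
class PCADecomposition:
    """Sample scores, transcript loadings and explained-variance fractions.

    ``scores`` is sample x PC, ``loadings`` transcript x PC with unit-norm
    columns; ``scores @ loadings.T`` reconstructs the centered input.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: pd.Series
    center: pd.Series

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class PCAssociation:
    pc_index: int
    F_statistic: float
    p_value: float
    group_means: dict
    degenerate: bool = False


@dataclass
class LoadingSignificance:
    transcript_id: str
    pc_index: int
    loading: float
    direction: str
    p_value: float
    null_size: int
    flag: str = ""


def pca_decompose(logtpm: pd.DataFrame) -> PCADecomposition:
    """PCA of a gene x sample matrix (samples as observations).

    Per-transcript centering, no variance scaling; number of PCs is
    min(n_samples - 1, n_transcripts). Each PC's sign is fixed so its
    largest-magnitude loading is positive.
    """
    if logtpm.shape[1] < 2 or logtpm.shape[0] < 2:
        raise ValueError("need at least 2 samples and 2 transcripts")
    X = logtpm.to_numpy(dtype=float).T  # samples x transcripts
    center = X.mean(axis=0)
    Xc = X - center
    if not np.any(Xc):
        raise ValueError("matrix has zero total variance")
    n_samples, n_transcripts = X.shape
    k = min(n_samples - 1, n_transcripts)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| entry of each PC is positive
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    pcs = [f"PC{j + 1}" for j in range(k)]
    frac = s**2 / np.sum(s**2)
    return PCADecomposition(
        scores=pd.DataFrame(scores, index=logtpm.columns, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=logtpm.index, columns=pcs),
        explained_variance_fraction=pd.Series(frac, index=pcs),
        center=pd.Series(center, index=logtpm.index),
    )


def pc_group_association(
    scores: pd.DataFrame, groups
) -> list[PCAssociation]:
    """One-way ANOVA of each PC's sample scores across groups.

    ``groups`` is a per-sample label sequence (booleans give the binary
    focus-vs-other contrast). F = (SSB/(k-1)) / (SSW/(N-k)); p is the
    upper tail of F(k-1, N-k). SSW = 0 with SSB > 0 is reported as a
    degenerate perfect separation with p = 0.
    """
    labels = np.asarray(list(groups))
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("groups must label every sample")
    levels, inverse = np.unique(labels, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least two nonempty groups")
    N = scores.shape[0]
    k = len(levels)
    if N < 3:
        raise ValueError("need at least 3 samples")
    out: list[PCAssociation] = []
    for j, pc in enumerate(scores.columns):
        y = scores[pc].to_numpy(dtype=float)
        grand = y.mean()
        ssb = ssw = 0.0
        means: dict = {}
        for li, level in enumerate(levels):
            yy = y[inverse == li]
            m = yy.mean()
            means[level.item() if hasattr(level, "item") else level] = float(m)
            ssb += len(yy) * (m - grand) ** 2
            ssw += float(np.sum((yy - m) ** 2))
        if ssw == 0.0:
            if ssb > 0.0:
                out.append(
                    PCAssociation(j + 1, float("inf"), 0.0, means, degenerate=True)
                )
            else:
                out.append(PCAssociation(j + 1, 0.0, 1.0, means, degenerate=True))
            continue
        F = (ssb / (k - 1)) / (ssw / (N - k))
        p = float(stats.f.sf(F, k - 1, N - k))
        out.append(PCAssociation(j + 1, float(F), p, means))
    return out


def loading_significance(
    loadings: pd.DataFrame,
    pc_index: int,
    exclude_self: bool = True,
) -> list[LoadingSignificance]:
    """Empirical P values for each transcript's loading on one PC.

    The null pool is every loading in the other PCs; with
    ``exclude_self`` (default) the tested transcript's own rows are
    removed from the pool. For loading L > 0,
    p = #{null > L} / #{null > 0}; for L < 0, p = #{null < L} / #{null < 0}.
    L = 0 yields p = 1 (flagged ``zero-loading``); an empty same-sign null
    yields p = 0 (flagged ``small-null``).

    ``pc_index`` is 1-based, matching PC column names.
    """
    n_pcs = loadings.shape[1]
    if n_pcs < 2:
        raise ValueError("need at least 2 PCs to form a cross-PC null")
    if loadings.shape[0] < 2:
        raise ValueError("need at least 2 transcripts")
    if not 1 <= pc_index <= n_pcs:
        raise ValueError(f"pc_index {pc_index} out of range 1..{n_pcs}")
    L = loadings.to_numpy(dtype=float)
    tested = L[:, pc_index - 1]
    others = np.delete(L, pc_index - 1, axis=1)  # transcripts x (P-1)
    flat = others.ravel()
    pos_sorted = np.sort(flat[flat > 0])
    neg_sorted = np.sort(flat[flat < 0])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)

    results: list[LoadingSignificance] = []
    for t, tid in enumerate(loadings.index):
        val = float(tested[t])
        own = others[t]
        if val > 0:
            direction = "positive"
            exceed = n_pos - int(np.searchsorted(pos_sorted, val, side="right"))
            null_n = n_pos
            if exclude_self:
                exceed -= int(np.sum(own > val))
                null_n -= int(np.sum(own > 0))
        elif val < 0:
            direction = "negative"
            exceed = int(np.searchsorted(neg_sorted, val, side="left"))
            null_n = n_neg
            if exclude_self:
                exceed -= int(np.sum(own < val))
                null_n -= int(np.sum(own < 0))
        else:
            results.append(
                LoadingSignificance(
                    str(tid), pc_index, 0.0, "positive", 1.0, 0, "zero-loading"
                )
            )
            continue
        if null_n == 0:
            results.append(
                LoadingSignificance(
                    str(tid), pc_index, val, direction, 0.0, 0, "small-null"
                )
            )
            continue
        results.append(
            LoadingSignificance(
                str(tid), pc_index, val, direction, exceed / null_n, null_n
            )
        )
    return results


def select_significant(
    sig: list[LoadingSignificance], alpha: float = 0.05
) -> set[str]:
    """Transcripts whose loading P value is <= alpha (inclusive)."""
    return {s.transcript_id for s in sig if s.p_value <= alpha}


def significance_table(sig: list[LoadingSignificance]) -> pd.DataFrame:
    """Loading-significance results as a tidy DataFrame."""
    return pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sig],
            "pc": [s.pc_index for s in sig],
            "loading": [s.loading for s in sig],
            "direction": [s.direction for s in sig],
            "p_value": [s.p_value for s in sig],
            "null_size": [s.null_size for s in sig],
            "flag": [s.flag for s in sig],
        }
    )


def association_table(assocs: list[PCAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pc": [a.pc_index for a in assocs],
            "F": [a.F_statistic for a in assocs],
            "p_value": [a.p_value for a in assocs],
            "degenerate": [a.degenerate for a in assocs],
        }
    )
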