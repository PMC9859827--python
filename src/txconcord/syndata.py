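"""Synthetic bulk RNA-seq experiments with planted group structure.

Generates gene x sample count matrices that mimic a multi-model-system
tumor experiment (e.g. bulk tumor, sorted tumor cells, 2D lines, 3D
tumoroids):

* lognormal gene baseline means and lognormal library-size factors;
* negative-binomial counts (variance = mu + mu^2 * dispersion);
* group-specific expression shifts on a shared planted gene subset:
  every group carries its own random per-gene sign pattern over the
  signal genes, the focus group at the full log2 ``signal_shift``
  amplitude and the non-focus groups at a configurable fraction of it
  (default one half). Group mean profiles are therefore mutually
  decorrelated on the planted genes -- each model system has its own
  expression signature -- while the focus group's larger amplitude
  dominates the leading variance direction;
* dropout (exact zeros) injected AFTER count sampling as an independent
  Bernoulli mask whose per-gene propensity follows a U-shaped Beta
  quantile map over the expression rank: zeros concentrate in lowly
  expressed genes and presence/absence patterns are consistent across
  samples, the structure real RNA-seq zeros have and that the
  information-weighted correlation exploits. The mean propensity in a
  group equals that group's configured dropout rate exactly.

Ground truth (planted genes, per-gene sign, group of every sample) is
returned alongside the matrix so every downstream stage can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from txconcord.exprio import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_experiment",
    "expected_zero_fraction",
    "counts_to_tpm",
    "counts_to_cpm",
]

# default layout mirrors a four-system design (bulk tumor / sorted tumor /
# 2D lines / 3D tumoroids) scaled to 6 samples per group for desk speed;
# the 2D-culture group is the focus contrast
DEFAULT_GROUPS: tuple[tuple[str, int, bool], ...] = (
    ("tumor", 6, False),
    ("sorted", 6, False),
    ("2D", 6, True),
    ("3D", 6, False),
)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic experiment.

    Attributes
    ----------
    n_genes
        Number of genes simulated.
    groups
        Sequence of ``(group_label, n_samples, is_focus)``; the focus
        flags define the binary contrast tested downstream.
    frac_signal_genes
        Fraction of genes planted with the group factor, in [0, 1].
    signal_shift
        Log2-scale mean shift (>= 0) applied to signal genes in
        focus-group samples (times a random per-gene sign); non-focus
        groups receive ``nonfocus_shift_fraction`` of it with their own
        sign patterns.
    nonfocus_shift_fraction
        Amplitude of the non-focus groups' shifts relative to
        ``signal_shift``, in [0, 1].
    nb_dispersion
        Negative-binomial dispersion phi > 0 (variance = mu + mu^2*phi).
    libsize_log_mean, libsize_log_sd
        Natural-log parameters of the per-sample lognormal library-size
        factor.
    dropout_rate_per_group
        Map group_label -> marginal dropout probability in [0, 1].
        Missing groups default to 0.2.
    gene_length_range
        Inclusive (min, max) gene length in bases, uniform per gene.
    basemean_log_mean, basemean_log_sd
        Natural-log parameters of the lognormal gene baseline mean.
    dropout_shape
        Beta concentration (> 0) of the per-gene dropout propensity:
        small values push propensities toward 0 or 1 (consistent
        presence patterns), large values toward a uniform rate.
    signal_min_expression_quantile
        Planted genes are drawn from genes above this baseline-
        expression quantile (markers are reliably detected genes).
    seed
        Seed making generation fully reproducible.
    """

    n_genes: int = 2000
    groups: tuple[tuple[str, int, bool], ...] = DEFAULT_GROUPS
    frac_signal_genes: float = 0.10
    signal_shift: float = 2.0
    nonfocus_shift_fraction: float = 0.5
    nb_dispersion: float = 0.05
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.25
    dropout_rate_per_group: dict[str, float] = field(default_factory=dict)
    gene_length_range: tuple[int, int] = (200, 10_000)
    basemean_log_mean: float = 4.6
    basemean_log_sd: float = 1.5
    dropout_shape: float = 0.1
    signal_min_expression_quantile: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be a positive integer")
        if len(self.groups) < 2:
            raise ValueError("groups must list at least two groups")
        labels = [g[0] for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("groups must have unique labels")
        for label, n, _ in self.groups:
            if n < 1:
                raise ValueError(f"groups: group {label!r} needs n_samples >= 1")
        if not any(g[2] for g in self.groups):
            raise ValueError("groups must flag at least one focus group")
        if all(g[2] for g in self.groups):
            raise ValueError("groups must leave at least one non-focus group")
        if not 0.0 <= self.frac_signal_genes <= 1.0:
            raise ValueError("frac_signal_genes must lie in [0, 1]")
        if self.signal_shift < 0:
            raise ValueError("signal_shift must be >= 0")
        if not 0.0 <= self.nonfocus_shift_fraction <= 1.0:
            raise ValueError("nonfocus_shift_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for label, rate in self.dropout_rate_per_group.items():
            if label not in labels:
                raise ValueError(f"dropout_rate_per_group: unknown group {label!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(
                    f"dropout_rate_per_group[{label!r}] must lie in [0, 1]"
                )
        lo, hi = self.gene_length_range
        if lo < 1 or hi < lo:
            raise ValueError("gene_length_range must be positive with min <= max")
        if self.libsize_log_sd < 0 or self.basemean_log_sd < 0:
            raise ValueError("lognormal sd parameters must be >= 0")
        if self.dropout_shape <= 0:
            raise ValueError("dropout_shape must be > 0")
        if not 0.0 <= self.signal_min_expression_quantile < 1.0:
            raise ValueError("signal_min_expression_quantile must lie in [0, 1)")

    def dropout_rate(self, group: str) -> float:
        return self.dropout_rate_per_group.get(group, 0.2)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment.

    ``group_sign`` maps each group label to its per-gene sign pattern
    (+1 up, -1 down) over the planted genes; ``signal_gene_sign`` is the
    focus group's pattern (the direction of each planted gene in the
    focus contrast).
    """

    signal_gene_ids: set[str]
    signal_gene_sign: dict[str, int]
    group_sign: dict[str, dict[str, int]]
    group_of_sample: dict[str, str]
    focus_flag: dict[str, bool]


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and gene lengths.

    Per sample: rate_g = count_g / length_g, TPM_g = rate_g / sum(rate) * 1e6,
    so each column sums to 1e6.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"gene_lengths missing for genes: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    rate = counts.div(lengths.astype(float), axis=0)
    denom = rate.sum(axis=0)
    zero = denom[denom == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return rate / denom * 1e6


def counts_to_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: count / library size * 1e6; columns sum to 1e6."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return counts / libsize * 1e6


def _dropout_propensity(u: np.ndarray, rate: float, shape: float) -> np.ndarray:
    """Per-gene propensity = Beta(shape*rate, shape*(1-rate)) quantile at u."""
    if rate <= 0.0:
        return np.zeros_like(u)
    if rate >= 1.0:
        return np.ones_like(u)
    return stats.beta.ppf(u, shape * rate, shape * (1.0 - rate))


@dataclass
class _ExperimentParams:
    """Deterministic-from-seed layout shared by sampling and expectation."""

    gene_ids: list[str]
    sample_ids: list[str]
    sample_group: list[str]
    sample_focus: list[bool]
    lengths: pd.Series
    base_mean: np.ndarray
    dropout_quantile: np.ndarray  # per gene, rank-derived u in (0,1)
    signal_idx: np.ndarray
    group_sign: dict[str, np.ndarray]  # group -> +/-1 per signal gene
    lib_factor: np.ndarray
    mean: np.ndarray  # gene x sample NB mean


def _experiment_params(
    config: SyntheticConfig, rng: np.random.Generator
) -> _ExperimentParams:
    n_genes = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    sample_ids: list[str] = []
    sample_group: list[str] = []
    sample_focus: list[bool] = []
    for label, n, is_focus in config.groups:
        for j in range(n):
            sample_ids.append(f"{label}_{j + 1:02d}")
            sample_group.append(label)
            sample_focus.append(bool(is_focus))

    lo, hi = config.gene_length_range
    lengths = pd.Series(
        rng.integers(lo, hi + 1, size=n_genes), index=gene_ids, name="length"
    )
    base_mean = rng.lognormal(config.basemean_log_mean, config.basemean_log_sd, n_genes)
    lib_factor = rng.lognormal(
        config.libsize_log_mean, config.libsize_log_sd, len(sample_ids)
    )

    # dropout propensity follows expression rank: highest-expressed gene has
    # the smallest Beta quantile, so zeros concentrate in low-expression genes
    order = np.argsort(-base_mean, kind="stable")
    rank = np.empty(n_genes, dtype=float)
    rank[order] = np.arange(n_genes)
    dropout_quantile = (rank + 0.5) / n_genes

    n_signal = int(round(config.frac_signal_genes * n_genes))
    q = config.signal_min_expression_quantile
    eligible = np.flatnonzero(dropout_quantile <= 1.0 - q)
    if n_signal > len(eligible):
        raise ValueError(
            "frac_signal_genes too large for signal_min_expression_quantile"
        )
    signal_idx = rng.choice(eligible, size=n_signal, replace=False)
    group_sign = {
        label: rng.choice([-1, 1], size=n_signal) for label, _, _ in config.groups
    }

    mean = np.outer(base_mean, lib_factor)
    amplitude = {
        label: (1.0 if is_focus else config.nonfocus_shift_fraction)
        for label, _, is_focus in config.groups
    }
    group_cols = {
        label: [j for j, g in enumerate(sample_group) if g == label]
        for label, _, _ in config.groups
    }
    for label, _, _ in config.groups:
        fold = 2.0 ** (
            config.signal_shift * amplitude[label] * group_sign[label]
        )  # per signal gene
        cols = group_cols[label]
        mean[np.ix_(signal_idx, cols)] *= fold[:, None]
    return _ExperimentParams(
        gene_ids, sample_ids, sample_group, sample_focus, lengths, base_mean,
        dropout_quantile, signal_idx, group_sign, lib_factor, mean,
    )


def generate_experiment(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a synthetic experiment; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    par = _experiment_params(config, rng)

    phi = config.nb_dispersion
    r = 1.0 / phi
    p = r / (r + par.mean)
    counts = rng.negative_binomial(r, p)

    # dropout: independent Bernoulli zero-mask after count sampling
    for j, grp in enumerate(par.sample_group):
        rate = config.dropout_rate(grp)
        if rate > 0:
            prop = _dropout_propensity(par.dropout_quantile, rate,
                                       config.dropout_shape)
            mask = rng.random(config.n_genes) < prop
            counts[mask, j] = 0

    counts_df = pd.DataFrame(counts, index=par.gene_ids, columns=par.sample_ids)
    tpm_df = counts_to_tpm(counts_df, par.lengths)
    metadata = pd.DataFrame(
        {"group": par.sample_group, "is_focus": par.sample_focus},
        index=pd.Index(par.sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(metadata=metadata, counts=counts_df, tpm=tpm_df)
    signal_ids = [par.gene_ids[i] for i in par.signal_idx]
    group_sign = {
        label: dict(zip(signal_ids, (int(s) for s in signs)))
        for label, signs in par.group_sign.items()
    }
    focus_labels = [label for label, _, is_focus in config.groups if is_focus]
    truth = SyntheticTruth(
        signal_gene_ids=set(signal_ids),
        signal_gene_sign=dict(group_sign[focus_labels[0]]),
        group_sign=group_sign,
        group_of_sample=dict(zip(par.sample_ids, par.sample_group)),
        focus_flag=dict(zip(par.sample_ids, map(bool, par.sample_focus))),
    )
    return matrix, truth


def expected_zero_fraction(config: SyntheticConfig) -> dict[str, float]:
    """Exact expected zero fraction per group for ``config``.

    Recomputes the seed-determined gene layout and returns, per group,
    mean over genes and samples of
    ``propensity + (1 - propensity) * P(NB = 0)``.
    """
    rng = np.random.default_rng(config.seed)
    par = _experiment_params(config, rng)
    phi = config.nb_dispersion
    nb_zero = (1.0 + phi * par.mean) ** (-1.0 / phi)
    out: dict[str, float] = {}
    for label, _, _ in config.groups:
        cols = [j for j, g in enumerate(par.sample_group) if g == label]
        prop = _dropout_propensity(
            par.dropout_quantile, config.dropout_rate(label), config.dropout_shape
        )[:, None]
        out[label] = float(np.mean(prop + (1.0 - prop) * nb_zero[:, cols]))
    return out


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write ground truth as a long-form TSV (samples, then planted genes)."""
    rows = [
        {"kind": "sample", "id": s, "value": g, "extra": str(truth.focus_flag[s])}
        for s, g in sorted(truth.group_of_sample.items())
    ] + [
        {"kind": "signal_gene", "id": g, "value": str(truth.signal_gene_sign[g]),
         "extra": ""}
        for g in sorted(truth.signal_gene_ids)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
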