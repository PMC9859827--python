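"""PCA contracts, score ANOVA, and the cross-PC empirical loading null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import anova_f_oracle, loading_p_oracle
from txconcord.pcload import (
    loading_significance,
    pc_group_association,
    pca_decompose,
    select_significant,
)

# worked 4-transcript x 3-PC loading matrix used in several tests
EXAMPLE_LOADINGS = pd.DataFrame(
    {
        "PC1": [0.9, -0.1, 0.2, -0.6],
        "PC2": [0.1, 0.5, -0.3, 0.4],
        "PC3": [0.05, -0.2, 0.6, -0.1],
    },
    index=["t1", "t2", "t3", "t4"],
)


def _random_logtpm(rng, genes=40, samples=10):
    return pd.DataFrame(
        rng.gamma(2.0, 2.0, size=(genes, samples)),
        index=[f"g{i}" for i in range(genes)],
        columns=[f"s{j}" for j in range(samples)],
    )


class TestPcaDecompose:
    def test_orthonormal_loadings_and_reconstruction(self, rng):
        lg = _random_logtpm(rng)
        dec = pca_decompose(lg)
        V = dec.loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        centered = lg.to_numpy().T - dec.center.to_numpy()
        recon = dec.scores.to_numpy() @ V.T
        assert np.abs(recon - centered).max() < 1e-6
        assert dec.explained_variance_fraction.sum() <= 1 + 1e-8

    def test_single_varying_transcript(self):
        lg = pd.DataFrame(
            {"s1": [1.0, 5.0], "s2": [2.0, 5.0], "s3": [3.0, 5.0]},
            index=["var", "const"],
        )
        dec = pca_decompose(lg)
        assert dec.explained_variance_fraction.iloc[0] == pytest.approx(1.0)

    def test_hand_eigen_example(self):
        # two transcripts (0,1,2) and (0,2,4): covariance is rank one with
        # direction (1,2)/sqrt(5)
        lg = pd.DataFrame(
            {"s1": [0.0, 0.0], "s2": [1.0, 2.0], "s3": [2.0, 4.0]},
            index=["a", "b"],
        )
        dec = pca_decompose(lg)
        np.testing.assert_allclose(
            dec.loadings["PC1"].to_numpy(), [1 / np.sqrt(5), 2 / np.sqrt(5)],
            atol=1e-12,
        )

    def test_sign_convention_largest_loading_positive(self, rng):
        dec = pca_decompose(_random_logtpm(rng))
        for pc in dec.loadings.columns:
            col = dec.loadings[pc].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_component_count(self, rng):
        dec = pca_decompose(_random_logtpm(rng, genes=30, samples=8))
        assert dec.n_components == 7
        dec2 = pca_decompose(_random_logtpm(rng, genes=3, samples=8))
        assert dec2.n_components == 3

    def test_constant_matrix_rejected(self):
        lg = pd.DataFrame(np.ones((4, 5)))
        with pytest.raises(ValueError, match="variance"):
            pca_decompose(lg)


class TestGroupAssociation:
    def _scores(self, values):
        return pd.DataFrame({"PC1": values},
                            index=[f"s{i}" for i in range(len(values))])

    def test_equal_means_f_zero(self):
        res = pc_group_association(
            self._scores([1.0, 2.0, 1.0, 2.0]), [True, True, False, False]
        )
        assert res[0].F_statistic == pytest.approx(0.0)
        assert res[0].p_value == pytest.approx(1.0)

    def test_perfect_separation_degenerate(self):
        res = pc_group_association(
            self._scores([0.0, 0.0, 1.0, 1.0]), [True, True, False, False]
        )
        assert res[0].degenerate
        assert res[0].p_value == 0.0

    def test_hand_f_example(self):
        # groups (1,2,3) vs (2,3,4): F = 1.5 on (1, 4) df
        res = pc_group_association(
            self._scores([1.0, 2.0, 3.0, 2.0, 3.0, 4.0]),
            [True, True, True, False, False, False],
        )
        assert res[0].F_statistic == pytest.approx(1.5)
        assert res[0].p_value == pytest.approx(float(stats.f.sf(1.5, 1, 4)))

    def test_matches_sum_of_squares_oracle(self, rng):
        y = rng.normal(size=12)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2])
        res = pc_group_association(self._scores(y), labels)
        expected = anova_f_oracle([y[labels == g] for g in (0, 1, 2)])
        assert res[0].F_statistic == pytest.approx(expected)
        # and scipy's reference test agrees
        f_ref, p_ref = stats.f_oneway(*(y[labels == g] for g in (0, 1, 2)))
        assert res[0].F_statistic == pytest.approx(float(f_ref))
        assert res[0].p_value == pytest.approx(float(p_ref))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            pc_group_association(self._scores([1.0, 2.0, 3.0]),
                                 [True, True, True])


class TestLoadingSignificance:
    def test_worked_example_t3(self):
        res = {s.transcript_id: s for s in
               loading_significance(EXAMPLE_LOADINGS, 1)}
        # t3 (L = 0.2): null positives {0.1, 0.5, 0.4, 0.05}; two exceed
        assert res["t3"].p_value == pytest.approx(0.5)
        assert res["t3"].null_size == 4
        assert res["t3"].direction == "positive"

    def test_worked_example_t1_extreme(self):
        res = {s.transcript_id: s for s in
               loading_significance(EXAMPLE_LOADINGS, 1)}
        # t1 (L = 0.9) exceeds every same-sign null loading
        assert res["t1"].p_value == 0.0
        assert res["t1"].null_size == 3

    def test_negative_direction(self):
        res = {s.transcript_id: s for s in
               loading_significance(EXAMPLE_LOADINGS, 1)}
        # t4 (L = -0.6): null negatives {-0.3, -0.2, -0.1}; none below
        assert res["t4"].direction == "negative"
        assert res["t4"].p_value == 0.0

    @pytest.mark.parametrize("exclude_self", [True, False])
    def test_matches_counting_oracle(self, rng, exclude_self):
        for _ in range(25):
            n_t = int(rng.integers(3, 40))
            n_pc = int(rng.integers(2, 8))
            L = pd.DataFrame(
                rng.normal(size=(n_t, n_pc)),
                index=[f"t{i}" for i in range(n_t)],
                columns=[f"PC{j + 1}" for j in range(n_pc)],
            )
            pc = int(rng.integers(1, n_pc + 1))
            res = loading_significance(L, pc, exclude_self=exclude_self)
            for t, s in enumerate(res):
                p_exp, n_exp = loading_p_oracle(
                    L.to_numpy(), pc - 1, t, exclude_self
                )
                assert s.p_value == p_exp, (n_t, n_pc, pc, t)
                if s.flag == "":
                    assert s.null_size == n_exp

    def test_mirror_symmetry_under_full_negation(self, rng):
        # the directional test depends on each PC's sign convention, but
        # negating the whole loading matrix mirrors every test exactly
        L = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=[f"PC{j+1}" for j in range(5)])
        for pc in (1, 3):
            p0 = [s.p_value for s in loading_significance(L, pc)]
            p1 = [s.p_value for s in loading_significance(-L, pc)]
            assert p0 == p1

    def test_zero_loading_flagged(self):
        L = EXAMPLE_LOADINGS.copy()
        L.loc["t2", "PC1"] = 0.0
        res = {s.transcript_id: s for s in loading_significance(L, 1)}
        assert res["t2"].p_value == 1.0
        assert res["t2"].flag == "zero-loading"

    def test_single_pc_rejected(self):
        with pytest.raises(ValueError, match="PC"):
            loading_significance(EXAMPLE_LOADINGS[["PC1"]], 1)


class TestSelectSignificant:
    def test_inclusive_boundary(self):
        sig = loading_significance(EXAMPLE_LOADINGS, 1)
        for s in sig:
            s.p_value = {"t1": 0.05, "t2": 0.051, "t3": 0.2, "t4": 0.0}[
                s.transcript_id
            ]
        assert select_significant(sig, 0.05) == {"t1", "t4"}
        assert select_significant(sig, 0.0) == {"t4"}
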