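"""RV coefficient contracts: identities, oracle equivalence, permutation nulls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import lcms_like, nmr_like, study_config
from oracle_utils import rv_bruteforce
from ringdim import (
    ConfigError,
    DomainError,
    average_links,
    modified_rv,
    rv_coefficient,
    rv_matrix,
    rv_permutation_null,
    simulate_ring_study,
)
from ringdim.rv import RVMatrix


def centered(rng, n, p):
    X = rng.standard_normal((n, p))
    return X - X.mean(axis=0)


class TestIdentitiesAndInvariances:
    def test_self_rv_is_one_for_both_variants(self, rng):
        X = centered(rng, 12, 30)
        assert rv_coefficient(X, X) == pytest.approx(1.0, abs=1e-12)
        assert modified_rv(X, X) == pytest.approx(1.0, abs=1e-12)

    def test_rotation_invariance(self, rng):
        X = centered(rng, 10, 4)
        R, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        assert rv_coefficient(X, X @ R) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_and_range(self, rng):
        X, Y = centered(rng, 8, 5), centered(rng, 8, 7)
        assert rv_coefficient(X, Y) == rv_coefficient(Y, X)
        assert 0.0 <= rv_coefficient(X, Y) <= 1.0
        assert -1.0 <= modified_rv(X, Y) <= 1.0

    def test_zero_matrix_is_domain_error(self, rng):
        X = centered(rng, 5, 3)
        with pytest.raises(DomainError):
            rv_coefficient(X, np.zeros((5, 4)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        data=st.data(),
        a=st.floats(0.1, 10),
        b=st.floats(0.1, 10),
        sa=st.sampled_from([-1.0, 1.0]),
        sb=st.sampled_from([-1.0, 1.0]),
    )
    def test_scale_invariance(self, data, a, b, sa, sb):
        seed = data.draw(st.integers(0, 2**20))
        rng = np.random.default_rng(seed)
        X, Y = centered(rng, 6, 4), centered(rng, 6, 3)
        assert rv_coefficient(a * sa * X, b * sb * Y) == pytest.approx(
            rv_coefficient(X, Y), abs=1e-10
        )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**30), modified=st.booleans())
    def test_matches_bruteforce_oracle(self, seed, modified):
        rng = np.random.default_rng(seed)
        X = rng.integers(-5, 6, size=(5, 3)).astype(float)
        Y = rng.integers(-5, 6, size=(5, 3)).astype(float)
        if np.linalg.norm(X - X.mean(0)) < 1e-9 or np.linalg.norm(Y - Y.mean(0)) < 1e-9:
            return  # degenerate draw
        func = modified_rv if modified else rv_coefficient
        assert func(X, Y) == pytest.approx(
            rv_bruteforce(X, Y, modified=modified), abs=1e-10
        )

    def test_modified_rv_smaller_than_classic_on_independent_wide_tables(self):
        classic, mod = [], []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((30, 500))
            Y = rng.standard_normal((30, 800))
            classic.append(rv_coefficient(X, Y))
            mod.append(abs(modified_rv(X, Y)))
        assert np.mean(mod) < 0.1
        assert np.mean(classic) > np.mean(mod)


class TestRVMatrix:
    def test_identical_blocks_give_all_ones(self, rng):
        from test_preprocess import make_block

        values = rng.random((5, 6))
        blocks = [make_block(values, f"B{i}") for i in range(3)]
        rvm = rv_matrix(blocks)
        np.testing.assert_allclose(rvm.values, 1.0, atol=1e-12)

    def test_shape_symmetry_and_diagonals(self, high_contrast_study):
        blockset, _ = high_contrast_study
        for variant in ("classic", "modified"):
            rvm = rv_matrix(blockset, variant=variant)
            assert rvm.values.shape == (4, 4)
            np.testing.assert_allclose(rvm.values, rvm.values.T, atol=1e-12)
            np.testing.assert_allclose(np.diag(rvm.values), 1.0, atol=1e-9)

    def test_common_structure_raises_pairwise_rv_over_control(self):
        shared, _ = simulate_ring_study(study_config(n_individuals=8), seed=21)
        # control: same profiles rendered from two unrelated designs
        from ringdim import make_latent_design, render_block

        d1 = make_latent_design(8, "high", True, 0, seed=1)
        d2 = make_latent_design(8, "high", True, 0, seed=2)
        b1 = render_block(d1, nmr_like("N1", 150, seed=11))
        b2 = render_block(d2, lcms_like("Q1P", 200, seed=12))
        control = rv_coefficient(b1.values, b2.values)
        rvm = rv_matrix(shared)
        assert rvm.values[0, 1] > control

    def test_block_named_in_domain_error(self, rng):
        from test_preprocess import make_block

        blocks = [
            make_block(rng.random((4, 3)), "GOOD"),
            make_block(np.ones((4, 3)), "FLAT"),
        ]
        with pytest.raises(DomainError, match="FLAT"):
            rv_matrix(blocks)


class TestPermutationNull:
    def test_same_seed_reproduces_the_null(self, rng):
        X, Y = centered(rng, 10, 6), centered(rng, 10, 8)
        a = rv_permutation_null(X, Y, n_perm=120, seed=5)
        b = rv_permutation_null(X, Y, n_perm=120, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_identical_tables_exceed_every_null_draw(self, rng):
        X = centered(rng, 12, 10)
        null = rv_permutation_null(X, X, n_perm=150, seed=1)
        assert null.observed == pytest.approx(1.0, abs=1e-12)
        assert (null.values < null.observed).all()
        assert null.exceedance == 0.0

    def test_calibration_on_independent_tables(self):
        """Observed RV of independent tables falls inside the null's central
        90% band in at least 80% of seeded repeats."""
        inside = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(3000 + seed)
            X, Y = centered(rng, 15, 8), centered(rng, 15, 10)
            null = rv_permutation_null(X, Y, n_perm=199, seed=seed)
            lo, hi = np.quantile(null.values, [0.05, 0.95])
            inside += lo <= null.observed <= hi
        assert inside / reps >= 0.8

    def test_too_few_permutations_rejected(self, rng):
        X = centered(rng, 5, 3)
        with pytest.raises(ConfigError):
            rv_permutation_null(X, X, n_perm=99, seed=0)


class TestAverageLinks:
    def toy_matrix(self):
        ids = ["N1", "N2", "Q1", "Q2"]
        V = np.array(
            [
                [1.0, 0.8, 0.5, 0.6],
                [0.8, 1.0, 0.7, 0.4],
                [0.5, 0.7, 1.0, 0.9],
                [0.6, 0.4, 0.9, 1.0],
            ]
        )
        tech = {"N1": "NMR", "N2": "NMR", "Q1": "LCMS", "Q2": "LCMS"}
        return RVMatrix(ids, V, "classic"), tech

    def test_hand_computed_within_between_averages(self):
        rvm, tech = self.toy_matrix()
        links = average_links(rvm, tech)
        assert links.within["NMR"] == pytest.approx(0.8)
        assert links.within["LCMS"] == pytest.approx(0.9)
        assert links.between[("LCMS", "NMR")] == pytest.approx((0.5 + 0.6 + 0.7 + 0.4) / 4)
        assert links.per_block.loc["N1", "mean_all"] == pytest.approx((0.8 + 0.5 + 0.6) / 3)
        assert links.per_block.loc["N1", "mean_within"] == pytest.approx(0.8)
        assert links.per_block.loc["N1", "mean_between"] == pytest.approx(0.55)

    def test_constant_matrix_gives_constant_summaries(self):
        ids = ["A", "B", "C"]
        V = np.full((3, 3), 0.7)
        np.fill_diagonal(V, 1.0)
        links = average_links(RVMatrix(ids, V, "classic"), dict.fromkeys(ids, "NMR"))
        assert links.within["NMR"] == pytest.approx(0.7)
        np.testing.assert_allclose(links.per_block["mean_all"], 0.7, atol=1e-12)

    def test_block_order_permutation_leaves_summaries_unchanged(self):
        rvm, tech = self.toy_matrix()
        perm = [2, 0, 3, 1]
        rvm_p = RVMatrix(
            [rvm.block_ids[i] for i in perm],
            rvm.values[np.ix_(perm, perm)],
            "classic",
        )
        a, b = average_links(rvm, tech), average_links(rvm_p, tech)
        assert a.within == b.within and a.between == b.between

    def test_singleton_technology_has_no_within_average(self):
        ids = ["N1", "Q1", "Q2"]
        V = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.9], [0.6, 0.9, 1.0]])
        links = average_links(
            RVMatrix(ids, V, "classic"), {"N1": "NMR", "Q1": "LCMS", "Q2": "LCMS"}
        )
        assert "NMR" not in links.within
        assert np.isnan(links.per_block.loc["N1", "mean_within"])

    def test_missing_label_raises(self):
        rvm, tech = self.toy_matrix()
        tech.pop("Q2")
        with pytest.raises(ConfigError):
            average_links(rvm, tech)
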