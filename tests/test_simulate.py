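"""Generator contracts: design structure, rendering, and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from conftest import lcms_like, nmr_like, study_config
from ringdim import (
    ConfigError,
    PlatformProfile,
    make_latent_design,
    render_block,
    rv_coefficient,
    simulate_ring_study,
)
from ringdim.simulate import _render_block


class TestLatentDesign:
    def test_paired_design_counts_and_columns(self):
        d = make_latent_design(14, "high", paired_spike=True, n_outliers=2, seed=1)
        assert d.n_samples == 28
        assert d.factor_names.count("group") == 1
        assert sum(f.startswith("metabotype") for f in d.factor_names) == 11
        assert sum(f.startswith("outlier") for f in d.factor_names) == 2
        assert len(set(d.group_labels)) == 2
        # native and spiked sample per individual
        assert all(d.individual_ids.count(i) == 2 for i in set(d.individual_ids))

    def test_unpaired_design_counts(self):
        d = make_latent_design(9, "low", paired_spike=False, n_outliers=0, seed=7)
        assert d.n_samples == 9
        assert "group" in d.factor_names

    def test_contrast_none_has_no_group_factor_but_keeps_labels(self):
        d = make_latent_design(14, "none", paired_spike=True, n_outliers=0, seed=3)
        assert "group" not in d.factor_names
        assert sorted(set(d.group_labels)) == ["native", "spiked"]

    def test_group_column_is_two_valued_and_balanced(self):
        d = make_latent_design(10, "high", paired_spike=True, n_outliers=0, seed=2)
        g = d.latent_scores[:, d.factor_names.index("group")]
        assert len(np.unique(g)) == 2
        assert abs(g.mean()) < 1e-12

    def test_centered_columns_orthogonal_and_unit_variance(self):
        d = make_latent_design(14, "high", paired_spike=True, n_outliers=2, seed=11)
        Z = d.centered_scores()
        C = Z.T @ Z / d.n_samples
        assert np.allclose(np.diag(C), 1.0, atol=1e-10)
        names = d.factor_names
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                both_outliers = names[i].startswith("outlier") and names[j].startswith("outlier")
                if both_outliers:
                    # disjoint indicators cannot be exactly orthogonal after
                    # centering while staying zero off their support
                    assert abs(C[i, j]) < 0.15
                else:
                    assert abs(C[i, j]) < 1e-10, (names[i], names[j])

    def test_outlier_columns_zero_off_support(self):
        d = make_latent_design(12, "high", paired_spike=True, n_outliers=2, seed=5)
        ind = np.asarray(d.individual_ids)
        for j, name in enumerate(d.factor_names):
            if name.startswith("outlier"):
                col = d.latent_scores[:, j]
                k = int(name.split("_")[1]) - 1
                support = ind == d.outlier_individuals[k]
                assert np.all(col[~support] == 0)
                assert np.all(col[support] > 0)

    def test_dilution_and_specific_gravity_ranges(self):
        d = make_latent_design(14, "high", True, 0, seed=4, dilution_cv=0.3)
        assert np.all(d.dilution_factors > 0)
        assert np.all((d.specific_gravity > 1.0) & (d.specific_gravity <= 1.050))
        # pairs share the urine, hence the dilution
        dil = pd.Series(d.dilution_factors, index=d.individual_ids)
        assert dil.groupby(level=0).nunique().eq(1).all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_individuals": 2},
            {"n_individuals": 5, "n_outliers": 5},
            {"n_individuals": 5, "contrast": "huge"},
            {"n_individuals": 5, "seed": None},
        ],
    )
    def test_invalid_configurations_raise(self, kwargs):
        kwargs.setdefault("seed", 1)
        if kwargs.get("seed", 1) is None:
            kwargs["seed"] = None
        with pytest.raises(ConfigError):
            make_latent_design(**kwargs)


class TestRenderBlock:
    def test_noise_free_single_factor_block_has_rank_one(self):
        d = make_latent_design(4, "none", paired_spike=False, n_outliers=0, seed=1)
        profile = PlatformProfile(
            "X1", "NMR", n_features=5,
            variance_shares={"metabotype_01": 1.0}, noise_fraction=0.0, seed=2,
        )
        block = render_block(d, profile)
        centered = block.values - block.values.mean(axis=0)
        assert np.linalg.matrix_rank(centered, tol=1e-8) == 1

    def test_planted_variance_shares_recovered(self):
        """Realized per-factor variance shares match the profile within 0.05,
        averaged over seeds, for both an NMR-like and an LCMS-like lens."""
        shares = {"N": 0.7, "Q": 0.3}
        for tag, group_share in shares.items():
            realized = []
            for seed in range(10):
                d = make_latent_design(14, "high", True, 0, seed=100 + seed)
                profile = PlatformProfile(
                    tag, "NMR" if tag == "N" else "LCMS", n_features=500,
                    variance_shares={"group": group_share,
                                     "metabotype": round(0.9 - group_share, 12)},
                    noise_fraction=0.1, responds_to_spike=0.2, seed=200 + seed,
                )
                block = render_block(d, profile)
                X = block.values - block.values.mean(axis=0)
                g = d.centered_scores()[:, d.factor_names.index("group")]
                g = g / np.linalg.norm(g)
                realized.append(np.sum((X.T @ g) ** 2) / np.sum(X * X))
            assert abs(np.mean(realized) - group_share) < 0.05

    def test_spike_difference_only_on_carrier_features(self):
        d = make_latent_design(6, "high", paired_spike=True, n_outliers=0, seed=9)
        profile = PlatformProfile(
            "Q", "LCMS", n_features=50,
            variance_shares={"group": 0.5, "metabotype": 0.5},
            noise_fraction=0.0, responds_to_spike=0.2, seed=3,
        )
        block, _, spike_idx = _render_block(d, profile, np.random.default_rng(3))
        spiked = np.asarray(d.spiked)
        diff = block.values[spiked] - block.values[~spiked]  # paired order
        nonzero = np.nonzero(np.abs(diff).max(axis=0) > 1e-9)[0]
        assert set(nonzero) == set(spike_idx)

    def test_profile_factor_absent_from_design_raises(self):
        d = make_latent_design(5, "none", paired_spike=False, n_outliers=0, seed=1)
        profile = PlatformProfile(
            "Q", "LCMS", n_features=10,
            variance_shares={"group": 0.9}, noise_fraction=0.1, seed=1,
        )
        with pytest.raises(ConfigError, match="group"):
            render_block(d, profile)


class TestSimulateRingStudy:
    def test_same_seed_gives_identical_outputs(self):
        conf = study_config(dilution_cv=0.2)
        a, ta = simulate_ring_study(conf, seed=5)
        b, tb = simulate_ring_study(conf, seed=5)
        for ba, bb in zip(a, b):
            np.testing.assert_array_equal(ba.values, bb.values)
            assert ba.feature_ids == bb.feature_ids
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        assert ta.spike_features == tb.spike_features

    def test_appending_a_platform_leaves_existing_blocks_unchanged(self):
        conf = study_config()
        small, _ = simulate_ring_study(conf, seed=8)
        conf_big = study_config(
            profiles=[nmr_like("N1", 150), lcms_like("Q1P", 200), lcms_like("Q2P", 100)]
        )
        big, _ = simulate_ring_study(conf_big, seed=8)
        for ba, bb in zip(small, big):
            np.testing.assert_array_equal(ba.values, bb.values)

    def test_duplicate_instrument_id_raises(self):
        conf = study_config(profiles=[nmr_like("N1"), nmr_like("N1")])
        with pytest.raises(ConfigError, match="duplicate"):
            simulate_ring_study(conf, seed=1)

    def test_identical_profiles_and_seeds_give_rv_one(self):
        d = make_latent_design(6, "high", True, 0, seed=2)
        prof = dict(
            n_features=80, variance_shares={"group": 0.6, "metabotype": 0.3},
            noise_fraction=0.1, responds_to_spike=0.25,
        )
        b1 = render_block(d, PlatformProfile("A", "NMR", seed=7, **prof))
        b2 = render_block(d, PlatformProfile("B", "NMR", seed=7, **prof))
        np.testing.assert_array_equal(b1.values, b2.values)
        assert rv_coefficient(b1.values, b2.values) == pytest.approx(1.0, abs=1e-12)

    def test_feature_counts_follow_the_roster(self):
        profiles = [nmr_like(f"N{i}", 60 + 10 * i) for i in range(3)] + [
            lcms_like(f"Q{i}P", 100 + 25 * i) for i in range(4)
        ]
        conf = study_config(profiles=profiles)
        bs, truth = simulate_ring_study(conf, seed=3)
        assert [b.n_features for b in bs] == [p.n_features for p in profiles]
        assert len(bs) == 7
        # spike carriers recorded per block
        assert all(len(v) > 0 for v in truth.spike_features.values())
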