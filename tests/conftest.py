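"""Shared fixtures and study-configuration helpers for the test suite."""

import numpy as np
import pytest

from ringdim import BlockSet, PlatformProfile, simulate_ring_study


def nmr_like(instrument_id="N1", n_features=200, noise=0.10, seed=None, **kw):
    """NMR-like lens: most variance on the group contrast."""
    shares = {"group": 0.70, "metabotype": 0.20}
    shares.update(kw.pop("variance_shares", {}))
    return PlatformProfile(
        instrument_id=instrument_id,
        technology="NMR",
        ion_mode="none",
        n_features=n_features,
        variance_shares=shares,
        noise_fraction=round(1.0 - sum(shares.values()), 12),
        responds_to_spike=kw.pop("responds_to_spike", 0.2),
        seed=seed,
    )


def lcms_like(instrument_id="Q1P", n_features=300, noise=0.10, seed=None, **kw):
    """LC-MS-like lens: most variance on individual metabotypes."""
    shares = {"group": 0.30, "metabotype": 0.60}
    shares.update(kw.pop("variance_shares", {}))
    return PlatformProfile(
        instrument_id=instrument_id,
        technology="LCMS",
        ion_mode="pos",
        n_features=n_features,
        variance_shares=shares,
        noise_fraction=round(1.0 - sum(shares.values()), 12),
        responds_to_spike=kw.pop("responds_to_spike", 0.15),
        seed=seed,
    )


def study_config(
    n_individuals=8,
    contrast="high",
    paired_spike=True,
    n_outliers=0,
    dilution_cv=0.0,
    profiles=None,
):
    """Small ring-study configuration dict for fast end-to-end tests."""
    if profiles is None:
        profiles = [nmr_like("N1", 150), lcms_like("Q1P", 200)]
    return {
        "design": {
            "n_individuals": n_individuals,
            "contrast": contrast,
            "paired_spike": paired_spike,
            "n_outliers": n_outliers,
            "dilution_cv": dilution_cv,
        },
        "platforms": profiles,
    }


@pytest.fixture(scope="session")
def high_contrast_study() -> tuple[BlockSet, object]:
    """One paired high-contrast study shared by read-only tests."""
    conf = study_config(
        n_individuals=10,
        n_outliers=1,
        profiles=[
            nmr_like("N1", 180, variance_shares={"group": 0.65, "metabotype": 0.20, "outlier": 0.05}),
            nmr_like("N2", 120, variance_shares={"group": 0.60, "metabotype": 0.25, "outlier": 0.05}),
            lcms_like("Q1P", 250, variance_shares={"group": 0.30, "metabotype": 0.55, "outlier": 0.05}),
            lcms_like("Q2P", 300, variance_shares={"group": 0.25, "metabotype": 0.60, "outlier": 0.05}),
        ],
    )
    return simulate_ring_study(conf, seed=424242)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
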