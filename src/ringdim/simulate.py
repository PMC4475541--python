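"""Synthetic multi-platform ring-trial data generator.

Emulates the statistical structure of an inter-laboratory metabolomics ring
trial at the post-deconvolution feature-table level: a shared latent sample
design (a two-group contrast, per-individual metabotypes, planted outlier
individuals, urine-dilution variation) rendered through platform-specific
"lenses" (NMR-like vs LC-MS-like variance allocations, feature counts
spanning two orders of magnitude, instrument noise).

The generator is the test bed for the whole pipeline: every planted quantity
is recorded in a :class:`SimTruth` so that recovery can be measured.

Model
-----
Each block is a noisy factor model.  Let ``z_f`` be the centered,
unit-variance latent score columns of the design and ``l_f`` the per-block
loading vectors.  A feature column is

    x_j = sum_f l_jf * z_f + e_j,        e_j ~ N(0, noise_fraction)

with loading columns rescaled so that factor ``f`` carries exactly the
fraction ``variance_shares[f]`` of the block's expected total variance.
The matrix is shifted so the minimum intensity is zero (feature tables are
nonnegative) and rows are then multiplied by the per-sample dilution factor;
dilution correction followed by column centering removes the offset exactly.

In a paired spiking design the group contrast is realized entirely through
the spike: the group factor's loadings are nonzero only on the
spike-carrying feature subset, so the spiked-minus-native difference of a
noise-free pair is nonzero exactly on the spike carriers and, because the
group score is constant within each group, the spike acts as an additive
constant across all spiked samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import ION_MODES, TECHNOLOGIES, Block, BlockSet
from .errors import ConfigError

CONTRASTS = ("high", "low", "none")

#: factor-class prefixes recognised in variance_shares
FACTOR_CLASSES = ("group", "metabotype", "outlier")


# ---------------------------------------------------------------------------
# latent design
# ---------------------------------------------------------------------------


@dataclass
class LatentDesign:
    """Planted latent structure shared by all platforms of a study.

    ``latent_scores`` columns are, in order: the group contrast (absent when
    ``contrast == "none"``), the metabotype factors, and one indicator
    column per planted outlier individual.  Group and metabotype columns are
    centered with unit variance; outlier columns are stored as raw scaled
    indicators (zero except at the outlier's samples) and become centered,
    unit-variance columns once column-centered.

    After centering, columns are mutually orthogonal except between two
    outlier indicator columns (and, in unpaired designs with outliers,
    between the group column and an outlier column), where an O(1/n)
    residual correlation is unavoidable if the indicators are to stay zero
    off their support.
    """

    sample_ids: list[str]
    individual_ids: list[str]
    group_labels: list[str]
    factor_names: list[str]
    latent_scores: np.ndarray  # (n_samples, n_factors)
    dilution_factors: np.ndarray  # (n_samples,), > 0
    specific_gravity: np.ndarray  # (n_samples,), in (1.000, 1.050]
    spiked: np.ndarray  # (n_samples,) bool
    paired_spike: bool
    contrast: str
    outlier_individuals: list[str]
    sg_reference: float = 1.020

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_factors(self) -> int:
        return self.latent_scores.shape[1]

    def centered_scores(self) -> np.ndarray:
        """Latent score matrix with every column mean-centered."""
        Z = self.latent_scores
        return Z - Z.mean(axis=0, keepdims=True)

    def factor_classes(self) -> dict[str, list[int]]:
        """Map each factor class present in the design to its column indices."""
        out: dict[str, list[int]] = {}
        for i, name in enumerate(self.factor_names):
            cls = name.split("_")[0]
            out.setdefault(cls, []).append(i)
        return out

    def metadata_frame(self) -> pd.DataFrame:
        """Sample-metadata table (group, individual, pair, specific gravity)."""
        pair = self.individual_ids if self.paired_spike else [""] * self.n_samples
        return pd.DataFrame(
            {
                "individual": self.individual_ids,
                "group": self.group_labels,
                "pair": pair,
                "specific_gravity": self.specific_gravity,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def _unit_variance(v: np.ndarray) -> np.ndarray:
    sd = v.std()  # population convention throughout the generator
    if sd == 0:
        raise ConfigError("degenerate latent column with zero variance")
    return v / sd


def make_latent_design(
    n_individuals: int,
    contrast: str = "high",
    paired_spike: bool = True,
    n_outliers: int = 0,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    dilution_cv: float = 0.0,
    sg_reference: float = 1.020,
) -> LatentDesign:
    """Build the planted latent design of a ring study.

    Parameters
    ----------
    n_individuals:
        Number of biological individuals (>= 3).  With ``paired_spike`` each
        contributes a native and a spiked sample, giving ``2 * n_individuals``
        samples; otherwise one sample each.
    contrast:
        ``"high"`` or ``"low"`` plants a two-group contrast factor;
        ``"none"`` keeps the group labels (pairing or a balanced split) but
        plants no group-aligned latent factor, so any downstream
        group separation is a false positive.
    n_outliers:
        Number of individuals given a dedicated outlier factor
        (must be < ``n_individuals``).
    dilution_cv:
        Coefficient of variation of the per-sample (per-individual when
        paired) lognormal dilution factors; 0 disables dilution variation.
    sg_reference:
        Reference specific gravity; sample specific gravities are generated
        as ``1 + (sg_reference - 1) * dilution``, clipped to (1.000, 1.050],
        so specific-gravity normalization at the reference removes the
        planted dilution.
    """
    if n_individuals < 3:
        raise ConfigError(f"n_individuals must be >= 3, got {n_individuals}")
    if contrast not in CONTRASTS:
        raise ConfigError(f"contrast must be one of {CONTRASTS}, got {contrast!r}")
    if not 0 <= n_outliers < n_individuals:
        raise ConfigError(
            f"n_outliers must satisfy 0 <= n_outliers < n_individuals, "
            f"got {n_outliers} with {n_individuals} individuals"
        )
    if seed is None:
        raise ConfigError("a seed is required for a reproducible design")
    if dilution_cv < 0:
        raise ConfigError("dilution_cv must be >= 0")
    if not 1.0 < sg_reference <= 1.050:
        raise ConfigError("sg_reference must lie in (1.000, 1.050]")
    rng = np.random.default_rng(seed)

    individuals = [f"I{i + 1:02d}" for i in range(n_individuals)]
    outlier_pick = sorted(rng.choice(n_individuals, size=n_outliers, replace=False))
    outlier_individuals = [individuals[i] for i in outlier_pick]

    if paired_spike:
        sample_ids = []
        individual_ids = []
        group_labels = []
        spiked = []
        for ind in individuals:
            sample_ids += [f"{ind}-native", f"{ind}-spiked"]
            individual_ids += [ind, ind]
            group_labels += ["native", "spiked"]
            spiked += [False, True]
    else:
        sample_ids = list(individuals)
        individual_ids = list(individuals)
        group_labels = ["low" if i % 2 == 0 else "high" for i in range(n_individuals)]
        spiked = [g == "high" for g in group_labels]
    n = len(sample_ids)
    spiked = np.asarray(spiked, dtype=bool)
    ind_arr = np.asarray(individual_ids)

    columns: list[np.ndarray] = []
    names: list[str] = []

    # group contrast: two-valued, centered and unit-variance by construction
    if contrast != "none":
        raw = np.where(spiked, 1.0, -1.0)
        g = _unit_variance(raw - raw.mean())
        # keep two-valuedness: standardization of a two-valued vector is
        # two-valued
        columns.append(g)
        names.append("group")

    # outlier indicators: raw scaled indicators, zero off their support
    outlier_cols: list[np.ndarray] = []
    for j, ind in enumerate(outlier_individuals):
        mask = (ind_arr == ind).astype(float)
        col = mask / mask.std()
        outlier_cols.append(col)
        columns.append(col)
        names.append(f"outlier_{j + 1:02d}")

    # metabotype factors: orthonormal complement of the columns above within
    # the centered (pair-constant, when paired) sample space
    if paired_spike:
        n_meta = n_individuals - 1 - n_outliers
    else:
        n_meta = n - 1 - n_outliers - (1 if contrast != "none" else 0)
    if n_meta > 0:
        per_ind = rng.standard_normal((n_individuals, n_meta))
        raw_meta = per_ind[[individuals.index(i) for i in individual_ids], :]
        existing = [c - c.mean() for c in columns]
        basis = np.column_stack(
            existing + [raw_meta[:, j] - raw_meta[:, j].mean() for j in range(n_meta)]
        )
        q, r = np.linalg.qr(basis)
        start = len(existing)
        meta_cols = []
        for j in range(start, start + n_meta):
            if abs(r[j, j]) < 1e-10:  # pragma: no cover - rank loss has measure zero
                raise ConfigError("metabotype construction lost rank; change the seed")
            meta_cols.append(_unit_variance(q[:, j] - q[:, j].mean()))
        # insert metabotypes between the group column and the outlier columns
        insert_at = 1 if contrast != "none" else 0
        columns = columns[:insert_at] + meta_cols + columns[insert_at:]
        names = (
            names[:insert_at]
            + [f"metabotype_{j + 1:02d}" for j in range(n_meta)]
            + names[insert_at:]
        )

    Z = np.column_stack(columns) if columns else np.empty((n, 0))

    # dilution and specific gravity (shared within a native/spiked pair:
    # the spike is reconstituted in the same urine)
    if dilution_cv > 0:
        sigma = float(np.sqrt(np.log1p(dilution_cv**2)))
        per_ind_dil = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=n_individuals)
        dil = per_ind_dil[[individuals.index(i) for i in individual_ids]]
    else:
        dil = np.ones(n)
    sg = 1.0 + (sg_reference - 1.0) * dil
    sg = np.clip(sg, 1.0005, 1.050)

    return LatentDesign(
        sample_ids=sample_ids,
        individual_ids=individual_ids,
        group_labels=group_labels,
        factor_names=names,
        latent_scores=Z,
        dilution_factors=dil,
        specific_gravity=sg,
        spiked=spiked,
        paired_spike=paired_spike,
        contrast=contrast,
        outlier_individuals=outlier_individuals,
        sg_reference=sg_reference,
    )


# ---------------------------------------------------------------------------
# platform profiles and block rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlatformProfile:
    """How one instrument "sees" the latent design.

    ``variance_shares`` maps factor names — or factor-class names
    (``group``, ``metabotype``, ``outlier``), which are expanded equally
    over the matching design columns — to the fraction of the block's
    expected variance they carry.  Shares plus ``noise_fraction`` must sum
    to 1.  ``responds_to_spike`` is the fraction of features carrying the
    spike (i.e. with nonzero group loadings) in a paired spiking design.
    """

    instrument_id: str
    technology: str
    n_features: int
    variance_shares: Mapping[str, float]
    noise_fraction: float
    ion_mode: str = "none"
    responds_to_spike: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.technology not in TECHNOLOGIES:
            raise ConfigError(
                f"profile {self.instrument_id!r}: technology must be one of "
                f"{TECHNOLOGIES}"
            )
        if self.ion_mode not in ION_MODES:
            raise ConfigError(
                f"profile {self.instrument_id!r}: ion_mode must be one of {ION_MODES}"
            )
        if self.n_features < 1:
            raise ConfigError(f"profile {self.instrument_id!r}: n_features must be >= 1")
        total = float(sum(self.variance_shares.values())) + float(self.noise_fraction)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"profile {self.instrument_id!r}: variance shares plus noise "
                f"must sum to 1, got {total!r}"
            )
        if any(v < 0 for v in self.variance_shares.values()) or self.noise_fraction < 0:
            raise ConfigError(f"profile {self.instrument_id!r}: negative share")
        if not 0 < self.responds_to_spike <= 1:
            raise ConfigError(
                f"profile {self.instrument_id!r}: responds_to_spike must lie in (0, 1]"
            )


def expand_variance_shares(
    design: LatentDesign, profile: PlatformProfile
) -> np.ndarray:
    """Per-factor variance shares aligned with the design's factor columns.

    Class names are split equally over the class's columns.  Naming a factor
    or class absent from the design is a configuration error.
    """
    shares = np.zeros(design.n_factors)
    classes = design.factor_classes()
    name_to_idx = {n: i for i, n in enumerate(design.factor_names)}
    for key, value in profile.variance_shares.items():
        if key in name_to_idx:
            shares[name_to_idx[key]] += float(value)
        elif key in classes:
            idx = classes[key]
            shares[idx] += float(value) / len(idx)
        else:
            raise ConfigError(
                f"profile {profile.instrument_id!r} allocates variance to "
                f"{key!r}, which is not a factor of the design "
                f"(available: {design.factor_names})"
            )
    return shares


def _render_block(
    design: LatentDesign,
    profile: PlatformProfile,
    rng: np.random.Generator | None = None,
) -> tuple[Block, np.ndarray, np.ndarray]:
    """Render one block; also return the loading matrix and spike indices."""
    if rng is None:
        if profile.seed is None:
            raise ConfigError(
                f"profile {profile.instrument_id!r}: set profile.seed or pass rng"
            )
        rng = np.random.default_rng(profile.seed)
    shares = expand_variance_shares(design, profile)
    Z = design.centered_scores()
    Z = Z / Z.std(axis=0, keepdims=True)
    n, nf = Z.shape
    p = profile.n_features

    loadings = rng.standard_normal((p, nf))

    # spike carriers: in a paired spiking design the group contrast lives
    # only on the spike-carrying features
    spike_idx = np.array([], dtype=int)
    group_cols = [i for i, f in enumerate(design.factor_names) if f == "group"]
    if group_cols and design.paired_spike:
        n_carriers = max(1, int(round(profile.responds_to_spike * p)))
        spike_idx = np.sort(rng.choice(p, size=min(n_carriers, p), replace=False))
        mask = np.zeros(p, dtype=bool)
        mask[spike_idx] = True
        loadings[~mask, group_cols[0]] = 0.0

    # scale loading columns so each factor carries exactly its share of the
    # block's expected total variance (feature variance budget of 1 each)
    for f in range(nf):
        norm = np.linalg.norm(loadings[:, f])
        target = np.sqrt(shares[f] * p)
        loadings[:, f] = loadings[:, f] * (target / norm) if norm > 0 else 0.0
        if shares[f] == 0:
            loadings[:, f] = 0.0

    X = Z @ loadings.T
    if profile.noise_fraction > 0:
        X = X + rng.standard_normal((n, p)) * np.sqrt(profile.noise_fraction)
    # nonnegativity offset on the concentration scale, *then* dilution: real
    # intensities are nonnegative analyte levels scaled by the sample's
    # dilution, so dilution correction followed by column centering removes
    # the offset exactly instead of leaving an offset/dilution artifact
    low = X.min()
    if low < 0:
        X = X - low
    X = X * design.dilution_factors[:, None]

    feature_ids = [f"{profile.instrument_id}_F{j + 1:05d}" for j in range(p)]
    block = Block(
        instrument_id=profile.instrument_id,
        technology=profile.technology,
        ion_mode=profile.ion_mode,
        sample_ids=list(design.sample_ids),
        feature_ids=feature_ids,
        values=X,
    )
    return block, loadings, spike_idx


def render_block(
    design: LatentDesign,
    profile: PlatformProfile,
    rng: np.random.Generator | None = None,
) -> Block:
    """Render the design through one platform profile into a feature table."""
    block, _, _ = _render_block(design, profile, rng)
    return block


# ---------------------------------------------------------------------------
# whole-study simulation
# ---------------------------------------------------------------------------


@dataclass
class DesignConfig:
    n_individuals: int = 14
    contrast: str = "high"
    paired_spike: bool = True
    n_outliers: int = 2
    dilution_cv: float = 0.0
    sg_reference: float = 1.020

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(d) - allowed
        if unknown:
            raise ConfigError(f"unknown design keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RingStudyConfig:
    """Full simulation configuration: one design, >= 2 platform profiles."""

    design: DesignConfig
    platforms: list[PlatformProfile]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.platforms) < 2:
            raise ConfigError("a ring study needs at least 2 platform profiles")
        ids = [p.instrument_id for p in self.platforms]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ConfigError(f"duplicate instrument_id in platforms: {dupes}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RingStudyConfig":
        design = d.get("design", {})
        if not isinstance(design, DesignConfig):
            design = DesignConfig.from_dict(design)
        platforms = [
            p if isinstance(p, PlatformProfile) else PlatformProfile(**p)
            for p in d.get("platforms", [])
        ]
        return cls(design=design, platforms=platforms, seed=d.get("seed"))


@dataclass
class SimTruth:
    """Everything planted by the generator, for recovery tests.

    Given the master seed, the truth fully determines the generated block
    set; ``loadings`` maps instrument ID to its (n_features, n_factors)
    loading matrix and ``spike_features`` to the IDs of the spike-carrying
    features.
    """

    design: LatentDesign
    profiles: list[PlatformProfile]
    loadings: dict[str, np.ndarray] = field(default_factory=dict)
    spike_features: dict[str, list[str]] = field(default_factory=dict)

    def group_factor_index(self) -> int | None:
        try:
            return self.design.factor_names.index("group")
        except ValueError:
            return None


def simulate_ring_study(
    config: RingStudyConfig | Mapping,
    seed: int | None = None,
) -> tuple[BlockSet, SimTruth]:
    """Simulate a full multi-platform ring study.

    One master seed (argument overrides ``config.seed``) deterministically
    spawns a child seed for the design and one per platform, so appending a
    platform to the roster leaves all existing blocks unchanged.
    """
    if not isinstance(config, RingStudyConfig):
        config = RingStudyConfig.from_dict(config)
    master = seed if seed is not None else config.seed
    if master is None:
        raise ConfigError("a seed is required (config.seed or the seed argument)")
    ss = np.random.SeedSequence(master)
    children = ss.spawn(1 + len(config.platforms))

    design = make_latent_design(
        n_individuals=config.design.n_individuals,
        contrast=config.design.contrast,
        paired_spike=config.design.paired_spike,
        n_outliers=config.design.n_outliers,
        seed=children[0],
        dilution_cv=config.design.dilution_cv,
        sg_reference=config.design.sg_reference,
    )

    blocks: list[Block] = []
    truth = SimTruth(design=design, profiles=list(config.platforms))
    for child, profile in zip(children[1:], config.platforms):
        rng = np.random.default_rng(
            profile.seed if profile.seed is not None else child
        )
        block, loadings, spike_idx = _render_block(design, profile, rng)
        blocks.append(block)
        truth.loadings[profile.instrument_id] = loadings
        truth.spike_features[profile.instrument_id] = [
            block.feature_ids[j] for j in spike_idx
        ]

    blockset = BlockSet(blocks=blocks, metadata=design.metadata_frame())
    return blockset, truth
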