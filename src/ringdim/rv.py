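"""RV coefficients between data tables, permutation nulls, and link summaries.

The RV coefficient between two column-centered tables X (n x p) and Y
(n x q) sharing the same n samples is

    RV(X, Y) = trace(X X' Y Y') / sqrt(trace((X X')^2) * trace((Y Y')^2)),

the multivariate analogue of a squared correlation: it compares the two
sample configurations and lies in [0, 1].  Because the diagonal of the
cross-product matrices inflates RV for very wide tables, the modified RV
zeroes those diagonals before taking the same ratio; it lies in [-1, 1] and
is close to 0 for independent high-dimensional tables.

The permutation null breaks the sample correspondence by permuting the rows
of the second table, giving an empirical reference distribution for each
observed pairwise RV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .blocks import Block, BlockSet
from .errors import ConfigError, DomainError

VARIANTS = ("classic", "modified")


def _centered(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DomainError(f"expected a 2-D table, got shape {X.shape}")
    if X.shape[0] < 3:
        raise DomainError(f"RV needs at least 3 samples, got {X.shape[0]}")
    return X - X.mean(axis=0, keepdims=True)


def _gram(X: np.ndarray) -> np.ndarray:
    return X @ X.T


def _rv_from_grams(Sx: np.ndarray, Sy: np.ndarray, modified: bool) -> float:
    if modified:
        Sx = Sx - np.diag(np.diag(Sx))
        Sy = Sy - np.diag(np.diag(Sy))
    num = float(np.sum(Sx * Sy))
    den = float(np.linalg.norm(Sx) * np.linalg.norm(Sy))
    if den == 0:
        raise DomainError(
            "RV undefined: a table has zero (off-diagonal) cross-product norm"
        )
    return num / den


def _check_pair(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Xc, Yc = _centered(X), _centered(Y)
    if Xc.shape[0] != Yc.shape[0]:
        raise DomainError(
            f"tables must share the sample dimension: {Xc.shape[0]} vs {Yc.shape[0]}"
        )
    return Xc, Yc


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Classic RV coefficient between two tables sharing their rows.

    Tables are column-centered internally (a no-op when already centered).
    The value lies in [0, 1]; 1 means the two sample configurations are
    identical up to rotation and global scale.
    """
    Xc, Yc = _check_pair(X, Y)
    return _rv_from_grams(_gram(Xc), _gram(Yc), modified=False)


def modified_rv(X: np.ndarray, Y: np.ndarray) -> float:
    """Modified RV for wide tables: cross-product diagonals are zeroed.

    Removes the upward bias of the classic RV when the feature counts are
    large relative to the sample count; the value lies in [-1, 1] and is
    near 0 for independent tables.

    Unlike :func:`rv_coefficient`, the tables are used exactly as given:
    the diagonal-zeroing removes the large-p bias only when the
    cross-product off-diagonals are zero-mean, and exact per-feature
    centering itself couples the off-diagonals (their sum is forced to
    ``-trace``), re-introducing a bias that grows with the feature counts.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise DomainError("expected 2-D tables")
    if X.shape[0] != Y.shape[0]:
        raise DomainError(
            f"tables must share the sample dimension: {X.shape[0]} vs {Y.shape[0]}"
        )
    if X.shape[0] < 3:
        raise DomainError(f"RV needs at least 3 samples, got {X.shape[0]}")
    return _rv_from_grams(_gram(X), _gram(Y), modified=True)


# ---------------------------------------------------------------------------
# pairwise matrices
# ---------------------------------------------------------------------------


@dataclass
class RVMatrix:
    """Symmetric matrix of pairwise inter-block RV coefficients."""

    block_ids: list[str]
    values: np.ndarray  # (K, K)
    variant: str
    nulls: pd.DataFrame | None = None  # per-pair permutation-null summary

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.block_ids, columns=self.block_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variant: str = "classic") -> "RVMatrix":
        values = frame.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1] or list(frame.index) != list(frame.columns):
            raise ConfigError("RV matrix frame must be square with matching labels")
        return cls(list(frame.index.astype(str)), values, variant)

    def offdiag_pairs(self):
        k = len(self.block_ids)
        for i in range(k):
            for j in range(i + 1, k):
                yield self.block_ids[i], self.block_ids[j], self.values[i, j]


def _as_blocks(blockset: BlockSet | Sequence[Block]) -> list[Block]:
    return list(blockset.blocks) if isinstance(blockset, BlockSet) else list(blockset)


def rv_matrix(blockset: BlockSet | Sequence[Block], variant: str = "classic") -> RVMatrix:
    """All pairwise RV coefficients between the blocks of an aligned set.

    The classic diagonal is 1 by definition; the modified diagonal is
    computed (it equals 1 analytically).
    """
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    blocks = _as_blocks(blockset)
    modified = variant == "modified"
    grams = []
    for b in blocks:
        try:
            # the modified variant uses the tables as given (see modified_rv)
            grams.append(_gram(b.values if modified else _centered(b.values)))
        except DomainError as exc:
            raise DomainError(f"block {b.instrument_id!r}: {exc}") from None
    k = len(blocks)
    out = np.ones((k, k))
    for i in range(k):
        if modified:
            out[i, i] = _rv_from_grams(grams[i], grams[i], modified=True)
        for j in range(i + 1, k):
            try:
                out[i, j] = out[j, i] = _rv_from_grams(grams[i], grams[j], modified)
            except DomainError as exc:
                raise DomainError(
                    f"blocks {blocks[i].instrument_id!r} / "
                    f"{blocks[j].instrument_id!r}: {exc}"
                ) from None
    return RVMatrix([b.instrument_id for b in blocks], out, variant)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Empirical null for one table pair from row permutations of the second."""

    observed: float
    values: np.ndarray
    n_perm: int
    seed: int | None
    variant: str

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def q95(self) -> float:
        return float(np.quantile(self.values, 0.95))

    @property
    def exceedance(self) -> float:
        """Fraction of null draws at or above the observed RV."""
        return float(np.mean(self.values >= self.observed))


def rv_permutation_null(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = None,
    variant: str = "classic",
) -> PermutationNull:
    """Null RV distribution obtained by permuting the rows of ``Y``.

    Row permutation commutes with column centering, so the null values are
    computed by symmetric reindexing of the second table's cross-product
    matrix.  At least 100 permutations are required for stable quantiles.
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100 for stable quantiles, got {n_perm}")
    if variant not in VARIANTS:
        raise ConfigError(f"variant must be one of {VARIANTS}, got {variant!r}")
    modified = variant == "modified"
    if modified:
        Xc, Yc = np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
    else:
        Xc, Yc = _check_pair(X, Y)
    Sx, Sy = _gram(Xc), _gram(Yc)
    observed = _rv_from_grams(Sx, Sy, modified)
    rng = np.random.default_rng(seed)
    n = Sy.shape[0]
    values = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(n)
        values[t] = _rv_from_grams(Sx, Sy[np.ix_(perm, perm)], modified)
    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    return PermutationNull(
        observed=observed, values=values, n_perm=n_perm,
        seed=seed_int, variant=variant,
    )


def pairwise_permutation_nulls(
    blockset: BlockSet | Sequence[Block],
    n_perm: int = 999,
    seed: int | None = None,
    variant: str = "classic",
) -> pd.DataFrame:
    """Permutation-null summaries for every block pair, one child seed each."""
    blocks = _as_blocks(blockset)
    k = len(blocks)
    children = iter(np.random.SeedSequence(seed).spawn(k * (k - 1) // 2))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            null = rv_permutation_null(
                blocks[i].values, blocks[j].values,
                n_perm=n_perm, seed=next(children), variant=variant,
            )
            rows.append(
                {
                    "block_a": blocks[i].instrument_id,
                    "block_b": blocks[j].instrument_id,
                    "observed": null.observed,
                    "null_median": null.median,
                    "null_q95": null.q95,
                    "exceedance": null.exceedance,
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# link summaries (within / between technologies)
# ---------------------------------------------------------------------------


@dataclass
class LinkSummary:
    """Average RV links per block and within/between technologies.

    ``per_block`` has one row per block with its mean RV to all other
    blocks, to blocks of the same technology, and to blocks of the other
    technologies.  ``within``/``between`` are simple arithmetic means over
    the unique off-diagonal pairs of each kind; a technology with a single
    member has no within average (absent, NaN).
    """

    per_block: pd.DataFrame
    within: dict[str, float]
    between: dict[tuple[str, str], float]


def average_links(
    rvm: RVMatrix, technologies: Mapping[str, str]
) -> LinkSummary:
    """Summarize an RV matrix into per-block and technology-level averages."""
    missing = [b for b in rvm.block_ids if b not in technologies]
    if missing:
        raise ConfigError(f"technology label missing for blocks {missing[:5]}")
    ids = rvm.block_ids
    tech = np.array([technologies[b] for b in ids])
    V = rvm.values
    k = len(ids)
    off = ~np.eye(k, dtype=bool)

    rows = []
    for i, b in enumerate(ids):
        others = off[i]
        same = others & (tech == tech[i])
        diff = others & (tech != tech[i])
        rows.append(
            {
                "block_id": b,
                "technology": tech[i],
                "mean_all": float(V[i, others].mean()),
                "mean_within": float(V[i, same].mean()) if same.any() else np.nan,
                "mean_between": float(V[i, diff].mean()) if diff.any() else np.nan,
            }
        )
    per_block = pd.DataFrame(rows).set_index("block_id")

    within: dict[str, float] = {}
    for t in sorted({str(t) for t in tech}):
        idx = np.nonzero(tech == t)[0]
        if len(idx) < 2:
            continue
        vals = [V[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]]
        within[t] = float(np.mean(vals))

    between: dict[tuple[str, str], float] = {}
    techs = sorted({str(t) for t in tech})
    for a in range(len(techs)):
        for b in range(a + 1, len(techs)):
            ia = np.nonzero(tech == techs[a])[0]
            ib = np.nonzero(tech == techs[b])[0]
            vals = [V[i, j] for i in ia for j in ib]
            between[(techs[a], techs[b])] = float(np.mean(vals))

    return LinkSummary(per_block=per_block, within=within, between=between)
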